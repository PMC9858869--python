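"""Synthetic two-species RAD-seq study generator.

Produces a complete, internally consistent study bundle — all-sites
VCF, reference FASTA, GFF3 gene models, gene->GO map, population map
and a machine-readable truth file — simulated under a known two-deme
demographic history (see :mod:`divscan.models`).  The genome is a set
of short RAD-like loci scattered over several chromosomes; each locus
carries one non-recombining genealogy with infinite-sites mutations.

Divergent regions emulate barriers to gene flow: loci inside them are
simulated without migration (``barrier`` mode), optionally sharing a
single genealogy per region to mimic a non-recombining inversion-like
block (``barrier+linked`` mode), and with a reduced local effective
size (sweep-like diversity loss).  Downstream scans should therefore
recover elevated FST, elevated dxy, reduced diversity and long-range
LD inside these regions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from random import Random
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coalescent import Genealogy, sample_locus_genealogy
from .models import MODELS, DemographicParams, ModelSpec
from .types import GenotypeMatrix

__all__ = [
    "GenomeLayout",
    "SimulationConfig",
    "SimulatedDataset",
    "genotypes_from_genealogy",
    "simulate_dataset",
    "write_dataset",
    "default_layout",
]

BASES = "ACGT"


@dataclass(frozen=True)
class Locus:
    chrom: str
    start: int  # 1-based
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class DivergentRegion:
    chrom: str
    start: int
    end: int
    mode: str  # "barrier" or "barrier+linked"

    def __post_init__(self):
        if self.mode not in ("barrier", "barrier+linked"):
            raise ValueError(f"unknown divergent-region mode {self.mode!r}")

    def contains(self, locus: Locus) -> bool:
        return (
            locus.chrom == self.chrom
            and locus.start >= self.start
            and locus.end <= self.end
        )


@dataclass
class GenomeLayout:
    """Chromosomes, RAD-like loci, and divergent-region annotations."""

    chromosomes: List[Tuple[str, int]]
    loci: List[Locus]
    divergent_regions: List[DivergentRegion] = field(default_factory=list)

    def __post_init__(self):
        lengths = dict(self.chromosomes)
        by_chrom: Dict[str, List[Locus]] = {}
        for loc in self.loci:
            if loc.length < 1:
                raise ValueError("locus length must be >= 1")
            if loc.chrom not in lengths:
                raise ValueError(f"locus on unknown chromosome {loc.chrom!r}")
            if loc.start < 1 or loc.end > lengths[loc.chrom]:
                raise ValueError(f"locus {loc} outside chromosome bounds")
            by_chrom.setdefault(loc.chrom, []).append(loc)
        for chrom, locs in by_chrom.items():
            locs = sorted(locs, key=lambda l: l.start)
            for a, b in zip(locs, locs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping loci on {chrom}: {a} / {b}")
        for reg in self.divergent_regions:
            if reg.chrom not in lengths:
                raise ValueError(f"region on unknown chromosome {reg.chrom!r}")
            if reg.start < 1 or reg.end > lengths[reg.chrom] or reg.start > reg.end:
                raise ValueError(f"region {reg} outside chromosome bounds")

    def region_of(self, locus: Locus) -> Optional[DivergentRegion]:
        for reg in self.divergent_regions:
            if reg.contains(locus):
                return reg
        return None


def default_layout(
    n_chromosomes: int = 6,
    chrom_length: int = 500_000,
    n_loci: int = 240,
    locus_length: int = 150,
    n_divergent: int = 2,
    region_length: int = 100_000,
    mode: str = "barrier+linked",
    seed: int = 0,
) -> GenomeLayout:
    """A scaled-down multi-chromosome RAD landscape.

    Loci are evenly spaced within each chromosome; the first
    ``n_divergent`` chromosomes carry one divergent region each, placed
    mid-chromosome.
    """
    rng = Random(seed)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chromosomes)]
    per = n_loci // n_chromosomes
    loci: List[Locus] = []
    spacing = chrom_length // (per + 1)
    for name, _ in chroms:
        for j in range(per):
            start = (j + 1) * spacing + rng.randrange(-spacing // 4, spacing // 4)
            start = max(1, min(start, chrom_length - locus_length))
            loci.append(Locus(name, start, locus_length))
    regions = []
    for i in range(n_divergent):
        chrom = f"chr{i + 1}"
        start = (chrom_length - region_length) // 2 + 1
        regions.append(DivergentRegion(chrom, start, start + region_length - 1, mode))
    return GenomeLayout(chroms, loci, regions)


@dataclass
class SimulationConfig:
    layout: GenomeLayout
    model: ModelSpec
    truth: DemographicParams
    samples_per_deme: Tuple[int, int] = (30, 15)
    theta_per_locus: float = 4.0
    seed: int = 0
    #: local Ne multiplier inside divergent regions (sweep-like loss of
    #: diversity); 1.0 disables it.
    region_ne_scale: float = 0.3
    #: inversion-polymorphism emulation inside barrier+linked regions:
    #: deme-B haploid lineages carry one of two orientations (minor
    #: frequency ``inversion_freq``) and a fraction of each region
    #: locus's mutations become orientation markers — sites in complete
    #: mutual LD across the whole region within deme B, as expected for
    #: loci differentiated between non-recombining inversion
    #: orientations.  Set the fraction to 0 to disable.
    inversion_freq: float = 0.25
    inversion_marker_fraction: float = 0.25
    #: fraction of loci overlapped by a gene model
    gene_fraction: float = 0.4
    species_names: Tuple[str, str] = ("maximus", "jacobaeus")
    populations_per_species: Tuple[int, int] = (4, 2)
    #: DP ~ NegBinom(mean, dispersion); GQ = min(99, Poisson(gq_mean)).
    dp_mean: float = 20.0
    dp_dispersion: float = 5.0
    gq_mean: float = 40.0

    def __post_init__(self):
        s1, s2 = self.samples_per_deme
        if s1 < 2 or s2 < 2:
            raise ValueError("need at least two diploid samples per deme")
        if self.theta_per_locus <= 0:
            raise ValueError("theta_per_locus must be > 0")
        self.truth.validate()


def _harmonic(n: int) -> float:
    return sum(1.0 / i for i in range(1, n + 1))


def genotypes_from_genealogy(
    tree: Genealogy,
    theta: float,
    locus_length: int,
    rng: np.random.Generator,
    branch_scale: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Drop infinite-sites mutations on a genealogy.

    The mutation count is Poisson with mean
    ``theta * L / branch_scale`` where ``L`` is the realised total
    branch length; ``branch_scale`` defaults to the neutral
    single-deme expectation ``4 * N * H_{n-1}`` evaluated at ``N`` such
    that the scale equals ``L``'s long-run mean — callers pass the
    expectation appropriate to their reference size.  When no scale is
    given the realised ``L`` itself is used, making ``theta`` the exact
    expected mutation count per locus.

    Returns ``(offsets, dosages)``: 0-based distinct positions within
    the locus (sorted) and an ``(n_mut, n_individuals)`` diploid ALT
    dosage matrix; haploid leaves ``2i`` and ``2i+1`` form individual
    ``i``.

    Raises ``ValueError`` if more mutations than positions are drawn.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    lengths = tree.branch_lengths()
    total = lengths.sum()
    scale = total if branch_scale is None else branch_scale
    n_mut = int(rng.poisson(theta * total / scale)) if total > 0 else 0
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, tree.n_leaves // 2), np.int8)
    if n_mut > locus_length:
        raise ValueError(
            f"{n_mut} mutations cannot occupy {locus_length} distinct positions"
        )
    offsets = np.sort(rng.choice(locus_length, size=n_mut, replace=False))
    probs = lengths / total
    branches = rng.choice(tree.n_nodes, size=n_mut, p=probs)
    sets = tree.leaf_sets()
    n_ind = tree.n_leaves // 2
    dosages = np.zeros((n_mut, n_ind), dtype=np.int8)
    for k, node in enumerate(branches):
        for leaf in sets[node]:
            dosages[k, leaf // 2] += 1
    return offsets, dosages


@dataclass
class SimulatedDataset:
    """In-memory result of a simulation run (pre-noise truth)."""

    config: SimulationConfig
    allsites: GenotypeMatrix  # every locus position, with GQ/DP noise
    popmap: pd.DataFrame
    site_region: np.ndarray  # region label per all-sites row
    locus_truth: List[dict]  # per-locus TMRCA, region, mutation origins
    reference: Dict[str, np.ndarray]  # chrom -> base array (uint8 codes)

    def variants(self) -> GenotypeMatrix:
        """The variant-only view (sites with an ALT allele)."""
        return self.allsites.take_sites(self.allsites.is_variant())


def _mutation_origin(dos_row: np.ndarray, s1: int) -> str:
    """Classify a mutation by which deme carries the derived allele."""
    a = int(dos_row[:s1].sum())
    b = int(dos_row[s1:].sum())
    if a and b:
        return "shared"
    return "A" if a else "B"


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator; deterministic in ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pyrng = Random(int(rng.integers(2**31)))
    s1, s2 = cfg.samples_per_deme
    n1, n2 = 2 * s1, 2 * s2
    n_ind = s1 + s2
    truth = cfg.truth
    # reference branch-length scale: neutral single-deme expectation at
    # the deme-A size, so theta_per_locus reads as 4*N*mu*H-style units
    branch_scale = 4.0 * truth.n_pma * _harmonic(n1 + n2 - 1)

    # sample names / popmap
    names = [f"pma{i:03d}" for i in range(s1)] + [f"pja{i:03d}" for i in range(s2)]
    sp_a, sp_b = cfg.species_names
    pops_a, pops_b = cfg.populations_per_species
    rows = []
    for i in range(s1):
        rows.append((names[i], sp_a, f"{sp_a}_p{i % pops_a + 1}"))
    for i in range(s2):
        rows.append((names[s1 + i], sp_b, f"{sp_b}_p{i % pops_b + 1}"))
    popmap = pd.DataFrame(rows, columns=["sample", "species", "population"])

    # one shared genealogy (and one inversion-orientation assignment)
    # per barrier+linked region
    region_tree: Dict[int, Genealogy] = {}
    region_orient: Dict[int, np.ndarray] = {}
    scale = cfg.region_ne_scale

    def region_params() -> DemographicParams:
        return truth.replace(
            n_pma=truth.n_pma * scale, n_pja=truth.n_pja * scale
        )

    for ridx, reg in enumerate(cfg.layout.divergent_regions):
        if reg.mode == "barrier+linked":
            region_tree[ridx] = sample_locus_genealogy(
                region_params(), cfg.model, (n1, n2), barrier=True, rng=pyrng
            )
            # exactly round(freq * n2) carrier lineages, so the minor
            # orientation always segregates at intermediate frequency
            n_carriers = max(2, int(round(cfg.inversion_freq * n2)))
            orient = np.zeros(n2, dtype=np.int8)
            orient[rng.choice(n2, size=n_carriers, replace=False)] = 1
            region_orient[ridx] = orient

    loci_sorted = sorted(cfg.layout.loci, key=lambda l: (l.chrom, l.start))
    chrom_rows: List[tuple] = []  # (chrom, pos, dosage_row or None, region)
    locus_truth: List[dict] = []
    for loc in loci_sorted:
        reg = cfg.layout.region_of(loc)
        if reg is None:
            tree = sample_locus_genealogy(
                truth, cfg.model, (n1, n2), barrier=False, rng=pyrng
            )
            label = "neutral"
        else:
            ridx = cfg.layout.divergent_regions.index(reg)
            label = reg.mode
            if reg.mode == "barrier+linked":
                tree = region_tree[ridx]
            else:
                tree = sample_locus_genealogy(
                    region_params(), cfg.model, (n1, n2), barrier=True, rng=pyrng
                )
        offsets, dosages = genotypes_from_genealogy(
            tree, cfg.theta_per_locus, loc.length, rng, branch_scale
        )
        marker = np.zeros(len(offsets), dtype=bool)
        if label == "barrier+linked" and cfg.inversion_marker_fraction > 0:
            orient = region_orient[cfg.layout.divergent_regions.index(reg)]
            b_dosage = orient[0::2] + orient[1::2]  # per deme-B individual
            marker = rng.random(len(offsets)) < cfg.inversion_marker_fraction
            for k in np.flatnonzero(marker):
                dosages[k, :s1] = 0
                dosages[k, s1:] = b_dosage
        mut = {int(o): dosages[k] for k, o in enumerate(offsets)}
        for off in range(loc.length):
            chrom_rows.append((loc.chrom, loc.start + off, mut.get(off), label))
        locus_truth.append(
            {
                "chrom": loc.chrom,
                "start": loc.start,
                "length": loc.length,
                "region": label,
                "tmrca": tree.tmrca,
                "n_mutations": len(offsets),
                "mutation_origins": [
                    "inversion_marker" if marker[k] else _mutation_origin(dosages[k], s1)
                    for k in range(len(offsets))
                ],
            }
        )

    n_sites = len(chrom_rows)
    gt = np.zeros((n_sites, n_ind), dtype=np.int8)
    chroms = np.empty(n_sites, dtype=object)
    pos = np.empty(n_sites, dtype=np.int64)
    region_lab = np.empty(n_sites, dtype=object)
    variant = np.zeros(n_sites, dtype=bool)
    for i, (chrom, p, dos, lab) in enumerate(chrom_rows):
        chroms[i] = chrom
        pos[i] = p
        region_lab[i] = lab
        if dos is not None:
            gt[i] = dos
            variant[i] = True

    # reference sequence and alleles
    reference: Dict[str, np.ndarray] = {}
    for chrom, length in cfg.layout.chromosomes:
        reference[chrom] = rng.integers(0, 4, size=length, dtype=np.uint8)
    ref = np.empty(n_sites, dtype=object)
    alt = np.empty(n_sites, dtype=object)
    for i in range(n_sites):
        base = int(reference[chroms[i]][pos[i] - 1])
        ref[i] = BASES[base]
        if variant[i]:
            alt[i] = BASES[(base + 1 + int(rng.integers(0, 3))) % 4]
        else:
            alt[i] = None

    # sequencing-noise annotations
    p_nb = cfg.dp_dispersion / (cfg.dp_dispersion + cfg.dp_mean)
    dp = rng.negative_binomial(cfg.dp_dispersion, p_nb, size=gt.shape).astype(np.int16)
    gq = np.minimum(99, rng.poisson(cfg.gq_mean, size=gt.shape)).astype(np.int16)
    gt = gt.copy()
    gt[dp == 0] = -1  # no reads, no call

    allsites = GenotypeMatrix(
        samples=names,
        chrom=chroms,
        pos=pos,
        ref=ref,
        alt=alt,
        gt=gt,
        gq=gq,
        dp=dp,
    )
    return SimulatedDataset(
        config=cfg,
        allsites=allsites,
        popmap=popmap,
        site_region=region_lab,
        locus_truth=locus_truth,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# file output


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def _write_fasta(reference: Dict[str, np.ndarray], path: Path) -> None:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for chrom, codes in reference.items():
            fh.write(f">{chrom}\n")
            seq = lut[codes].tobytes().decode()
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_vcf(ds: SimulatedDataset, path: Path) -> None:
    gm = ds.allsites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscan-simdata\n")
        for chrom, length in ds.config.layout.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            alt = gm.alt[i] or "."
            cells = [
                f"{_GT_STR[int(g)]}:{int(q)}:{int(d)}"
                for g, q, d in zip(gm.gt[i], gm.gq[i], gm.dp[i])
            ]
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{alt}\t.\tPASS\t.\t"
                "GT:GQ:DP\t" + "\t".join(cells) + "\n"
            )


#: gene-model template, offsets relative to gene start (1-based spans):
#: exon1 [0,99] = 5'UTR [0,29] + CDS [30,99]; intron [100,169];
#: exon2 [170,269] = CDS [170,231] + 3'UTR [232,269].  CDS length 132.
GENE_SPAN = 270
_T = {
    "exon1": (0, 99),
    "utr5": (0, 29),
    "cds1": (30, 99),
    "intron": (100, 169),
    "exon2": (170, 269),
    "cds2": (170, 231),
    "utr3": (232, 269),
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


def _plant_codons(reference, chrom, g0, strand):
    """Force an ATG start and TAA stop into the reference CDS."""
    codes = reference[chrom]

    def put(pos0, base):  # pos0: 0-based
        codes[pos0] = _CODE[base]

    if strand == "+":
        c1 = g0 + _T["cds1"][0]
        for k, b in enumerate("ATG"):
            put(c1 + k, b)
        c2_end = g0 + _T["cds2"][1]
        for k, b in enumerate("TAA"):
            put(c2_end - 2 + k, b)
    else:
        # minus strand: CDS read from the right end leftwards, complemented
        c_start = g0 + _T["cds2"][1]  # first base of codon 1 on - strand
        for k, b in enumerate("ATG"):
            codes[c_start - k] = _COMP[_CODE[b]]
        c_end = g0 + _T["cds1"][0]  # last base of the stop codon
        for k, b in enumerate("TAA"):
            codes[c_end + 2 - k] = _COMP[_CODE[b]]


def _write_gff(ds: SimulatedDataset, path: Path, rng: np.random.Generator):
    """Place gene models over a fraction of loci; returns gene table."""
    cfg = ds.config
    lengths = dict(cfg.layout.chromosomes)
    loci = sorted(cfg.layout.loci, key=lambda l: (l.chrom, l.start))
    n_genes = int(round(cfg.gene_fraction * len(loci)))
    chosen = sorted(rng.choice(len(loci), size=n_genes, replace=False).tolist())
    genes = []
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gnum, li in enumerate(chosen):
            loc = loci[li]
            # cycle gene placements so variants (which only occur inside
            # the locus) can fall in every feature class: left-aligned
            # (5'UTR side), centred, right-aligned (3'UTR side)
            offset = (loc.start, loc.start - 60, loc.end - GENE_SPAN + 1)[gnum % 3]
            g0 = max(1, offset)
            g0 = min(g0, lengths[loc.chrom] - GENE_SPAN + 1)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            gid = f"gene{gnum + 1:04d}"
            _plant_codons(ds.reference, loc.chrom, g0 - 1, strand)
            s = lambda a, b: (g0 + a, g0 + b)

            def line(ftype, a, b, attrs, phase="."):
                x, y = s(a, b)
                fh.write(
                    f"{loc.chrom}\tdivscan\t{ftype}\t{x}\t{y}\t.\t{strand}\t{phase}\t{attrs}\n"
                )

            line("gene", 0, GENE_SPAN - 1, f"ID={gid}")
            line("mRNA", 0, GENE_SPAN - 1, f"ID={gid}.t1;Parent={gid}")
            line("exon", *_T["exon1"], f"ID={gid}.e1;Parent={gid}.t1")
            line("exon", *_T["exon2"], f"ID={gid}.e2;Parent={gid}.t1")
            if strand == "+":
                line("five_prime_UTR", *_T["utr5"], f"Parent={gid}.t1")
                line("CDS", *_T["cds1"], f"ID={gid}.c;Parent={gid}.t1", "0")
                line("CDS", *_T["cds2"], f"ID={gid}.c;Parent={gid}.t1", "2")
                line("three_prime_UTR", *_T["utr3"], f"Parent={gid}.t1")
            else:
                line("three_prime_UTR", *_T["utr5"], f"Parent={gid}.t1")
                line("CDS", *_T["cds1"], f"ID={gid}.c;Parent={gid}.t1", "2")
                line("CDS", *_T["cds2"], f"ID={gid}.c;Parent={gid}.t1", "0")
                line("five_prime_UTR", *_T["utr3"], f"Parent={gid}.t1")
            genes.append((gid, loc.chrom, g0, g0 + GENE_SPAN - 1, strand))
    return genes


def _write_go_map(genes, path: Path, parents_path: Path, rng: np.random.Generator):
    """Assign each gene 1-3 terms from a small two-level ontology."""
    leaves = [f"GO:{i:07d}" for i in range(1, 13)]
    parents = {
        leaves[i]: f"GO:{1000 + i // 4:07d}" for i in range(len(leaves))
    }  # 4 leaves per parent
    with open(parents_path, "w") as fh:
        fh.write("term\tparent\n")
        for child, par in parents.items():
            fh.write(f"{child}\t{par}\n")
    with open(path, "w") as fh:
        for gid, *_ in genes:
            k = int(rng.integers(1, 4))
            terms = rng.choice(len(leaves), size=k, replace=False)
            fh.write(gid + "\t" + ",".join(leaves[t] for t in sorted(terms)) + "\n")


def write_dataset(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Simulate and write the full study bundle; byte-deterministic.

    Returns a name -> path mapping for: vcf, fasta, gff, go_map,
    go_parents, popmap, truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    # file-layout randomness separated from the genealogy stream so the
    # in-memory dataset matches simulate_dataset() with the same seed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    paths = {
        "vcf": outdir / "sites.vcf",
        "fasta": outdir / "reference.fa",
        "gff": outdir / "genes.gff3",
        "go_map": outdir / "go_map.tsv",
        "go_parents": outdir / "go_parents.tsv",
        "popmap": outdir / "popmap.tsv",
        "truth": outdir / "truth.json",
    }
    genes = _write_gff(ds, paths["gff"], rng)  # may edit reference (codons)
    # re-derive REF/ALT where codon planting changed the reference
    gm = ds.allsites
    for i in range(gm.n_sites):
        base = "ACGT"[int(ds.reference[gm.chrom[i]][gm.pos[i] - 1])]
        if gm.ref[i] != base:
            gm.ref[i] = base
            if gm.alt[i] is not None and gm.alt[i] == base:
                gm.alt[i] = "ACGT"[(_CODE[base] + 1) % 4]
    _write_fasta(ds.reference, paths["fasta"])
    _write_vcf(ds, paths["vcf"])
    _write_go_map(genes, paths["go_map"], paths["go_parents"], rng)
    ds.popmap.to_csv(paths["popmap"], sep="\t", header=False, index=False)
    truth = {
        "model": config.model.name,
        "params": config.truth.as_dict(),
        "seed": config.seed,
        "samples_per_deme": list(config.samples_per_deme),
        "theta_per_locus": config.theta_per_locus,
        "region_ne_scale": config.region_ne_scale,
        "divergent_regions": [
            {"chrom": r.chrom, "start": r.start, "end": r.end, "mode": r.mode}
            for r in config.layout.divergent_regions
        ],
        "loci": ds.locus_truth,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
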