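"""Variant effect classification against GFF3 + FASTA, and GO enrichment.

Each SNP receives exactly one category — the most severe applicable
one, with precedence loss-of-function > missense > synonymous >
splice-region > UTR > intron > up/downstream > intergenic.  Coding
effects are computed by codon substitution under the standard genetic
code, strand-aware.  Loss of function covers stop-gained, start-lost
and splice donor/acceptor (intronic 1–2 bp) variants.  Up/downstream
extends 5 kb from the gene span and the splice region covers intronic
positions 3–8 bp from an exon boundary (common annotation-tool
defaults).

GO enrichment is a one-sided Fisher exact (hypergeometric upper-tail)
test per term, either independently per term ("classic") or with the
"elim" decorrelation: terms are processed most-specific-first and the
genes of significant child terms are removed from their ancestors
before testing.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

import gffutils
from Bio.Seq import Seq

__all__ = [
    "VariantEffect",
    "EnrichmentRow",
    "Annotator",
    "go_enrichment",
    "tabulate_effects",
    "load_go_map",
    "load_go_parents",
    "CATEGORIES",
]

#: category -> (within_gene, transcribed), most severe first
CATEGORIES = {
    "loss_of_function": (True, True),
    "missense_variant": (True, True),
    "synonymous_variant": (True, True),
    "splice_region_intron_variant": (True, False),
    "5'UTR": (True, False),
    "3'UTR": (True, False),
    "intron_variant": (True, False),
    "upstream_gene_variant": (False, False),
    "downstream_gene_variant": (False, False),
    "intergenic_region": (False, False),
}

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class VariantEffect:
    category: str
    gene_id: Optional[str]
    detail: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown effect category {self.category!r}")

    @property
    def within_gene(self) -> bool:
        return CATEGORIES[self.category][0]

    @property
    def transcribed(self) -> bool:
        return CATEGORIES[self.category][1]


class Annotator:
    """Classifies variants against a GFF3 gene set and reference FASTA.

    ``fasta`` is a ``pyfaidx.Fasta``-like mapping of chromosome name to
    indexable sequence.  The GFF3 must use gene/mRNA/exon/CDS (and
    optionally five_prime_UTR/three_prime_UTR) features with Parent
    links.
    """

    def __init__(
        self,
        gff_path,
        fasta,
        updown_dist: int = 5000,
        splice_intron: Tuple[int, int] = (3, 8),
    ):
        self.db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        self.fasta = fasta
        self.updown_dist = updown_dist
        self.splice_intron = splice_intron
        self._genes: Dict[str, List] = {}
        for g in self.db.features_of_type("gene"):
            self._genes.setdefault(g.seqid, []).append(g)
        for genes in self._genes.values():
            genes.sort(key=lambda g: g.start)
        self._flagged: Set[str] = set()

    # -- gene lookup -------------------------------------------------

    def assign_gene(self, chrom: str, pos: int) -> Optional[str]:
        """Containing gene, else the nearest by span distance.

        Ties are broken by the lower start coordinate.  Returns None on
        a chromosome without genes.
        """
        genes = self._genes.get(chrom, [])
        if not genes:
            return None
        best = None
        best_key = None
        for g in genes:
            if g.start <= pos <= g.end:
                dist = 0
            elif pos < g.start:
                dist = g.start - pos
            else:
                dist = pos - g.end
            key = (dist, g.start)
            if best_key is None or key < best_key:
                best, best_key = g, key
        return best.id

    # -- classification ----------------------------------------------

    def classify(self, chrom: str, pos: int, ref: str, alt: str) -> VariantEffect:
        base = str(self.fasta[chrom][pos - 1 : pos]).upper()
        if base != ref.upper():
            raise ValueError(
                f"REF mismatch at {chrom}:{pos}: FASTA has {base}, VCF has {ref}"
            )
        genes = self._genes.get(chrom, [])
        containing = [g for g in genes if g.start <= pos <= g.end]
        if containing:
            effects = [self._within_gene(g, chrom, pos, ref, alt) for g in containing]
            order = list(CATEGORIES)
            return min(effects, key=lambda e: order.index(e.category))
        # upstream/downstream of the nearest gene within updown_dist
        best = None
        for g in genes:
            dist = g.start - pos if pos < g.start else pos - g.end
            if dist <= self.updown_dist and (best is None or dist < best[0]):
                side_5prime = (pos < g.start) == (g.strand != "-")
                best = (dist, "upstream_gene_variant" if side_5prime else "downstream_gene_variant", g.id)
        if best:
            return VariantEffect(best[1], best[2])
        return VariantEffect("intergenic_region", None)

    def _transcript_parts(self, gene):
        mrnas = list(self.db.children(gene, featuretype="mRNA"))
        if not mrnas:
            return None
        t = mrnas[0]
        exons = sorted(self.db.children(t, featuretype="exon"), key=lambda f: f.start)
        cds = sorted(self.db.children(t, featuretype="CDS"), key=lambda f: f.start)
        return t, exons, cds

    def _within_gene(self, gene, chrom, pos, ref, alt) -> VariantEffect:
        parts = self._transcript_parts(gene)
        gid = gene.id
        if parts is None:
            return VariantEffect("intron_variant", gid, "no mRNA feature")
        t, exons, cds = parts
        strand = gene.strand
        in_exon = any(e.start <= pos <= e.end for e in exons)
        in_cds = any(c.start <= pos <= c.end for c in cds)
        if in_cds:
            return self._coding_effect(gene, cds, strand, chrom, pos, ref, alt)
        if in_exon:
            return VariantEffect(self._utr_side(pos, cds, strand), gid)
        # intronic: distance (in bp into the intron) from the closest
        # flanking exon boundary; 1 means the first intronic base
        dists = []
        for e in exons:
            if pos < e.start:
                dists.append(e.start - pos)
            elif pos > e.end:
                dists.append(pos - e.end)
        d = min(dists) if dists else 10**9
        lo, hi = self.splice_intron
        if d <= 2:
            return VariantEffect("loss_of_function", gid, "splice_donor_acceptor")
        if lo <= d <= hi:
            return VariantEffect("splice_region_intron_variant", gid)
        return VariantEffect("intron_variant", gid)

    def _utr_side(self, pos, cds, strand) -> str:
        if not cds:
            return "5'UTR"
        cds_start = min(c.start for c in cds)
        cds_end = max(c.end for c in cds)
        before = pos < cds_start
        if strand == "-":
            return "3'UTR" if before else "5'UTR"
        return "5'UTR" if before else "3'UTR"

    def _coding_effect(self, gene, cds, strand, chrom, pos, ref, alt) -> VariantEffect:
        gid = gene.id
        coords: List[int] = []
        for c in cds:
            coords.extend(range(c.start, c.end + 1))
        if len(coords) % 3 != 0:
            if gid not in self._flagged:
                self._flagged.add(gid)
                warnings.warn(
                    f"CDS length of {gid} not divisible by 3; coding effects skipped",
                    stacklevel=3,
                )
            return VariantEffect("intron_variant", gid, "broken CDS")
        if strand == "-":
            coords = coords[::-1]
        idx = coords.index(pos)
        codon_i = idx // 3
        codon_pos = idx % 3
        codon_coords = coords[3 * codon_i : 3 * codon_i + 3]
        seq = self.fasta[chrom]

        def base_at(p):
            return str(seq[p - 1 : p]).upper()

        def oriented(b):
            return str(Seq(b).complement()) if strand == "-" else b

        ref_codon = "".join(oriented(base_at(p)) for p in codon_coords)
        alt_codon = list(ref_codon)
        alt_codon[codon_pos] = oriented(alt.upper())
        alt_codon = "".join(alt_codon)
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if codon_i == 0 and ref_codon == "ATG" and alt_codon != "ATG":
            return VariantEffect("loss_of_function", gid, "start_lost")
        if alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS:
            return VariantEffect("loss_of_function", gid, "stop_gained")
        if ref_aa == alt_aa:
            return VariantEffect("synonymous_variant", gid)
        return VariantEffect(
            "missense_variant", gid, f"{ref_aa}{codon_i + 1}{alt_aa}"
        )


# ---------------------------------------------------------------------------
# GO enrichment


@dataclass
class EnrichmentRow:
    go_id: str
    term: str
    n_study_with: int
    n_study: int
    n_bg_with: int
    n_bg: int
    p_value: float


def load_go_map(path) -> Dict[str, Set[str]]:
    """Read a gene -> comma-separated-GO-terms TSV."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, terms = line.split("\t")[:2]
            out[gene] = set(t for t in terms.split(",") if t)
    return out


def load_go_parents(path) -> Dict[str, Set[str]]:
    """Read a term -> parent TSV (optionally with a header line)."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or parts[0] in ("term", "#term"):
                continue
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def _ancestors(term: str, parents: Mapping[str, Set[str]]) -> Set[str]:
    seen: Set[str] = set()
    stack = list(parents.get(term, ()))
    while stack:
        p = stack.pop()
        if p not in seen:
            seen.add(p)
            stack.extend(parents.get(p, ()))
    return seen


def _topo_specific_first(terms: Set[str], parents: Mapping[str, Set[str]]) -> List[str]:
    """Order with every term before its ancestors (children first)."""
    depth: Dict[str, int] = {}

    def d(t: str) -> int:
        if t not in depth:
            anc = _ancestors(t, parents)
            depth[t] = len(anc & terms)
        return depth[t]

    # fewer ancestors inside the term set = closer to the root; sort
    # descending so leaves (most specific) come first
    return sorted(terms, key=lambda t: (-d(t), t))


def go_enrichment(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    go_map: Mapping[str, Set[str]],
    algorithm: str = "classic",
    alpha: float = 0.05,
    parents: Optional[Mapping[str, Set[str]]] = None,
) -> List[EnrichmentRow]:
    """Per-term Fisher-exact GO over-representation test.

    ``study_genes`` must be a subset of ``background_genes``.  When a
    parent map is supplied, annotations are propagated to ancestor
    terms (the true-path rule) and the "elim" algorithm can exploit the
    hierarchy; without one, every term is treated as a leaf and elim
    reduces to classic.  Rows are sorted by p-value; no
    multiple-testing correction is applied.
    """
    if algorithm not in ("classic", "elim"):
        raise ValueError("algorithm must be 'classic' or 'elim'")
    study = set(study_genes)
    bg = set(background_genes)
    if not study:
        warnings.warn("empty study set: no enrichment computed", stacklevel=2)
        return []
    if not study <= bg:
        raise ValueError("study genes must be a subset of the background")
    parents = parents or {}
    # annotate with true-path propagation
    gene_terms: Dict[str, Set[str]] = {}
    for g in bg:
        terms = set(go_map.get(g, ()))
        full = set(terms)
        for t in terms:
            full |= _ancestors(t, parents)
        gene_terms[g] = full
    term_genes: Dict[str, Set[str]] = {}
    for g, terms in gene_terms.items():
        for t in terms:
            term_genes.setdefault(t, set()).add(g)

    N, n = len(bg), len(study)
    order = _topo_specific_first(set(term_genes), parents)
    eliminated: Dict[str, Set[str]] = {}
    rows: List[EnrichmentRow] = []
    for t in order:
        genes_t = term_genes[t]
        if algorithm == "elim":
            genes_t = genes_t - eliminated.get(t, set())
        K = len(genes_t)
        k = len(genes_t & study)
        if K == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentRow(t, "", k, n, K, N, p))
        if algorithm == "elim" and p < alpha:
            for anc in _ancestors(t, parents):
                eliminated.setdefault(anc, set()).update(term_genes[t])
    rows.sort(key=lambda r: (r.p_value, r.go_id))
    return rows


def tabulate_effects(
    effects: Sequence[VariantEffect], diagnostic_flags: Sequence[bool]
) -> pd.DataFrame:
    """Contingency table of effect categories for the highly divergent
    SNP set and its diagnostic subset (counts and proportions)."""
    if len(effects) != len(diagnostic_flags):
        raise ValueError("effects and diagnostic flags differ in length")
    cats = list(CATEGORIES)
    div = {c: 0 for c in cats}
    dia = {c: 0 for c in cats}
    for e, flag in zip(effects, diagnostic_flags):
        div[e.category] += 1
        if flag:
            dia[e.category] += 1
    n_div = max(sum(div.values()), 1)
    n_dia = max(sum(dia.values()), 1)
    return pd.DataFrame(
        {
            "category": cats,
            "within_gene": [CATEGORIES[c][0] for c in cats],
            "transcribed": [CATEGORIES[c][1] for c in cats],
            "highly_divergent": [div[c] for c in cats],
            "highly_divergent_prop": [div[c] / n_div for c in cats],
            "diagnostic": [dia[c] for c in cats],
            "diagnostic_prop": [dia[c] / n_dia for c in cats],
        }
    )
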