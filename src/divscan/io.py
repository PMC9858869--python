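"""File I/O: VCF -> GenotypeMatrix, FASTA handles, table export."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from cyvcf2 import VCF

from .types import GenotypeMatrix

__all__ = ["read_vcf", "contig_lengths", "write_flanks_fasta"]

_DOSAGE = {0: 0, 1: 1, 2: -1, 3: 2}  # cyvcf2 gt_types -> ALT dosage


def read_vcf(path, require_format: bool = False) -> GenotypeMatrix:
    """Load a (possibly all-sites) VCF into a genotype matrix.

    Multi-allelic records are skipped.  GQ/DP arrays are populated when
    the FORMAT fields are present; ``require_format`` makes their
    absence an error.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, gts, gqs, dps = [], [], [], [], [], [], []
    has_gq = has_dp = True
    for v in vcf:
        if len(v.ALT) > 1:
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else None)
        gts.append([_DOSAGE[int(t)] for t in v.gt_types])
        if has_gq:
            try:
                q = v.format("GQ")
                gqs.append(q.reshape(-1) if q is not None else None)
                has_gq = q is not None
            except KeyError:
                has_gq = False
        if has_dp:
            try:
                d = v.format("DP")
                dps.append(d.reshape(-1) if d is not None else None)
                has_dp = d is not None
            except KeyError:
                has_dp = False
    if require_format and not (has_gq and has_dp):
        raise ValueError("VCF lacks GQ/DP FORMAT fields required for filtering")
    n = len(chroms)
    gm = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        gt=np.array(gts, dtype=np.int8) if n else np.zeros((0, len(samples)), np.int8),
        gq=np.vstack(gqs).astype(np.int16) if has_gq and n else None,
        dp=np.vstack(dps).astype(np.int16) if has_dp and n else None,
    )
    return gm


def contig_lengths(path) -> Dict[str, int]:
    """Chromosome lengths from the VCF header contig lines."""
    vcf = VCF(str(path))
    out = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens):
        out[name] = int(length)
    return out


def write_flanks_fasta(records, path) -> None:
    """Write diagnostic-SNP flank records to FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name} span={rec.chrom}:{rec.start}-{rec.end}\n")
            fh.write(rec.seq + "\n")
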