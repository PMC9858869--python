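"""Fully diagnostic (species-discriminating) SNPs and flank extraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, species_indices

__all__ = ["DiagnosticSite", "find_diagnostic_snps", "extract_flanks", "FlankRecord"]


@dataclass
class DiagnosticSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    orientation: str  # "A_ref" (species A fixed REF, B fixed ALT) or "A_alt"
    call_rate_a: float
    call_rate_b: float


def find_diagnostic_snps(
    gm: GenotypeMatrix,
    popmap: pd.DataFrame,
    min_species_call_rate: float = 0.8,
    allow_missing: bool = True,
    both_orientations: bool = False,
) -> List[DiagnosticSite]:
    """Sites fixed for alternative alleles in the two species.

    The reported orientation is species A (first species in popmap
    order) homozygous REF and species B homozygous ALT in every
    genotyped individual; set ``both_orientations`` to also report the
    mirror.  Fixedness is judged among genotyped calls, guarded by a
    per-species call-rate threshold (``allow_missing=False`` demands
    complete data).  Sites with zero genotyped individuals in either
    species are skipped.
    """
    idx = species_indices(gm, popmap)
    if len(idx) != 2:
        raise ValueError("expected exactly two species in the popmap")
    (sp_a, cols_a), (sp_b, cols_b) = idx.items()
    ga = gm.gt[:, cols_a]
    gb = gm.gt[:, cols_b]
    ca = ga != MISSING
    cb = gb != MISSING
    na = ca.sum(axis=1)
    nb = cb.sum(axis=1)
    rate_a = na / len(cols_a)
    rate_b = nb / len(cols_b)
    if allow_missing:
        guard = (rate_a >= min_species_call_rate) & (rate_b >= min_species_call_rate)
    else:
        guard = (rate_a == 1.0) & (rate_b == 1.0)
    guard &= (na > 0) & (nb > 0) & gm.is_variant()

    fixed_ref_a = np.all(np.where(ca, ga, 0) == 0, axis=1)
    fixed_alt_a = np.all(np.where(ca, ga, 2) == 2, axis=1)
    fixed_ref_b = np.all(np.where(cb, gb, 0) == 0, axis=1)
    fixed_alt_b = np.all(np.where(cb, gb, 2) == 2, axis=1)

    out: List[DiagnosticSite] = []
    for i in np.flatnonzero(guard):
        orientation: Optional[str] = None
        if fixed_ref_a[i] and fixed_alt_b[i]:
            orientation = "A_ref"
        elif both_orientations and fixed_alt_a[i] and fixed_ref_b[i]:
            orientation = "A_alt"
        if orientation:
            out.append(
                DiagnosticSite(
                    chrom=str(gm.chrom[i]),
                    pos=int(gm.pos[i]),
                    ref=str(gm.ref[i]),
                    alt=str(gm.alt[i]),
                    orientation=orientation,
                    call_rate_a=float(rate_a[i]),
                    call_rate_b=float(rate_b[i]),
                )
            )
    return out


@dataclass
class FlankRecord:
    chrom: str
    pos: int  # 1-based focal position
    start: int  # 1-based inclusive extracted span
    end: int
    seq: str
    truncated_left: bool
    truncated_right: bool

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.pos}"


def extract_flanks(
    fasta,
    chrom: str,
    pos: int,
    flank: int = 100,
    expected_ref: Optional[str] = None,
) -> FlankRecord:
    """Extract ``2*flank + 1`` bases centred on ``pos`` (1-based).

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chromosome name
    to indexable sequence).  Spans are truncated at chromosome ends and
    flagged.  If ``expected_ref`` is given, a mismatch with the centre
    base raises ``ValueError`` (reference mismatch).
    """
    seq = fasta[chrom]
    length = len(seq)
    if not 1 <= pos <= length:
        raise ValueError(f"position {pos} outside {chrom} (length {length})")
    start = max(1, pos - flank)
    end = min(length, pos + flank)
    sub = str(seq[start - 1 : end]).upper()
    centre = sub[pos - start]
    if expected_ref is not None and centre != expected_ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: FASTA has {centre}, "
            f"expected {expected_ref}"
        )
    return FlankRecord(
        chrom=chrom,
        pos=pos,
        start=start,
        end=end,
        seq=sub,
        truncated_left=start > pos - flank,
        truncated_right=end < pos + flank,
    )
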