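"""Folded joint site-frequency spectrum with hypergeometric projection.

Sites with missing genotypes are down-projected to fixed haploid
sample sizes ``(n1, n2)``: each site contributes the hypergeometric
probability vector of drawing ``i`` ALT alleles when ``n`` chromosomes
are sampled without replacement from its genotyped chromosomes.  The
unfolded 2-D spectrum is the accumulated outer product of the two
per-deme vectors; folding mirrors cells whose total allele count
exceeds half the projected total (boundary cells are split half and
half between the cell and its mirror, the dadi/easySFS convention).
The monomorphic corners are flagged masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .types import GenotypeMatrix, species_indices

__all__ = [
    "JointSFS",
    "project_site",
    "build_joint_folded_sfs",
    "fold_joint",
    "default_projection",
]


@dataclass
class JointSFS:
    """A (n1+1) x (n2+1) joint spectrum at fixed projection sizes."""

    counts: np.ndarray
    projection: Tuple[int, int]
    folded: bool = True
    masked_corners: bool = True
    n_dropped: int = 0  #: sites unusable at this projection
    #: for model-expected spectra: mean total branch length per locus
    #: genealogy (generations); used to anchor the absolute time/size
    #: scale through the expected SNP count
    mean_total_length: Optional[float] = None

    def __post_init__(self):
        n1, n2 = self.projection
        if self.counts.shape != (n1 + 1, n2 + 1):
            raise ValueError("counts shape does not match projection")

    def mask(self) -> np.ndarray:
        """Boolean mask of *unmasked* (usable) cells."""
        m = np.ones_like(self.counts, dtype=bool)
        if self.masked_corners:
            m[0, 0] = False
            m[-1, -1] = False
        return m

    @property
    def total(self) -> float:
        """Total mass over unmasked cells."""
        return float(self.counts[self.mask()].sum())

    def normalized(self, floor: float = 0.0) -> "JointSFS":
        """Proportions over unmasked cells, optionally flooring zeros."""
        c = self.counts.astype(float).copy()
        m = self.mask()
        c[~m] = 0.0
        if floor > 0:
            c[m] = np.maximum(c[m], floor)
        s = c[m].sum()
        if s <= 0:
            raise ValueError("spectrum has no unmasked mass")
        c[m] /= s
        return JointSFS(
            c,
            self.projection,
            self.folded,
            self.masked_corners,
            self.n_dropped,
            self.mean_total_length,
        )


def project_site(d: int, D: int, n: int) -> np.ndarray:
    """Hypergeometric projection of one site to ``n`` chromosomes.

    ``d`` ALT alleles were observed among ``D`` genotyped chromosomes;
    entry ``i`` of the returned length-``n+1`` vector is the
    probability that a subsample of ``n`` chromosomes carries ``i`` ALT
    alleles.  Signals an unusable site with ``ValueError`` when
    ``n > D``.
    """
    if not 0 <= d <= D:
        raise ValueError(f"need 0 <= d <= D, got d={d}, D={D}")
    if n > D:
        raise ValueError(f"cannot project {D} chromosomes up to {n}")
    return hypergeom.pmf(np.arange(n + 1), D, d, n)


def fold_joint(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded joint spectrum onto minor-allele counts.

    Cell ``(i, j)`` with ``i + j > (n1 + n2) / 2`` is added to its
    mirror ``(n1 - i, n2 - j)``; cells exactly on the boundary keep
    half their (cell + mirror) mass.
    """
    u = np.asarray(unfolded, dtype=float)
    n1 = u.shape[0] - 1
    n2 = u.shape[1] - 1
    tot = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
    mirror = u[::-1, ::-1]
    half = n1 + n2
    folded = np.where(
        2 * tot < half,
        u + mirror,
        np.where(2 * tot == half, (u + mirror) / 2.0, 0.0),
    )
    return folded


def default_projection(gm: GenotypeMatrix, popmap: pd.DataFrame) -> Tuple[int, int]:
    """Projection sizes at which ~80% of sites remain usable per deme."""
    idx = species_indices(gm, popmap)
    out = []
    for sp, cols in idx.items():
        called = (gm.gt[:, cols] != -1).sum(axis=1) * 2
        out.append(int(np.percentile(called, 20)))
    if len(out) != 2:
        raise ValueError("expected exactly two species in the popmap")
    return tuple(out)


def build_joint_folded_sfs(
    gm: GenotypeMatrix,
    popmap: pd.DataFrame,
    projection: Tuple[int, int],
) -> JointSFS:
    """Accumulate the folded joint SFS of a genotype matrix.

    The matrix must not have been MAF-filtered (rare variants carry
    most of the demographic signal); a provenance flag guards this.
    Sites with fewer genotyped chromosomes than the projection in
    either deme are dropped (counted in ``n_dropped``; a warning is
    issued past 50%).
    """
    if gm.maf_filtered:
        raise ValueError("SFS must be built from a non-MAF-filtered matrix")
    idx = species_indices(gm, popmap)
    if len(idx) != 2:
        raise ValueError("expected exactly two species in the popmap")
    (sp1, cols1), (sp2, cols2) = idx.items()
    n1, n2 = projection
    unfolded = np.zeros((n1 + 1, n2 + 1))
    cache: Dict[Tuple[int, int, int], np.ndarray] = {}

    def pvec(d: int, D: int, n: int) -> np.ndarray:
        key = (d, D, n)
        v = cache.get(key)
        if v is None:
            v = project_site(d, D, n)
            cache[key] = v
        return v

    g1 = gm.gt[:, cols1]
    g2 = gm.gt[:, cols2]
    called1 = g1 != -1
    called2 = g2 != -1
    D1 = 2 * called1.sum(axis=1)
    D2 = 2 * called2.sum(axis=1)
    d1 = np.where(called1, g1, 0).sum(axis=1)
    d2 = np.where(called2, g2, 0).sum(axis=1)
    usable = (D1 >= n1) & (D2 >= n2)
    n_dropped = int((~usable).sum())
    for i in np.flatnonzero(usable):
        unfolded += np.outer(
            pvec(int(d1[i]), int(D1[i]), n1), pvec(int(d2[i]), int(D2[i]), n2)
        )
    if gm.n_sites and n_dropped > 0.5 * gm.n_sites:
        warnings.warn(
            f"{n_dropped}/{gm.n_sites} sites dropped at projection {projection}",
            stacklevel=2,
        )
    return JointSFS(
        fold_joint(unfolded),
        projection,
        folded=True,
        masked_corners=True,
        n_dropped=n_dropped,
    )
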