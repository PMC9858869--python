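"""Core in-memory containers: genotype matrix and population map."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_popmap", "species_indices"]

MISSING = -1  #: dosage code for a missing genotype


@dataclass
class GenotypeMatrix:
    """Sites x samples table of diploid ALT-allele dosages.

    ``gt[i, j]`` is 0/1/2 (ALT dosage) or -1 for a missing call.  Site
    metadata is positional and 1-based, matching VCF convention.  Rows
    with ``alt`` equal to ``None``/``"."`` are monomorphic reference
    records from an all-sites file.
    """

    samples: List[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    gq: Optional[np.ndarray] = None
    dp: Optional[np.ndarray] = None
    #: set once a minor-allele-frequency filter has been applied; the
    #: SFS builder refuses such matrices.
    maf_filtered: bool = False

    def __post_init__(self):
        n_sites, n_samples = self.gt.shape
        if len(self.samples) != n_samples:
            raise ValueError("sample list does not match genotype matrix width")
        for name in ("chrom", "pos", "ref", "alt"):
            if len(getattr(self, name)) != n_sites:
                raise ValueError(f"{name} length does not match site count")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gt.shape[1]

    def is_variant(self) -> np.ndarray:
        """Mask of rows that carry an ALT allele definition."""
        return np.array([a not in (None, ".", "") for a in self.alt], dtype=bool)

    def called(self) -> np.ndarray:
        return self.gt != MISSING

    def take_sites(self, idx) -> "GenotypeMatrix":
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[idx],
            gq=None if self.gq is None else self.gq[idx],
            dp=None if self.dp is None else self.dp[idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            gt=self.gt[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            samples=list(self.samples),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            gt=self.gt.copy(),
            gq=None if self.gq is None else self.gq.copy(),
            dp=None if self.dp is None else self.dp.copy(),
        )


def read_popmap(path) -> pd.DataFrame:
    """Read a tab-separated population map.

    Columns: sample, species[, population].  A missing population
    column is filled with the species label.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        df.columns = ["sample", "species"]
        df["population"] = df["species"]
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["sample", "species", "population"]
    else:
        raise ValueError("popmap needs at least two columns: sample, species")
    return df


def species_indices(gm: GenotypeMatrix, popmap: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Column indices of ``gm`` per species, in popmap appearance order.

    Raises if the popmap names samples absent from the matrix.
    """
    col = {s: i for i, s in enumerate(gm.samples)}
    missing = [s for s in popmap["sample"] if s not in col]
    if missing:
        raise KeyError(f"popmap samples absent from genotype data: {missing}")
    out: Dict[str, List[int]] = {}
    for s, sp in zip(popmap["sample"], popmap["species"]):
        out.setdefault(sp, []).append(col[s])
    return {sp: np.array(ix, dtype=np.int64) for sp, ix in out.items()}
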