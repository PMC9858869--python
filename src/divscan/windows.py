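"""Sliding-window divergence landscape: FST, pi, dxy, outliers.

Windows are non-overlapping fixed-width tiles in 1-based inclusive
coordinates.  Per window:

* FST — Weir & Cockerham (1984) variance components accumulated over
  sites as a ratio of sums ``sum(a) / sum(a+b+c)`` (the "weighted"
  windowed estimator); negative values are preserved.
* pi — per-species nucleotide diversity, the sum over variant sites of
  the unbiased heterozygosity ``2 x (n - x) / (n (n - 1))`` divided by
  the window length (variant-only numerator, full-window denominator).
* dxy — absolute divergence from *all-sites* records: differing
  between-deme allele pairs over comparable between-deme pairs, with
  missing genotypes excluded from both numerator and denominator.

Windows with fewer SNPs than ``min_snps`` are kept in the output but
marked unusable for FST-based outlier calling.  Outliers are windows
at or above the empirical ``q``-quantile of FST (linear-interpolation
quantile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import MISSING, GenotypeMatrix, species_indices

__all__ = [
    "WindowStat",
    "site_variance_components",
    "window_fst",
    "window_pi",
    "window_dxy",
    "tile_windows",
    "scan_windows",
    "outlier_windows",
    "spearman",
]

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_snps",
    "fst",
    "pi_a",
    "pi_b",
    "dxy",
    "usable",
    "outlier",
]


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_snps: int
    fst: float
    pi_a: float
    pi_b: float
    dxy: float
    usable: bool = True
    outlier: bool = False


def site_variance_components(
    p1: Tuple[int, int, int], p2: Tuple[int, int, int]
) -> Tuple[float, float, float]:
    """Weir & Cockerham (1984) components for one biallelic site.

    Each deme is summarised as ``(n_ind, alt_allele_count, het_count)``
    over genotyped individuals.  Returns the among-population (a),
    among-individual-within-population (b) and within-individual (c)
    components for r = 2 populations.
    """
    r = 2
    n1, x1, h1c = p1
    n2, x2, h2c = p2
    if n1 < 2 or n2 < 2:
        raise ValueError("each deme needs >= 2 genotyped individuals")
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    pa1 = x1 / (2 * n1)
    pa2 = x2 / (2 * n2)
    p_bar = (n1 * pa1 + n2 * pa2) / (r * n_bar)
    s2 = (n1 * (pa1 - p_bar) ** 2 + n2 * (pa2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (h1c + h2c) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def _site_summaries(
    gt: np.ndarray, cols: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_ind, alt_count, het_count) arrays per site for one deme."""
    sub = gt[:, cols]
    called = sub != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    het = (sub == 1).sum(axis=1)
    return n, alt, het


def window_fst(site_components: Iterable[Tuple[float, float, float]]) -> float:
    """Ratio-of-sums FST over the usable sites of one window."""
    asum = bsum = csum = 0.0
    n = 0
    for a, b, c in site_components:
        asum += a
        bsum += b
        csum += c
        n += 1
    if n == 0:
        raise ValueError("no usable sites in window")
    denom = asum + bsum + csum
    if denom == 0:
        return float("nan")
    return asum / denom


def window_pi(
    x: np.ndarray, n_chrom: np.ndarray, window_len: int
) -> float:
    """Per-bp nucleotide diversity from variant sites of one window.

    ``x`` are ALT chromosome counts and ``n_chrom`` genotyped
    chromosome counts per variant site within the deme.
    """
    if window_len <= 0:
        raise ValueError("window length must be > 0")
    x = np.asarray(x, dtype=float)
    n = np.asarray(n_chrom, dtype=float)
    ok = n >= 2
    contrib = np.zeros_like(x)
    contrib[ok] = 2.0 * x[ok] * (n[ok] - x[ok]) / (n[ok] * (n[ok] - 1.0))
    return float(contrib.sum()) / window_len


def window_dxy(
    d1: np.ndarray, n1: np.ndarray, d2: np.ndarray, n2: np.ndarray
) -> float:
    """pixy-style dxy over the all-sites records of one window.

    Per site with ``d`` ALT among ``n`` genotyped chromosomes per deme,
    the differing between-deme pairs are ``d1 (n2 - d2) + (n1 - d1) d2``
    and the comparable pairs ``n1 n2``; both are summed over sites
    before dividing, so missing data reduces the weight of a site
    rather than biasing it.  Returns NaN when no pairs are comparable.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    diff = d1 * (n2 - d2) + (n1 - d1) * d2
    comp = n1 * n2
    total = comp.sum()
    if total == 0:
        return float("nan")
    return float(diff.sum() / total)


def tile_windows(chrom_length: int, window: int) -> List[Tuple[int, int]]:
    """1-based inclusive non-overlapping tiles covering a chromosome."""
    out = []
    start = 1
    while start <= chrom_length:
        out.append((start, min(start + window - 1, chrom_length)))
        start += window
    return out


def scan_windows(
    variants: GenotypeMatrix,
    allsites: Optional[GenotypeMatrix],
    popmap: pd.DataFrame,
    chrom_lengths: Dict[str, int],
    window: int = 100_000,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Windowed FST/pi/dxy scan over the genome.

    FST and pi come from the (filtered) variant matrix, dxy from the
    all-sites matrix when provided.  Input matrices must be
    position-sorted within chromosomes.  Returns one row per window
    (columns ``WINDOW_COLUMNS``); windows with fewer than ``min_snps``
    SNPs are flagged unusable rather than removed.
    """
    idx = species_indices(variants, popmap)
    if len(idx) != 2:
        raise ValueError("expected exactly two species in the popmap")
    (sp_a, cols_a), (sp_b, cols_b) = idx.items()
    for gm in (variants,) + ((allsites,) if allsites is not None else ()):
        for chrom in np.unique(gm.chrom):
            p = gm.pos[gm.chrom == chrom]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"input not position-sorted on {chrom}")

    na, xa, ha = _site_summaries(variants.gt, cols_a)
    nb, xb, hb = _site_summaries(variants.gt, cols_b)
    if allsites is not None:
        all_idx = species_indices(allsites, popmap)
        aa_n, aa_d, _ = _site_summaries(allsites.gt, all_idx[sp_a])
        ab_n, ab_d, _ = _site_summaries(allsites.gt, all_idx[sp_b])

    rows = []
    for chrom, length in chrom_lengths.items():
        vmask = variants.chrom == chrom
        vpos = variants.pos[vmask]
        vi = np.flatnonzero(vmask)
        if allsites is not None:
            amask = allsites.chrom == chrom
            apos = allsites.pos[amask]
            ai = np.flatnonzero(amask)
        for start, end in tile_windows(length, window):
            sel = vi[(vpos >= start) & (vpos <= end)]
            n_snps = len(sel)
            comps = []
            for i in sel:
                if na[i] >= 2 and nb[i] >= 2:
                    comps.append(
                        site_variance_components(
                            (int(na[i]), int(xa[i]), int(ha[i])),
                            (int(nb[i]), int(xb[i]), int(hb[i])),
                        )
                    )
            fst = window_fst(comps) if comps else float("nan")
            wlen = end - start + 1
            pi_a = window_pi(xa[sel], 2 * na[sel], wlen)
            pi_b = window_pi(xb[sel], 2 * nb[sel], wlen)
            if allsites is not None:
                asel = ai[(apos >= start) & (apos <= end)]
                dxy = window_dxy(
                    aa_d[asel], 2 * aa_n[asel], ab_d[asel], 2 * ab_n[asel]
                )
            else:
                dxy = float("nan")
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": n_snps,
                    "fst": fst,
                    "pi_a": pi_a,
                    "pi_b": pi_b,
                    "dxy": dxy,
                    "usable": n_snps >= min_snps and np.isfinite(fst),
                    "outlier": False,
                }
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def outlier_windows(
    stats_df: pd.DataFrame, q: float = 0.95, min_windows: int = 20
) -> Tuple[float, pd.DataFrame]:
    """Flag usable windows with FST at or above the ``q``-quantile.

    The threshold is the linear-interpolation empirical quantile over
    usable windows; comparison is ``>=``, so under ties all tied
    windows (possibly every window) are flagged.
    """
    usable = stats_df[stats_df["usable"]]
    if len(usable) < min_windows:
        raise ValueError(
            f"need >= {min_windows} usable windows, have {len(usable)}"
        )
    threshold = float(np.quantile(usable["fst"].to_numpy(), q))
    out = stats_df.copy()
    out["outlier"] = out["usable"] & (out["fst"] >= threshold)
    return threshold, out


def spearman(x, y) -> Tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(rho, p)`` using the large-sample t approximation; a
    constant input vector yields NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
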