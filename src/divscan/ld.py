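"""Linkage disequilibrium: pairwise r², Hill–Weir decay, LD matrices.

r² is the squared Pearson correlation of diploid ALT dosages
(0/1/2) over pairwise-complete individuals — the standard unphased
genotype-correlation estimator.  Decay with physical distance is
fitted to the Hill & Weir (1988) drift–recombination expectation

    E[r²] = (10 + C) / ((2 + C)(11 + C))
            * (1 + (3 + C)(12 + 12C + C²) / (n (2 + C)(11 + C)))

with ``C = rho_per_bp * distance`` and ``n`` the chromosome sample
size, after binning pairs by distance to tame heteroskedasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LDDecayFit",
    "pairwise_r2",
    "hill_weir_expectation",
    "fit_ld_decay",
    "ld_matrix",
]


def _r2_single(x: np.ndarray, y: np.ndarray) -> float:
    """r² of two dosage vectors over pairwise-complete entries."""
    ok = (x >= 0) & (y >= 0)
    if ok.sum() < 3:
        return float("nan")
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def pairwise_r2(
    gt: np.ndarray,
    positions: Sequence[int],
    max_dist: Optional[int] = None,
    max_pairs: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[int, int, int, float]]:
    """All within-chromosome site pairs as ``(pos_i, pos_j, dist, r2)``.

    ``gt`` is a sites x individuals dosage matrix (-1 missing) for one
    chromosome, rows matching ``positions``.  Pairs where either site
    is monomorphic among the shared genotyped individuals, or fewer
    than three individuals are shared, get ``r2 = NaN``.  ``max_dist``
    limits pair distance; ``max_pairs`` randomly subsamples the pair
    list (requires ``rng``).
    """
    positions = np.asarray(positions)
    n_sites = gt.shape[0]
    if len(positions) != n_sites:
        raise ValueError("positions do not match matrix rows")
    pairs = [
        (i, j)
        for i in range(n_sites)
        for j in range(i + 1, n_sites)
        if max_dist is None or abs(int(positions[j]) - int(positions[i])) <= max_dist
    ]
    if max_pairs is not None and len(pairs) > max_pairs:
        if rng is None:
            rng = np.random.default_rng(0)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    out = []
    for i, j in pairs:
        dist = abs(int(positions[j]) - int(positions[i]))
        out.append((int(positions[i]), int(positions[j]), dist, _r2_single(gt[i], gt[j])))
    return out


def hill_weir_expectation(C, n: int):
    """Hill & Weir (1988) expected r² at scaled recombination ``C``.

    Monotone decreasing in ``C``; at ``C = 0`` and large ``n`` the
    value approaches 10/22.
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    first = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    second = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C * C)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    out = first * second
    return float(out) if out.ndim == 0 else out


@dataclass
class LDDecayFit:
    rho_per_bp: float  #: fitted recombination scale; C = rho_per_bp * distance
    n: int  #: chromosome count used in the Hill-Weir formula
    background_r2: float
    decay_distance_bp: float  #: where the curve first comes within epsilon of background
    epsilon: float
    sse: float
    n_pairs: int

    def expectation(self, dist):
        return hill_weir_expectation(self.rho_per_bp * np.asarray(dist, float), self.n)


def fit_ld_decay(
    pairs: Sequence[Tuple[int, int, int, float]],
    n: int,
    bin_width: int = 100,
    epsilon: float = 0.005,
    background_quantile: float = 0.9,
    min_pairs: int = 50,
    background_r2: Optional[float] = None,
) -> LDDecayFit:
    """Fit the Hill–Weir decay curve to observed r² pairs.

    Pairs are binned by distance (``bin_width`` bp, means per bin) and
    the curve fitted to bin means by nonlinear least squares over
    ``rho_per_bp >= 0``.  The background r² is the mean among pairs in
    the top distance decile (configurable), or a caller-supplied value
    (``background_r2``) — e.g. the genome-wide background when fitting
    a subset of high-LD regions.  The decay distance is the smallest
    distance where the fitted curve is within ``epsilon`` of the
    background (0 when the curve starts there; capped at the largest
    observed distance when it never gets there).
    """
    data = [(d, r) for _, _, d, r in pairs if np.isfinite(r)]
    if len(data) < min_pairs:
        raise ValueError(f"need >= {min_pairs} finite pairs, have {len(data)}")
    dist = np.array([d for d, _ in data], dtype=float)
    r2 = np.array([r for _, r in data], dtype=float)
    if background_r2 is None:
        far = dist >= np.quantile(dist, background_quantile)
        background = float(r2[far].mean())
    else:
        background = float(background_r2)

    bins = (dist // bin_width).astype(int)
    uniq = np.unique(bins)
    bin_d = np.array([dist[bins == b].mean() for b in uniq])
    bin_r = np.array([r2[bins == b].mean() for b in uniq])

    def resid(log_rho):
        return hill_weir_expectation(np.exp(log_rho[0]) * bin_d, n) - bin_r

    # initial scale: C ~ 1 at the median distance
    x0 = np.array([math.log(max(1.0 / max(np.median(dist), 1.0), 1e-12))])
    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"LD decay fit did not converge: {sol.message}")
    rho = float(np.exp(sol.x[0]))
    sse = float((sol.fun**2).sum())

    # the fitted curve decreases monotonically toward its 1/n floor, so
    # "within epsilon of background" is first reached where the signed
    # excess fit(d) - background drops to epsilon
    max_d = float(dist.max())

    def excess(d):
        return hill_weir_expectation(rho * d, n) - background

    if excess(0.0) <= epsilon:
        decay = 0.0
    elif excess(max_d) > epsilon:
        decay = max_d  # never reaches background within the observed range
    else:
        lo, hi = 0.0, max_d
        for _ in range(100):
            mid = (lo + hi) / 2
            if excess(mid) <= epsilon:
                hi = mid
            else:
                lo = mid
        decay = hi
    return LDDecayFit(
        rho_per_bp=rho,
        n=n,
        background_r2=background,
        decay_distance_bp=decay,
        epsilon=epsilon,
        sse=sse,
        n_pairs=len(data),
    )


def ld_matrix(gt: np.ndarray, positions: Sequence[int]) -> np.ndarray:
    """Full symmetric r² matrix for one chromosome and one deme.

    Rows/columns of sites that are monomorphic (or uncallable) in this
    deme are entirely NaN — the "white line" convention of LD heatmaps.
    The diagonal is 1 for polymorphic sites.
    """
    n_sites = gt.shape[0]
    if len(positions) != n_sites:
        raise ValueError("positions do not match matrix rows")
    mat = np.full((n_sites, n_sites), np.nan)
    poly = np.zeros(n_sites, dtype=bool)
    for i in range(n_sites):
        row = gt[i][gt[i] >= 0]
        poly[i] = row.size >= 3 and row.min() != row.max()
    for i in range(n_sites):
        if not poly[i]:
            continue
        mat[i, i] = 1.0
        for j in range(i + 1, n_sites):
            if poly[j]:
                mat[i, j] = mat[j, i] = _r2_single(gt[i], gt[j])
    return mat
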