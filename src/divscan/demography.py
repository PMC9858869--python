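"""SFS-based demographic inference for the five divergence models.

The expected joint SFS under a parameter set is computed by Monte
Carlo: genealogies are simulated with the structured-coalescent engine
and every branch contributes its length to the unfolded cell indexed
by its descendant counts per deme (branch-length accumulation is the
mutation-rate-free expectation of the SFS, so the mutation rate is not
an estimated parameter).  The spectrum is folded, its monomorphic
corners masked, zero cells floored, and the rest normalised to
proportions.

Model fit is by maximising the multinomial composite log10-likelihood
``sum obs_ij * log10(exp_ij)`` with a derivative-free simplex search in
transformed coordinates (log-scale sizes and split time, logistic
fractions for the inner epoch boundaries, log-scale migration), with
common random numbers across evaluations inside a restart to tame
Monte-Carlo noise.  Models are compared by ``AIC = 2k - 2 ln(10) *
logCL10`` and uncertainty is assessed by parametric bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from random import Random
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._kernels import HAVE_NUMBA, accumulate_cells_fast
from .coalescent import _merge_sequence, branch_cell_lengths
from .models import MODELS, DemographicParams, ModelSpec
from .sfs import JointSFS, fold_joint

__all__ = [
    "SearchConfig",
    "FitResult",
    "expected_sfs",
    "simulate_observed_sfs",
    "composite_log_likelihood",
    "fit_model",
    "compare_models",
    "bootstrap_ci",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class SearchConfig:
    """Optimizer settings.

    ``n_loci`` genealogies per likelihood evaluation; every structured
    start (cascade init, method-of-moments guesses, their time-scale
    ladder) gets a simplex run of ``n_cycles`` cycles, plus the best
    ``n_restarts`` of ``n_screen`` screened random starts.  The search
    bounds are broad defaults: diploid sizes in ``[10, 1e6]``, split
    time in ``[1, 1e7]`` generations, migration in ``[1e-10, 0.5]``.
    """

    n_loci: int = 10_000
    #: random-start simplex runs (structured starts always run)
    n_restarts: int = 2
    n_cycles: int = 40
    #: random points screened for the random restarts
    n_screen: int = 20
    #: genealogies for the final high-precision likelihood evaluation,
    #: which uses a CRN seed derived from the observed SFS so that every
    #: model fitted to the same spectrum is scored on the same stream
    final_n_loci: int = 5000
    size_bounds: Tuple[float, float] = (10.0, 1e6)
    time_bounds: Tuple[float, float] = (1.0, 1e7)
    mig_bounds: Tuple[float, float] = (1e-10, 0.5)
    floor: float = 1e-10


@dataclass
class FitResult:
    model: ModelSpec
    params: DemographicParams
    logCL10: float
    n_restarts: int
    seed: int
    restart_logls: List[float] = field(default_factory=list)
    obs_signature: Optional[tuple] = None

    @property
    def aic(self) -> float:
        return 2.0 * self.model.k - 2.0 * LN10 * self.logCL10


def _accumulate_cells(
    params: DemographicParams,
    model: ModelSpec,
    n1: int,
    n2: int,
    n_loci: int,
    rng: Random,
) -> np.ndarray:
    # flat-list accumulator: this loop dominates fit_model runtime
    n = n1 + n2
    w = n2 + 1
    flat = [0.0] * ((n1 + 1) * w)
    for _ in range(n_loci):
        merges = _merge_sequence(params, model, n1, n2, rng)
        count_a = [1] * n1 + [0] * n2 + [0] * (n - 1)
        count_b = [0] * n1 + [1] * n2 + [0] * (n - 1)
        birth = [0.0] * (2 * n - 1)
        pid = n
        for c1, c2, t in merges:
            flat[count_a[c1] * w + count_b[c1]] += t - birth[c1]
            flat[count_a[c2] * w + count_b[c2]] += t - birth[c2]
            count_a[pid] = count_a[c1] + count_a[c2]
            count_b[pid] = count_b[c1] + count_b[c2]
            birth[pid] = t
            pid += 1
    return np.array(flat).reshape(n1 + 1, w)


def expected_sfs(
    params: DemographicParams,
    model: ModelSpec,
    projection: Tuple[int, int],
    n_loci: int = 10_000,
    rng: Random | int | None = None,
    floor: float = 1e-10,
    engine: str = "auto",
) -> JointSFS:
    """Monte-Carlo expected folded joint SFS (proportions).

    ``engine='auto'`` uses the compiled kernel when numba is available
    and the pure-Python reference engine otherwise; both implement the
    same process (they are cross-checked statistically in the tests)
    but draw different random streams.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    params.validate()
    n1, n2 = projection
    use_fast = engine == "numba" or (engine == "auto" and HAVE_NUMBA)
    if engine == "numba" and not HAVE_NUMBA:
        raise RuntimeError("numba engine requested but numba is unavailable")
    if use_fast:
        if isinstance(rng, Random):
            seed = rng.getrandbits(31)
        elif rng is None:
            seed = Random().getrandbits(31)
        else:
            seed = int(rng)
        cells = accumulate_cells_fast(params, model, n1, n2, n_loci, seed)
    else:
        if not isinstance(rng, Random):
            rng = Random(rng)
        cells = _accumulate_cells(params, model, n1, n2, n_loci, rng)
    if cells.sum() <= 0:
        raise RuntimeError("coalescent simulation produced an all-zero spectrum")
    folded = fold_joint(cells)
    out = JointSFS(
        folded,
        projection,
        folded=True,
        masked_corners=True,
        mean_total_length=float(cells.sum()) / n_loci,
    )
    return out.normalized(floor=floor)


def simulate_observed_sfs(
    params: DemographicParams,
    model: ModelSpec,
    projection: Tuple[int, int],
    n_loci: int,
    theta_per_locus: float,
    rng: Random | int | None = None,
) -> JointSFS:
    """Simulate an observed SFS: Poisson mutations on each locus genealogy.

    ``theta_per_locus`` is in units of mutations per generation of
    branch length times ``4 * n_pma`` — i.e. the classical
    ``4 N mu`` locus-scaled mutation rate with deme A as reference.
    """
    params.validate()
    if not isinstance(rng, Random):
        rng = Random(rng)
    n1, n2 = projection
    mu = theta_per_locus / (4.0 * params.n_pma)
    counts = np.zeros((n1 + 1, n2 + 1))
    nprng = np.random.default_rng(rng.getrandbits(63))
    for _ in range(n_loci):
        merges = _merge_sequence(params, model, n1, n2, rng)
        cells = branch_cell_lengths(merges, n1, n2)
        counts += nprng.poisson(mu * cells)
    folded = fold_joint(counts)
    return JointSFS(folded, projection, folded=True, masked_corners=True)


def composite_log_likelihood(obs: JointSFS, exp: JointSFS) -> float:
    """``sum over unmasked cells of obs * log10(exp)``."""
    if obs.counts.shape != exp.counts.shape:
        raise ValueError("observed and expected spectra have different shapes")
    if obs.masked_corners != exp.masked_corners or obs.folded != exp.folded:
        raise ValueError("observed and expected spectra have different masking")
    m = obs.mask()
    e = exp.counts[m]
    o = obs.counts[m]
    if np.any((e <= 0) & (o > 0)):
        raise ValueError("expected proportions must be positive where obs > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log10(np.where(e > 0, e, 1.0)), 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# parameter transforms: unconstrained simplex coordinates <-> natural units


def _sigmoid(u: float) -> float:
    if u >= 0:
        return 1.0 / (1.0 + math.exp(-u))
    z = math.exp(u)
    return z / (1.0 + z)


def _logit(x: float) -> float:
    x = min(max(x, 1e-12), 1 - 1e-12)
    return math.log(x / (1 - x))


def _to_bounded(u: float, lo: float, hi: float) -> float:
    """Map R -> [lo, hi] on a log scale."""
    return lo * (hi / lo) ** _sigmoid(u)

def _from_bounded(x: float, lo: float, hi: float) -> float:
    x = min(max(x, lo * (1 + 1e-12)), hi * (1 - 1e-12))
    return _logit(math.log(x / lo) / math.log(hi / lo))


def _free_vector_names(model: ModelSpec) -> List[str]:
    names = ["n_anc", "n_pma", "n_pja", "t_split"]
    if "t_contact" in model.free_params:
        names.append("frac_contact")  # t_contact / t_split
    if "t_stop" in model.free_params:
        names.append("frac_stop")  # t_stop / t_contact
    if model.has_migration:
        names += ["m_mj", "m_jm"]
    return names


def _decode(u: np.ndarray, model: ModelSpec, sc: SearchConfig) -> DemographicParams:
    names = _free_vector_names(model)
    vals = dict(zip(names, u))
    n_anc = _to_bounded(vals["n_anc"], *sc.size_bounds)
    n_pma = _to_bounded(vals["n_pma"], *sc.size_bounds)
    n_pja = _to_bounded(vals["n_pja"], *sc.size_bounds)
    t_split = _to_bounded(vals["t_split"], *sc.time_bounds)
    t_contact = t_stop = 0.0
    if "frac_contact" in vals:
        t_contact = t_split * _sigmoid(vals["frac_contact"])
        if "frac_stop" in vals:
            t_stop = t_contact * _sigmoid(vals["frac_stop"])
    m_mj = m_jm = 0.0
    if model.has_migration:
        m_mj = _to_bounded(vals["m_mj"], *sc.mig_bounds)
        m_jm = _to_bounded(vals["m_jm"], *sc.mig_bounds)
    return DemographicParams(
        n_anc, n_pma, n_pja, t_split, t_contact, t_stop, m_mj, m_jm
    )


def _encode(p: DemographicParams, model: ModelSpec, sc: SearchConfig) -> np.ndarray:
    out = [
        _from_bounded(p.n_anc, *sc.size_bounds),
        _from_bounded(p.n_pma, *sc.size_bounds),
        _from_bounded(p.n_pja, *sc.size_bounds),
        _from_bounded(p.t_split, *sc.time_bounds),
    ]
    if "t_contact" in model.free_params:
        out.append(_logit(p.t_contact / p.t_split if p.t_split else 0.5))
        if "t_stop" in model.free_params:
            out.append(_logit(p.t_stop / p.t_contact if p.t_contact else 0.5))
    if model.has_migration:
        out.append(_from_bounded(p.m_mj, *sc.mig_bounds))
        out.append(_from_bounded(p.m_jm, *sc.mig_bounds))
    return np.array(out)


def _anchor_term_log10(S: float, lam: float) -> float:
    """Poisson log10-likelihood (up to a constant) of seeing S SNPs."""
    if lam <= 0:
        return -1e18
    return (S * math.log(lam) - lam) / LN10


def _moment_starts(
    obs: JointSFS, model: ModelSpec, search: SearchConfig, anchor
) -> List[DemographicParams]:
    """Method-of-moments starting points when the scale is anchored.

    The observed SNP count fixes the expected total branch length per
    locus, which under a panmictic coalescent of size N is
    ``4 N H_{n-1}``; that N seeds all three sizes, and split times are
    tried at several multiples of 2N.
    """
    n_loci_data, mu = anchor
    n = sum(obs.projection)
    harmonic = sum(1.0 / i for i in range(1, n))
    length = obs.total / (n_loci_data * mu)
    n0 = max(min(length / (4 * harmonic), search.size_bounds[1]), search.size_bounds[0])
    out = []
    # ratio-2 ladder: some start lands within sqrt(2) of any split
    # time in [N0, 16 N0], close enough for local refinement to bridge
    for t_mult in (0.5, 1.0, 2.0, 4.0, 8.0):
        t = min(max(t_mult * 2 * n0, search.time_bounds[0]), search.time_bounds[1])
        p = DemographicParams(n0, n0, n0, t, 0.1 * t, 0.01 * t)
        if model.has_migration:
            p = p.replace(m_mj=1e-3, m_jm=1e-3)
        out.append(p)
    return out


def _time_ladder(p: DemographicParams, search: SearchConfig) -> List[DemographicParams]:
    """Variants of a start with all epoch times rescaled.

    The likelihood surface carries a narrow diagonal valley trading
    split depth against ancestral size; local searches started at one
    time scale rarely cross it, so every structured start is tried at
    several time scales.
    """
    lo, hi = search.time_bounds
    out = []
    for f in (1.0, 3.5):
        t = min(max(p.t_split * f, lo), hi)
        out.append(
            p.replace(
                t_split=t, t_contact=p.t_contact * (t / p.t_split),
                t_stop=p.t_stop * (t / p.t_split),
            )
        )
    return out


def fit_model(
    obs: JointSFS,
    model: ModelSpec,
    search: SearchConfig = SearchConfig(),
    seed: int = 0,
    init: Optional[DemographicParams] = None,
    anchor: Optional[Tuple[int, float]] = None,
    refine: bool = True,
) -> FitResult:
    """Multi-restart composite-likelihood maximisation of one model.

    A coarse random screen (optionally seeded with ``init`` and, when
    ``anchor`` is given, with method-of-moments guesses) selects
    ``n_restarts`` starting points; each runs a Nelder–Mead simplex for
    ``n_cycles`` cycles (``n_cycles`` times the free-parameter count in
    simplex iterations).  Every likelihood evaluation within a restart
    reuses one RNG seed (common random numbers), so the simplex sees a
    deterministic surface.  The restart with the highest final
    likelihood wins.

    ``anchor = (n_loci_data, mu_per_locus)`` adds a Poisson term for
    the total SNP count with mean ``n_loci * mu * E[total branch
    length]``.  Without it the masked, normalised SFS is invariant
    under a joint rescaling of all sizes and times (with migration
    rates scaled inversely), so only parameter ratios are identifiable.
    """
    if obs.counts.sum() <= 0:
        raise ValueError("observed SFS is empty")
    master = np.random.default_rng(seed)
    d = len(_free_vector_names(model))
    crn_seed = int(master.integers(2**31))
    neg_logl = _neg_logl_factory(obs, model, search, anchor)

    # structured starts (cascade init, moment guesses) each get their
    # own simplex run, at several time scales; random starts are
    # screened and only the best n_restarts of them are run
    structured: List[DemographicParams] = []
    if init is not None:
        # the moment starts already span a time ladder of their own
        structured += _time_ladder(model.constrain(init), search)
    if anchor is not None:
        structured += [model.constrain(p) for p in _moment_starts(obs, model, search, anchor)]
    start_us: List[np.ndarray] = []
    seen = set()
    for q in structured:
        u = _encode(q, model, search)
        key = tuple(np.round(u, 6))
        if key not in seen:
            seen.add(key)
            start_us.append(u)
    randoms = [master.normal(0.0, 1.5, size=d) for _ in range(search.n_screen)]
    randoms = sorted(randoms, key=lambda u: neg_logl(u, search.n_loci, crn_seed))
    start_us += randoms[: search.n_restarts]

    # stage 1: a short simplex from every start to triage basins on
    # the cheap surface; endpoints are then re-ranked with a single
    # high-precision evaluation, because the cheap surface's noise and
    # empty-cell bias systematically favour shallow-split basins
    final_seed_rank = _obs_crn_seed(obs)
    triaged = []
    for u0 in start_us:
        res = minimize(
            neg_logl,
            u0,
            args=(search.n_loci, crn_seed),
            method="Nelder-Mead",
            options={"maxiter": 8 * d, "xatol": 1e-3, "fatol": 1e-3},
        )
        triaged.append(
            (neg_logl(res.x, search.final_n_loci, final_seed_rank), res.x)
        )
    triaged.sort(key=lambda t: t[0])

    # stage 2: fuller simplex from the best basins, still optimising on
    # the cheap surface; the winner between endpoints is chosen on the
    # high-precision stream (one extra evaluation each), which protects
    # against the cheap surface's bias between basins
    best: Optional[Tuple[float, np.ndarray]] = None
    restart_logls: List[float] = []
    for _, u0 in triaged[:2]:
        res = minimize(
            neg_logl,
            u0,
            args=(search.n_loci, crn_seed),
            method="Nelder-Mead",
            options={
                "maxiter": search.n_cycles * d,
                "xatol": 1e-3,
                "fatol": 1e-3,
            },
        )
        score = -neg_logl(res.x, search.final_n_loci, final_seed_rank)
        restart_logls.append(score)
        if best is None or score > best[0]:
            best = (score, res.x)
    if best is None or not math.isfinite(best[0]):
        raise RuntimeError(
            f"no restart converged for model {model.name}; trace: {restart_logls}"
        )

    # stage 3: refine on the high-precision shared CRN stream.  The
    # cheap surface biases the split depth (sparsely filled cells get
    # floored), so the winner is re-optimised at a second point along
    # the time-scale/ancestral-size valley before direction-set and
    # per-coordinate polishing.
    final_seed = _obs_crn_seed(obs)

    def neg_final(u):
        return neg_logl(u, search.final_n_loci, final_seed)

    candidates = [best[1]]
    if refine:
        refined = _refine(
            neg_final, _decode(best[1], model, search), model, search, ladder=True
        )
        candidates.insert(0, refined[1])
    # the untouched init stays a candidate, preserving the nesting
    # guarantee that a richer model scores no worse than the simpler
    # fit that seeded it
    if init is not None:
        candidates.append(_encode(model.constrain(init), model, search))
    scored = [(-neg_final(u), u) for u in candidates]
    final_logl, best_u = max(scored, key=lambda t: t[0])
    return FitResult(
        model=model,
        params=model.constrain(_decode(best_u, model, search)),
        logCL10=final_logl,
        n_restarts=search.n_restarts,
        seed=seed,
        restart_logls=restart_logls,
        obs_signature=(obs.projection, round(float(obs.counts.sum()), 6)),
    )


def _refine(neg_final, p_start: DemographicParams, model: ModelSpec,
            search: SearchConfig, ladder: bool = False):
    """One round of high-precision local refinement from ``p_start``."""
    d = len(_free_vector_names(model))
    starts = [p_start]
    if ladder and "t_split" in model.free_params:
        for f in (2.5,):
            starts.append(
                p_start.replace(
                    t_split=min(
                        max(p_start.t_split * f, search.time_bounds[0]),
                        search.time_bounds[1],
                    ),
                    t_contact=p_start.t_contact * f,
                    t_stop=p_start.t_stop * f,
                    n_anc=min(
                        max(p_start.n_anc * f**-0.7, search.size_bounds[0]),
                        search.size_bounds[1],
                    ),
                )
            )
    refined: Optional[Tuple[float, np.ndarray]] = None
    for p0 in starts:
        u0 = _encode(model.constrain(p0), model, search)
        res = minimize(
            neg_final,
            u0,
            method="Nelder-Mead",
            options={"maxiter": 8 * d, "xatol": 5e-4, "fatol": 1e-4},
        )
        if refined is None or res.fun < refined[0]:
            refined = (res.fun, res.x)
    res = minimize(
        neg_final,
        refined[1],
        method="Powell",
        options={"maxiter": 3, "maxfev": 10 * d, "xtol": 1e-4, "ftol": 1e-5},
    )
    if res.fun < refined[0]:
        refined = (res.fun, res.x)
    # one sweep of per-coordinate line searches: weakly coupled
    # coordinates (recent epoch boundary, minor migration rate) move
    # little under the simplex and benefit from a direct profile
    return _coordinate_polish(neg_final, refined, d)


def refine_fit(
    obs: JointSFS,
    fit: FitResult,
    search: SearchConfig = SearchConfig(),
    anchor: Optional[Tuple[int, float]] = None,
    profile: bool = True,
) -> FitResult:
    """Deep high-precision refinement of an existing fit.

    Runs one round of local refinement (simplex + direction set +
    per-coordinate profiles) on the shared high-precision CRN surface,
    then — because the recent epoch boundary and the minor migration
    rate sit in needle-like likelihood ridges that local moves rarely
    cross — profile-refits those coordinates: each is pinned at several
    multiples of its current value while the remaining parameters are
    re-optimised, and the best profile point is released for a final
    free polish.  Used by :func:`fit_all_models` for the top-ranked
    models.
    """
    model = fit.model
    d = len(_free_vector_names(model))
    names = _free_vector_names(model)
    neg_logl = _neg_logl_factory(obs, model, search, anchor)
    final_seed = _obs_crn_seed(obs)

    def neg_final(u):
        return neg_logl(u, search.final_n_loci, final_seed)

    best = (-fit.logCL10, _encode(fit.params, model, search))
    cand = _refine(
        neg_final, _decode(best[1], model, search), model, search, ladder=True
    )
    if cand[0] < best[0]:
        best = cand

    if profile:
        # the gene-flow stop epoch is handled by the pinning loop below;
        # the minor migration rate gets an explicit two-point profile
        fragile = [n for n in ("m_mj",) if n in names]
        for cname in fragile:
            idx = names.index(cname)
            improved = None
            for shift in (-1.4, 1.4):  # ~ x1/4 and x4 on the natural scale
                u0 = best[1].copy()
                u0[idx] += shift
                fixval = u0[idx]

                def nfix(v):
                    return neg_final(np.insert(v, idx, fixval))

                res = minimize(
                    nfix,
                    np.delete(u0, idx),
                    method="Nelder-Mead",
                    options={"maxiter": 9 * (d - 1), "xatol": 5e-4, "fatol": 1e-4},
                )
                if res.fun < best[0] and (improved is None or res.fun < improved[0]):
                    improved = (res.fun, np.insert(res.x, idx, fixval))
            if improved is not None:
                res = minimize(
                    neg_final,
                    improved[1],
                    method="Nelder-Mead",
                    options={"maxiter": 8 * d, "xatol": 5e-4, "fatol": 1e-4},
                )
                best = min(best, improved, (res.fun, res.x), key=lambda t: t[0])

    if profile and "frac_stop" in names:
        # the recent gene-flow stop is the least-informed coordinate;
        # pin it with a low-noise 1-D profile (4x the genealogies),
        # re-optimise the rest, and iterate once
        from scipy.optimize import minimize_scalar

        idx = names.index("frac_stop")
        u = best[1].copy()
        for sweep in range(2):
            def along(v):
                u2 = u.copy()
                u2[idx] = v
                return neg_logl(u2, 4 * search.final_n_loci, final_seed)

            res1 = minimize_scalar(
                along,
                bounds=(u[idx] - 2.2, u[idx] + 2.2),
                method="bounded",
                options={"maxiter": 12},
            )
            u[idx] = res1.x
            fixval = u[idx]
            # re-optimise the remaining coordinates with the stop epoch
            # pinned; the second sweep uses a lower-noise surface so the
            # joint point can settle into the true basin
            n_reopt = search.final_n_loci if sweep == 0 else 2 * search.final_n_loci

            def nfix(v):
                return neg_logl(np.insert(v, idx, fixval), n_reopt, final_seed)

            res2 = minimize(
                nfix,
                np.delete(u, idx),
                method="Nelder-Mead",
                options={"maxiter": 10 * (d - 1), "xatol": 5e-4, "fatol": 1e-4},
            )
            u = np.insert(res2.x, idx, fixval)
        # judge the pinned candidate against the incumbent on the
        # lower-noise surface; report the standard-stream likelihood
        cand_hi = neg_logl(u, 2 * search.final_n_loci, final_seed)
        best_hi = neg_logl(best[1], 2 * search.final_n_loci, final_seed)
        if cand_hi < best_hi:
            best = (neg_final(u), u)

    if -best[0] <= fit.logCL10:
        return fit
    return FitResult(
        model=model,
        params=model.constrain(_decode(best[1], model, search)),
        logCL10=-best[0],
        n_restarts=fit.n_restarts,
        seed=fit.seed,
        restart_logls=fit.restart_logls,
        obs_signature=fit.obs_signature,
    )


def _neg_logl_factory(obs, model, search, anchor):
    n1, n2 = obs.projection
    S = obs.total

    def neg_logl(u: np.ndarray, n_loci: int, rng_seed: int) -> float:
        try:
            p = _decode(u, model, search).validate()
        except ValueError:
            return 1e18
        exp = expected_sfs(
            p, model, (n1, n2), n_loci, Random(rng_seed), search.floor
        )
        logl = composite_log_likelihood(obs, exp)
        if anchor is not None:
            lam = anchor[0] * anchor[1] * exp.mean_total_length
            logl += _anchor_term_log10(S, lam)
        return -logl

    return neg_logl


def _coordinate_polish(fun, best, d, half_width: float = 2.0):
    """One sweep of bounded 1-D minimisations along each coordinate."""
    from scipy.optimize import minimize_scalar

    f_best, u = best
    u = u.copy()
    for i in range(d):
        lo, hi = u[i] - half_width, u[i] + half_width

        def along(v):
            u2 = u.copy()
            u2[i] = v
            return fun(u2)

        res = minimize_scalar(
            along, bounds=(lo, hi), method="bounded", options={"maxiter": 10}
        )
        if res.fun < f_best:
            f_best = res.fun
            u[i] = res.x
    return f_best, u


def _obs_crn_seed(obs: JointSFS) -> int:
    import zlib

    return zlib.adler32(np.ascontiguousarray(obs.counts).tobytes()) % (2**31)


def fit_all_models(
    obs: JointSFS,
    search: SearchConfig = SearchConfig(),
    seed: int = 0,
    anchor: Optional[Tuple[int, float]] = None,
    models: Optional[Sequence[str]] = None,
) -> Dict[str, FitResult]:
    """Fit the five divergence models with cascading initialisation.

    The models are nested (SI within IM, IM at the epoch boundaries of
    AM/SC, SC within SCS), so each richer model's search is seeded with
    the best simpler fit in addition to its own random and
    method-of-moments starts: SI -> IM -> {AM, SC} -> SCS.
    """
    names = list(models) if models is not None else list(MODELS)
    fits: Dict[str, FitResult] = {}

    def init_for(name: str) -> Optional[DemographicParams]:
        def best_of(*cands):
            done = [fits[c] for c in cands if c in fits]
            return max(done, key=lambda f: f.logCL10).params if done else None

        if name == "IM":
            p = best_of("SI")
            return p.replace(m_mj=1e-4, m_jm=1e-4) if p else None
        if name in ("AM", "SC"):
            p = best_of("IM", "SI")
            if p is None:
                return None
            if p.m_mj == 0:
                p = p.replace(m_mj=1e-4, m_jm=1e-4)
            return p.replace(t_contact=p.t_split / 10)
        if name == "SCS":
            p = best_of("SC", "IM", "SI")
            if p is None:
                return None
            if p.m_mj == 0:
                p = p.replace(m_mj=1e-4, m_jm=1e-4)
            if p.t_contact == 0:
                p = p.replace(t_contact=p.t_split / 10)
            return p.replace(t_stop=p.t_contact / 20)
        return None

    for i, name in enumerate(names):
        fits[name] = fit_model(
            obs,
            MODELS[name],
            search,
            seed=seed + i,
            init=init_for(name),
            anchor=anchor,
            refine=False,
        )
    # the AIC race is decided among the top-ranked models, so only
    # they get the expensive high-precision refinement
    top = sorted(fits, key=lambda n: fits[n].aic)[:2]
    for name in top:
        fits[name] = refine_fit(obs, fits[name], search, anchor=anchor)
    return fits


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fitted models by AIC (ascending); adds a delta-AIC column."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    sigs = {f.obs_signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("fits were computed on different observed spectra")
    rows = [
        {
            "model": f.model.name,
            "k": f.model.k,
            "logCL10": f.logCL10,
            "AIC": f.aic,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(["AIC", "k"], kind="mergesort")
    df["delta_AIC"] = df["AIC"] - df["AIC"].min()
    return df.reset_index(drop=True)


def bootstrap_ci(
    best: FitResult,
    obs_S: int,
    n_boot: int = 100,
    search: SearchConfig = SearchConfig(),
    seed: int = 0,
    exp_n_loci: Optional[int] = None,
    ci: Tuple[float, float] = (2.5, 97.5),
    anchor: Optional[Tuple[int, float]] = None,
    warm_start: bool = True,
    refine: bool = True,
) -> Dict[str, Tuple[float, float]]:
    """Parametric-bootstrap percentile CIs for the best model's parameters.

    Each replicate draws a multinomial SFS of ``obs_S`` sites from the
    fitted model's expected proportions and refits the same model.
    Failed refits are skipped with a warning; more than 20% failures is
    an error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    model = best.model
    exp = expected_sfs(
        best.params,
        model,
        best.obs_signature[0] if best.obs_signature else None,
        exp_n_loci or search.n_loci,
        Random(int(rng.integers(2**31))),
        search.floor,
    )
    m = exp.mask()
    probs = exp.counts[m]
    estimates: Dict[str, List[float]] = {f: [] for f in model.free_params}
    failures = 0
    for b in range(n_boot):
        draw = rng.multinomial(obs_S, probs / probs.sum())
        counts = np.zeros_like(exp.counts)
        counts[m] = draw
        boot_obs = JointSFS(counts, exp.projection, folded=True, masked_corners=True)
        try:
            fit = fit_model(
                boot_obs,
                model,
                search,
                seed=int(rng.integers(2**31)),
                init=best.params if warm_start else None,
                anchor=anchor,
                refine=refine,
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover
            warnings.warn(f"bootstrap replicate {b} failed: {err}", stacklevel=2)
            failures += 1
            continue
        for f in model.free_params:
            estimates[f].append(getattr(fit.params, f))
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap replicates failed")
    # order-statistic percentiles: with two replicates the interval is
    # exactly the min/max of the estimates
    return {
        f: (
            float(np.percentile(v, ci[0], method="lower")),
            float(np.percentile(v, ci[1], method="higher")),
        )
        for f, v in estimates.items()
    }
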