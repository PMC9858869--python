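"""Genotype- and site-level filtering cascade and dataset variants.

The cascade mirrors common RAD-seq practice: (1) mask individual
genotype calls whose quality or depth is at or below a threshold
(strict inequality: the threshold value itself fails); (2) drop sites
genotyped in fewer than a given fraction of individuals, then samples
exceeding a missingness ceiling; (3) optionally drop sites by pooled
minor-allele frequency and/or by exact Hardy–Weinberg tests computed
within each sampled population.

Six standard dataset variants are produced by
:func:`make_dataset_variants`: the main dataset (MAF > 0.05, global
call rate, no HWE filter), per-species call rate, MAF > 0.01, no MAF
filter, and two HWE-filtered sets (violating in all, or in at least
half, of the populations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, species_indices

__all__ = [
    "FilterConfig",
    "mask_low_confidence_genotypes",
    "filter_sites_and_samples",
    "maf_filter",
    "hwe_exact_test",
    "hwe_site_pvalues",
    "make_dataset_variants",
    "EmptyFilterResult",
]


class EmptyFilterResult(ValueError):
    """All sites or all samples were removed by filtering."""


@dataclass(frozen=True)
class FilterConfig:
    min_gq: int = 5
    min_dp: int = 5
    site_call_rate: float = 0.8
    max_sample_missing: float = 0.8
    maf: float = 0.05
    maf_mode: str = "0.05"  # none | 0.01 | 0.05
    hwe_mode: str = "off"  # off | all_pops | half_pops
    hwe_alpha: float = 0.05
    call_rate_scope: str = "global"  # global | per_species

    def __post_init__(self):
        for name in ("site_call_rate", "max_sample_missing", "maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_gq < 0 or self.min_dp < 0:
            raise ValueError("min_gq and min_dp must be >= 0")
        if self.maf_mode not in ("none", "0.01", "0.05"):
            raise ValueError("maf_mode must be none, 0.01 or 0.05")
        if self.hwe_mode not in ("off", "all_pops", "half_pops"):
            raise ValueError("hwe_mode must be off, all_pops or half_pops")
        if self.call_rate_scope not in ("global", "per_species"):
            raise ValueError("call_rate_scope must be global or per_species")


def mask_low_confidence_genotypes(
    gm: GenotypeMatrix, min_gq: int = 5, min_dp: int = 5
) -> GenotypeMatrix:
    """Set calls with GQ <= min_gq or DP <= min_dp to missing.

    The comparison is strict ("greater than" passes), so a call at
    exactly the threshold is masked.
    """
    if gm.gq is None or gm.dp is None:
        missing = [n for n, v in (("GQ", gm.gq), ("DP", gm.dp)) if v is None]
        raise ValueError(f"genotype annotations required but absent: {missing}")
    out = gm.copy()
    bad = (out.gq <= min_gq) | (out.dp <= min_dp)
    out.gt[bad] = MISSING
    return out


def filter_sites_and_samples(
    gm: GenotypeMatrix,
    config: FilterConfig,
    popmap: Optional[pd.DataFrame] = None,
) -> GenotypeMatrix:
    """Call-rate site filter followed by sample-missingness filter.

    Sites first: a site is kept when genotyped in at least
    ``site_call_rate`` of the individuals (globally, or in at least one
    species under ``call_rate_scope='per_species'`` — i.e. a site is
    dropped only when under-genotyped in *both* species).  Then samples
    with missingness strictly above ``max_sample_missing`` are dropped.
    Monomorphic sites are retained here; MAF filtering is a separate
    step.
    """
    called = gm.called()
    if config.call_rate_scope == "per_species":
        if popmap is None:
            raise ValueError("per-species call rate requires a popmap")
        idx = species_indices(gm, popmap)
        keep = np.zeros(gm.n_sites, dtype=bool)
        for cols in idx.values():
            rate = called[:, cols].mean(axis=1)
            keep |= rate >= config.site_call_rate
    else:
        keep = called.mean(axis=1) >= config.site_call_rate
    out = gm.take_sites(keep)
    if out.n_sites == 0:
        raise EmptyFilterResult("all sites removed by the call-rate filter")
    miss = (out.gt == MISSING).mean(axis=0)
    keep_s = miss <= config.max_sample_missing
    if not keep_s.any():
        raise EmptyFilterResult("all samples removed by the missingness filter")
    return out.take_samples(keep_s)


def pooled_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per site over genotyped individuals."""
    called = gm.called()
    n_chrom = 2 * called.sum(axis=1)
    alt = np.where(called, gm.gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), 0.0)
    return np.minimum(p, 1 - p)


def maf_filter(gm: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep sites whose pooled MAF is strictly above ``threshold``."""
    out = gm.take_sites(pooled_maf(gm) > threshold)
    out.maf_filtered = True
    return out


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact Hardy–Weinberg test.

    Conditional on the observed allele counts, the probability of
    ``n_AB`` heterozygotes is
    ``n! 2^{n_AB} / (n_AA! n_AB! n_BB!) / C(2n, n_A)``; the p-value is
    the sum of probabilities of all compatible heterozygote counts no
    more likely than the observed one.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_homalt + n_het  # minor/major irrelevant: test is symmetric
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    # enumerate heterozygote counts with the parity of n_minor
    lgam = math.lgamma
    log_denom = lgam(2 * n + 1) - lgam(n_a + 1) - lgam(2 * n - n_a + 1)

    def logp(nab: int) -> float:
        naa = (n_a - nab) // 2
        nbb = n - naa - nab
        return (
            lgam(n + 1)
            + nab * math.log(2.0)
            - lgam(naa + 1)
            - lgam(nab + 1)
            - lgam(nbb + 1)
            - log_denom
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = {h: logp(h) for h in hets}
    obs = logs[n_het]
    total = 0.0
    for h, lp in logs.items():
        if lp <= obs + 1e-12:
            total += math.exp(lp)
    return min(1.0, total)


def hwe_site_pvalues(gm: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    """Exact HWE p-value per site within one set of individuals."""
    sub = gm.gt[:, cols]
    out = np.ones(gm.n_sites)
    for i in range(gm.n_sites):
        row = sub[i]
        row = row[row != MISSING]
        if row.size == 0:
            continue
        out[i] = hwe_exact_test(
            int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
        )
    return out


def _hwe_violation_fraction(
    gm: GenotypeMatrix, popmap: pd.DataFrame, alpha: float
) -> np.ndarray:
    """Fraction of sampled populations where each site violates HWE."""
    if "population" not in popmap.columns:
        raise ValueError("popmap must carry a population column for HWE filtering")
    col = {s: i for i, s in enumerate(gm.samples)}
    pops: Dict[str, list] = {}
    for s, p in zip(popmap["sample"], popmap["population"]):
        if s in col:
            pops.setdefault(p, []).append(col[s])
    if not pops:
        raise ValueError("no popmap samples present in the genotype matrix")
    viol = np.zeros(gm.n_sites)
    for cols in pops.values():
        pv = hwe_site_pvalues(gm, np.array(cols))
        viol += pv < alpha
    return viol / len(pops)


def make_dataset_variants(
    gm: GenotypeMatrix,
    popmap: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> Dict[str, GenotypeMatrix]:
    """The main filtered dataset plus five alternative variants.

    Input should be the GQ/DP-masked matrix.  Keys:

    - ``main``: global call rate, MAF > 0.05
    - ``per_species_call_rate``: site kept unless under-genotyped in
      both species, MAF > 0.05
    - ``maf01``: MAF > 0.01
    - ``no_maf``: no MAF filter (still call-rate filtered)
    - ``hwe_all_pops``: main + sites violating HWE in every population
      removed
    - ``hwe_half_pops``: main + sites violating in >= half removed
    """
    base = filter_sites_and_samples(gm, config, popmap)
    base_ps = filter_sites_and_samples(
        gm, replace(config, call_rate_scope="per_species"), popmap
    )
    variants = {
        "main": maf_filter(base, 0.05),
        "per_species_call_rate": maf_filter(base_ps, 0.05),
        "maf01": maf_filter(base, 0.01),
        "no_maf": base,
    }
    viol = _hwe_violation_fraction(base, popmap, config.hwe_alpha)
    main = variants["main"]
    # map HWE fractions (computed on `base`) onto the MAF-filtered rows
    key = {
        (c, p): v for c, p, v in zip(base.chrom, base.pos, viol)
    }
    main_viol = np.array([key[(c, p)] for c, p in zip(main.chrom, main.pos)])
    variants["hwe_all_pops"] = main.take_sites(main_viol < 1.0)
    variants["hwe_half_pops"] = main.take_sites(main_viol < 0.5)
    return variants
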