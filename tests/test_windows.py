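"""Windowed FST / pi / dxy estimators against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from divscan import windows
from divscan.types import GenotypeMatrix

from test_filters import make_gm
from test_sfs import two_species_popmap


def wc_oracle(p1, p2):
    """Independent Weir & Cockerham (1984) implementation, written from
    the published alpha/beta/gamma algebra with explicit averages."""
    (n1, x1, h1), (n2, x2, h2) = p1, p2
    r = 2
    p_1, p_2 = x1 / (2 * n1), x2 / (2 * n2)
    hb1, hb2 = h1 / n1, h2 / n2
    nbar = (n1 + n2) / r
    CV2_num = ((n1 - nbar) ** 2 + (n2 - nbar) ** 2) / r
    nc = nbar - CV2_num / nbar  # = nbar(1 - CV^2/...) algebraic identity
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p_1 + n2 * p_2) / (n1 + n2)
    s2 = (n1 * (p_1 - pbar) ** 2 + n2 * (p_2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * hb1 + n2 * hb2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestVarianceComponents:
    def test_fixed_difference_gives_fst_one(self):
        a, b, c = windows.site_variance_components((10, 0, 0), (10, 20, 0))
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_demes_give_nonpositive_ratio(self):
        a, b, c = windows.site_variance_components((8, 8, 4), (8, 8, 4))
        assert a <= 0
        assert a / (a + b + c) <= 0

    def test_small_counts_match_independent_oracle(self):
        got = windows.site_variance_components((4, 2, 2), (4, 6, 2))
        want = wc_oracle((4, 2, 2), (4, 6, 2))
        assert got == pytest.approx(want, abs=1e-12)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 30, size=2)
            x1 = rng.integers(0, 2 * n1 + 1)
            x2 = rng.integers(0, 2 * n2 + 1)
            h1 = rng.integers(0, min(x1, 2 * n1 - x1) + 1)
            h2 = rng.integers(0, min(x2, 2 * n2 - x2) + 1)
            got = windows.site_variance_components(
                (int(n1), int(x1), int(h1)), (int(n2), int(x2), int(h2))
            )
            want = wc_oracle((n1, x1, h1), (n2, x2, h2))
            assert got == pytest.approx(want, abs=1e-10)

    def test_single_individual_deme_rejected(self):
        with pytest.raises(ValueError):
            windows.site_variance_components((1, 0, 0), (5, 2, 2))


class TestWindowFst:
    def test_all_fixed_differences_is_one(self):
        comps = [windows.site_variance_components((5, 0, 0), (5, 10, 0))] * 3
        assert windows.window_fst(comps) == pytest.approx(1.0)

    def test_single_site_equals_per_site_ratio(self):
        comp = windows.site_variance_components((6, 3, 3), (6, 9, 3))
        a, b, c = comp
        assert windows.window_fst([comp]) == pytest.approx(a / (a + b + c))

    def test_three_hand_built_sites_ratio_of_sums(self):
        sites = [((5, 1, 1), (5, 9, 1)), ((5, 5, 3), (5, 5, 3)), ((5, 0, 0), (5, 10, 0))]
        comps = [windows.site_variance_components(p, q) for p, q in sites]
        asum = sum(x[0] for x in comps)
        dsum = sum(sum(x) for x in comps)
        assert windows.window_fst(comps) == pytest.approx(asum / dsum)


class TestWindowPi:
    def test_arithmetic_example(self):
        # one variant with 2 alt among 4 chromosomes in a 100 kb window
        got = windows.window_pi(np.array([2]), np.array([4]), 100_000)
        assert got == pytest.approx(8 / 12 / 1e5)

    def test_monomorphic_window_is_zero(self):
        assert windows.window_pi(np.array([0, 4]), np.array([4, 4]), 1000) == 0.0

    def test_matches_pairwise_difference_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(2, 10)) * 2
            x = rng.integers(0, n + 1, size=6)
            window_len = 1000
            got = windows.window_pi(x, np.full(6, n), window_len)
            # brute force: mean pairwise difference over chromosome pairs
            total = 0.0
            for xi in x:
                alleles = [1] * int(xi) + [0] * (n - int(xi))
                diffs = sum(
                    alleles[i] != alleles[j]
                    for i in range(n)
                    for j in range(i + 1, n)
                )
                total += diffs / (n * (n - 1) / 2)
            assert got == pytest.approx(total / window_len, abs=1e-12)


class TestWindowDxy:
    def test_one_fixed_difference_in_ten_sites(self):
        d1 = np.array([0] * 9 + [2 * 2])  # deme A alt counts (2 diploids)
        d2 = np.array([0] * 10)
        n1 = np.full(10, 4)
        n2 = np.full(10, 4)
        assert windows.window_dxy(d1, n1, d2, n2) == pytest.approx(0.1)

    def test_identical_demes_is_zero(self):
        d = np.array([4, 0, 2])
        n = np.full(3, 4)
        # same allele counts but also identical pairing: dxy counts
        # between-deme differences, which exist unless sites are fixed
        assert windows.window_dxy(
            np.array([0, 4]), np.full(2, 4), np.array([0, 4]), np.full(2, 4)
        ) == 0.0

    def test_matches_brute_force_pair_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = 8
            n1 = rng.integers(2, 7, size=k) * 2
            n2 = rng.integers(2, 7, size=k) * 2
            d1 = np.array([rng.integers(0, n + 1) for n in n1])
            d2 = np.array([rng.integers(0, n + 1) for n in n2])
            got = windows.window_dxy(d1, n1, d2, n2)
            num = den = 0
            for s in range(k):
                a = [1] * int(d1[s]) + [0] * int(n1[s] - d1[s])
                b = [1] * int(d2[s]) + [0] * int(n2[s] - d2[s])
                for x in a:
                    for y in b:
                        num += x != y
                        den += 1
            assert got == pytest.approx(num / den, abs=1e-12)

    def test_ungenotyped_invariant_sites_do_not_change_dxy(self):
        d1, n1 = np.array([2.0]), np.array([4.0])
        d2, n2 = np.array([0.0]), np.array([4.0])
        base = windows.window_dxy(d1, n1, d2, n2)
        with_empty = windows.window_dxy(
            np.array([2.0, 0.0]), np.array([4.0, 0.0]),
            np.array([0.0, 0.0]), np.array([4.0, 0.0]),
        )
        assert with_empty == pytest.approx(base)

    def test_genotyped_invariant_sites_strictly_decrease_dxy(self):
        base = windows.window_dxy(
            np.array([2.0]), np.array([4.0]), np.array([0.0]), np.array([4.0])
        )
        diluted = windows.window_dxy(
            np.array([2.0, 0.0]), np.array([4.0, 4.0]),
            np.array([0.0, 0.0]), np.array([4.0, 4.0]),
        )
        assert diluted < base

    def test_no_comparable_pairs_is_nan(self):
        out = windows.window_dxy(
            np.array([0.0]), np.array([0.0]), np.array([0.0]), np.array([4.0])
        )
        assert np.isnan(out)


class TestScanAndOutliers:
    def test_tiling_convention(self):
        assert windows.tile_windows(250_000, 100_000) == [
            (1, 100_000),
            (100_001, 200_000),
            (200_001, 250_000),
        ]

    def test_type7_quantile_threshold(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(100) * 10 + 1,
                "end": np.arange(100) * 10 + 10,
                "n_snps": 5,
                "fst": np.arange(1.0, 101.0),
                "pi_a": 0.0,
                "pi_b": 0.0,
                "dxy": 0.0,
                "usable": True,
                "outlier": False,
            }
        )
        threshold, out = windows.outlier_windows(df, q=0.95)
        assert threshold == pytest.approx(95.05)
        assert out["outlier"].sum() == 5

    def test_tied_fst_flags_all(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1", "start": 1, "end": 10, "n_snps": 5,
                "fst": np.full(30, 0.25), "pi_a": 0.0, "pi_b": 0.0,
                "dxy": 0.0, "usable": True, "outlier": False,
            }
        )
        threshold, out = windows.outlier_windows(df, q=0.95)
        assert threshold == pytest.approx(0.25)
        assert out["outlier"].all()

    def test_too_few_windows_rejected(self):
        df = pd.DataFrame(
            {"chrom": "c", "start": 1, "end": 2, "n_snps": 5,
             "fst": [0.1] * 5, "pi_a": 0.0, "pi_b": 0.0, "dxy": 0.0,
             "usable": True, "outlier": False}
        )
        with pytest.raises(ValueError):
            windows.outlier_windows(df)

    def test_scan_marks_sparse_windows_unusable(self):
        rng = np.random.default_rng(0)
        gt = rng.integers(0, 3, size=(8, 8)).astype(np.int8)
        gm = make_gm(gt)
        gm.pos = np.array([1, 2, 3, 4, 5, 6, 7, 150])
        pm = two_species_popmap(4, 4)
        df = windows.scan_windows(gm, None, pm, {"chr1": 200}, window=100,
                                  min_snps=5)
        assert len(df) == 2
        assert bool(df.iloc[0]["usable"]) is True
        assert bool(df.iloc[1]["usable"]) is False

    def test_unsorted_input_rejected(self):
        gm = make_gm(np.ones((3, 4), dtype=np.int8))
        gm.pos = np.array([5, 3, 9])
        with pytest.raises(ValueError, match="sorted"):
            windows.scan_windows(gm, None, two_species_popmap(2, 2),
                                 {"chr1": 100})

    def test_unknown_popmap_sample_rejected(self):
        gm = make_gm(np.ones((3, 4), dtype=np.int8))
        pm = two_species_popmap(2, 2)
        pm.loc[0, "sample"] = "ghost"
        with pytest.raises(KeyError, match="ghost"):
            windows.scan_windows(gm, None, pm, {"chr1": 100})


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.arange(10.0)
        assert windows.spearman(x, x**3)[0] == pytest.approx(1.0)
        assert windows.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_case_with_tie(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 2, 3, 5, 4, 6]  # one tie in y
        rho, p = windows.spearman(x, y)
        # manual average ranks: y -> [1.5, 1.5, 3, 5, 4, 6]
        rx = np.array([1, 2, 3, 4, 5, 6], float)
        ry = np.array([1.5, 1.5, 3, 5, 4, 6])
        want = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(want, abs=1e-12)

    def test_constant_vector_warns_nan(self):
        with pytest.warns(UserWarning):
            rho, p = windows.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho)
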