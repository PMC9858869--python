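"""Structured-coalescent engine: distributional checks and invariants."""

import math
from random import Random

import numpy as np
import pytest

from divscan.coalescent import branch_cell_lengths, sample_locus_genealogy
from divscan.demography import expected_sfs
from divscan._kernels import HAVE_NUMBA
from divscan.models import MODELS, DemographicParams, ParameterError


def _si(n=1000.0, t=1e7):
    return DemographicParams(n_anc=n, n_pma=n, n_pja=n, t_split=t)


class TestGenealogyStructure:
    def test_tree_shape_and_lengths(self):
        g = sample_locus_genealogy(_si(), MODELS["SI"], (6, 4), rng=1)
        assert g.n_nodes == 19
        assert len(g.merges) == 9
        assert math.isfinite(g.total_branch_length)
        assert g.total_branch_length > 0
        times = g.node_times()
        assert (np.diff([t for _, _, t in g.merges]) >= 0).all()
        # the root subtends every leaf
        assert g.leaf_sets()[-1] == frozenset(range(10))
        # each parent is older than its children
        par = g.parents()
        for child, parent in enumerate(par[:-1]):
            assert times[parent] > times[child] or child >= g.n_leaves

    def test_cell_lengths_partition_total_length(self):
        g = sample_locus_genealogy(_si(), MODELS["SCS"], (5, 5), rng=7)
        cells = g.cell_lengths()
        assert cells[0, 0] == 0.0
        assert cells.sum() == pytest.approx(g.total_branch_length)

    def test_cell_indices_match_leaf_sets(self):
        g = sample_locus_genealogy(_si(), MODELS["SI"], (4, 3), rng=3)
        cells = branch_cell_lengths(g.merges, 4, 3)
        lens = g.branch_lengths()
        sets = g.leaf_sets()
        manual = np.zeros_like(cells)
        for node in range(g.n_nodes - 1):  # root excluded
            a = sum(1 for x in sets[node] if x < 4)
            b = len(sets[node]) - a
            manual[a, b] += lens[node]
        assert np.allclose(cells, manual)

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            sample_locus_genealogy(
                DemographicParams(500, 500, 500, 10, 100, 0), MODELS["SCS"], (2, 2)
            )
        with pytest.raises(ValueError):
            sample_locus_genealogy(_si(), MODELS["SI"], (1, 0))


class TestCoalescentDistributions:
    def test_within_deme_pairwise_tmrca_is_two_n(self):
        """For n=2 in one deme the expected coalescence time is 2N."""
        n_diploid = 1000.0
        rng = Random(42)
        p = _si(n=n_diploid)
        reps = 10_000
        times = [
            sample_locus_genealogy(p, MODELS["SI"], (2, 0), rng=rng).tmrca
            for _ in range(reps)
        ]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / math.sqrt(reps)
        assert abs(mean - 2 * n_diploid) < 3 * se

    def test_isolation_limit_two_demes_coalesce_internally(self):
        """With a huge split time each deme finds its own MRCA first."""
        p = _si(n=100.0, t=1e9)
        rng = Random(5)
        for _ in range(50):
            g = sample_locus_genealogy(p, MODELS["SI"], (2, 2), rng=rng)
            # the two oldest merges happen only after t_split; the two
            # youngest, within the demes, long before
            t1, t2, t3 = (t for _, _, t in g.merges)
            assert t1 < 1e9 and t2 < 1e9
            assert t3 >= 1e9

    def test_im_with_zero_migration_matches_si(self):
        """IM with m=0 is parameter-degenerate with SI."""
        rng1, rng2 = Random(9), Random(9)
        p_si = _si(n=300.0, t=2000.0)
        p_im = p_si.replace(m_mj=0.0, m_jm=0.0)
        t_si = [
            sample_locus_genealogy(p_si, MODELS["SI"], (3, 3), rng=rng1).tmrca
            for _ in range(2000)
        ]
        t_im = [
            sample_locus_genealogy(p_im, MODELS["IM"], (3, 3), rng=rng2).tmrca
            for _ in range(2000)
        ]
        # identical random streams and identical dynamics: equal draws
        assert t_si == t_im


class TestMsprimeOracle:
    """Cross-check against an independent coalescent simulator."""

    @staticmethod
    def _msprime_branch_sfs(params, model_name, n1, n2, reps, seed):
        msprime = pytest.importorskip("msprime")
        demogr = msprime.Demography()
        demogr.add_population(name="A", initial_size=params.n_pma)
        demogr.add_population(name="B", initial_size=params.n_pja)
        demogr.add_population(name="ANC", initial_size=params.n_anc)
        demogr.add_population_split(
            time=params.t_split, derived=["A", "B"], ancestral="ANC"
        )
        window = MODELS[model_name].migration_window(params)
        if window is not None:
            lo, hi = window
            # backward lineage migration: B -> A at m_mj, A -> B at m_jm
            if lo > 0:
                demogr.add_migration_rate_change(time=lo, rate=params.m_mj,
                                                 source="B", dest="A")
                demogr.add_migration_rate_change(time=lo, rate=params.m_jm,
                                                 source="A", dest="B")
            else:
                demogr.set_migration_rate(source="B", dest="A", rate=params.m_mj)
                demogr.set_migration_rate(source="A", dest="B", rate=params.m_jm)
            demogr.add_migration_rate_change(time=hi, rate=0.0, source="B", dest="A")
            demogr.add_migration_rate_change(time=hi, rate=0.0, source="A", dest="B")
        demogr.sort_events()
        total = np.zeros((n1 + 1, n2 + 1))
        replicates = msprime.sim_ancestry(
            samples={"A": n1 // 2, "B": n2 // 2},
            demography=demogr,
            ploidy=2,
            num_replicates=reps,
            random_seed=seed,
        )
        for ts in replicates:
            sets = [
                ts.samples(population=0).tolist(),
                ts.samples(population=1).tolist(),
            ]
            total += ts.allele_frequency_spectrum(
                sample_sets=sets, mode="branch", polarised=True,
                span_normalise=False,
            )
        return total

    def test_expected_sfs_matches_msprime(self):
        """Branch-length joint SFS under SCS agrees with msprime."""
        from divscan.sfs import fold_joint

        p = DemographicParams(500, 500, 500, 3000, 300, 10, 0.0005, 0.005)
        n1, n2 = 8, 6
        ours = expected_sfs(p, MODELS["SCS"], (n1, n2), 8000, rng=1)
        theirs_unfolded = self._msprime_branch_sfs(p, "SCS", n1, n2, 4000, 7)
        theirs = fold_joint(theirs_unfolded)
        theirs[0, 0] = theirs[-1, -1] = 0.0
        theirs /= theirs.sum()
        tv = 0.5 * np.abs(ours.counts - theirs).sum()
        assert tv < 0.05

    def test_isolation_tmrca_distribution_matches_msprime(self):
        msprime = pytest.importorskip("msprime")
        from random import Random

        p = _si(n=400.0, t=5000.0)
        rng = Random(3)
        ours = [
            sample_locus_genealogy(p, MODELS["SI"], (4, 4), rng=rng).tmrca
            for _ in range(3000)
        ]
        demogr = msprime.Demography()
        demogr.add_population(name="A", initial_size=400)
        demogr.add_population(name="B", initial_size=400)
        demogr.add_population(name="ANC", initial_size=400)
        demogr.add_population_split(time=5000, derived=["A", "B"], ancestral="ANC")
        theirs = [
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples={"A": 2, "B": 2}, demography=demogr, ploidy=2,
                num_replicates=3000, random_seed=11,
            )
        ]
        stat, pval = __import__("scipy.stats", fromlist=["ks_2samp"]).ks_2samp(
            ours, theirs
        )
        assert pval > 0.01


@pytest.mark.skipif(not HAVE_NUMBA, reason="compiled kernel unavailable")
class TestKernelAgreement:
    def test_expected_sfs_engines_agree(self):
        """The compiled kernel and the reference engine sample the same
        process: their folded spectra agree within Monte-Carlo error."""
        p = DemographicParams(500, 500, 500, 3000, 300, 10, 0.0005, 0.005)
        e1 = expected_sfs(p, MODELS["SCS"], (10, 6), 6000, rng=1, engine="numba")
        e2 = expected_sfs(p, MODELS["SCS"], (10, 6), 6000, rng=1, engine="python")
        tv = 0.5 * np.abs(e1.counts - e2.counts).sum()
        assert tv < 0.05

    def test_kernel_deterministic(self):
        p = DemographicParams(500, 500, 500, 3000, 300, 10, 0.0005, 0.005)
        a = expected_sfs(p, MODELS["SCS"], (8, 4), 500, rng=11, engine="numba")
        b = expected_sfs(p, MODELS["SCS"], (8, 4), 500, rng=11, engine="numba")
        assert np.array_equal(a.counts, b.counts)
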