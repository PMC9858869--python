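"""Structured-coalescent engine for two demes with migration epochs.

Genealogies are simulated backward in time under a continuous-time
approximation of the discrete-generation two-deme Wright–Fisher model:
each pair of lineages in a deme of diploid size ``N`` coalesces at rate
``1/(2N)`` per generation, and — while the model's migration window is
open — each lineage in deme B jumps to deme A at rate ``m_mj`` (the
backward reading of a forward migrant proportion A->B) and vice versa.
At the split time all lineages are pooled into the ancestral deme of
size ``n_anc``.

Time is measured in generations; total branch length is therefore in
lineage-generations.

For speed, genealogies are represented as a flat *merge sequence*: the
``i``-th merge event joins two existing lineage ids into node
``n_leaves + i`` at a recorded time.  :class:`Genealogy` wraps that
sequence with tree conveniences (leaf sets, branch lengths, TMRCA),
while :func:`branch_cell_lengths` consumes it directly to accumulate
per-branch descendant-count occupancies for expected-SFS computation
without building any tree objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from random import Random
from typing import List, Sequence, Tuple

import numpy as np

from .models import DemographicParams, ModelSpec, ParameterError

__all__ = ["Genealogy", "sample_locus_genealogy", "branch_cell_lengths"]

_INF = math.inf


def _merge_sequence(
    params: DemographicParams,
    model: ModelSpec,
    n1: int,
    n2: int,
    rng: Random,
    barrier: bool = False,
) -> List[Tuple[int, int, float]]:
    """Simulate one genealogy; return the merge sequence.

    Leaves ``0..n1-1`` are sampled from deme A, ``n1..n1+n2-1`` from
    deme B.  Returns ``n1 + n2 - 1`` tuples ``(child1, child2, time)``;
    the ``i``-th tuple creates internal node ``n1 + n2 + i``.
    """
    p = params
    window = None if barrier else model.migration_window(p)
    if window is not None and window[1] <= window[0]:
        window = None
    demes = [list(range(n1)), list(range(n1, n1 + n2))]
    t = 0.0
    next_id = n1 + n2
    merges: List[Tuple[int, int, float]] = []
    uniform = rng.random
    randrange = rng.randrange
    inv4a = 1.0 / (4.0 * p.n_pma)
    inv4b = 1.0 / (4.0 * p.n_pja)
    inv4anc = 1.0 / (4.0 * p.n_anc)
    t_split = p.t_split
    merged = False

    while len(demes[0]) + len(demes[1]) > 1:
        if not merged and t >= t_split:
            demes[0].extend(demes[1])
            demes[1] = []
            merged = True
        k0 = len(demes[0])
        k1 = len(demes[1])
        if merged:
            rate = k0 * (k0 - 1) * inv4anc
            t += -math.log(1.0 - uniform()) / rate
            i = randrange(k0)
            j = randrange(k0 - 1)
            if j >= i:
                j += 1
            if i < j:
                i, j = j, i  # pop larger index first
            c1 = demes[0].pop(i)
            c2 = demes[0].pop(j)
            demes[0].append(next_id)
            merges.append((c1, c2, t))
            next_id += 1
            continue

        c0 = k0 * (k0 - 1) * inv4a
        c1r = k1 * (k1 - 1) * inv4b
        if window is not None and window[0] <= t < window[1]:
            mig_on = True
            m0 = k0 * p.m_jm  # deme-A lineage traces into B
            m1 = k1 * p.m_mj  # deme-B lineage traces into A
        else:
            mig_on = False
            m0 = m1 = 0.0
        total = c0 + c1r + m0 + m1

        # next epoch boundary ahead of t
        nb = t_split
        if window is not None:
            if t < window[0] < nb:
                nb = window[0]
            elif t < window[1] < nb and window[1] > window[0]:
                nb = window[1]
        if total <= 0.0:
            t = nb
            continue
        dt = -math.log(1.0 - uniform()) / total
        if t + dt >= nb:
            t = nb
            continue
        t += dt
        r = uniform() * total
        if r < c0 or r < c0 + c1r:
            d = 0 if r < c0 else 1
            pool = demes[d]
            k = len(pool)
            i = randrange(k)
            j = randrange(k - 1)
            if j >= i:
                j += 1
            if i < j:
                i, j = j, i
            a = pool.pop(i)
            b = pool.pop(j)
            pool.append(next_id)
            merges.append((a, b, t))
            next_id += 1
        elif r < c0 + c1r + m0:
            pool = demes[0]
            demes[1].append(pool.pop(randrange(len(pool))))
        else:
            pool = demes[1]
            demes[0].append(pool.pop(randrange(len(pool))))
    return merges


def branch_cell_lengths(
    merges: Sequence[Tuple[int, int, float]], n1: int, n2: int
) -> np.ndarray:
    """Accumulate branch lengths by descendant counts per deme.

    Returns an ``(n1+1, n2+1)`` array whose ``(a, b)`` entry is the
    total length (generations) of branches subtending ``a`` deme-A and
    ``b`` deme-B leaves.  A mutation on such a branch yields a derived
    allele at joint count ``(a, b)``, so this array is the unfolded
    joint-SFS expectation up to the mutation rate.  The root carries no
    branch and contributes nothing; cell ``(0, 0)`` is structurally
    empty.
    """
    n = n1 + n2
    n_nodes = 2 * n - 1
    count_a = np.zeros(n_nodes, dtype=np.int64)
    count_b = np.zeros(n_nodes, dtype=np.int64)
    count_a[:n1] = 1
    count_b[n1:n] = 1
    birth = np.zeros(n_nodes)
    cells = np.zeros((n1 + 1, n2 + 1))
    pid = n
    for c1, c2, t in merges:
        cells[count_a[c1], count_b[c1]] += t - birth[c1]
        cells[count_a[c2], count_b[c2]] += t - birth[c2]
        count_a[pid] = count_a[c1] + count_a[c2]
        count_b[pid] = count_b[c1] + count_b[c2]
        birth[pid] = t
        pid += 1
    return cells


@dataclass
class Genealogy:
    """A coalescent tree for ``n1 + n2`` haploid lineages.

    Nodes ``0..n1-1`` are deme-A leaves, ``n1..n1+n2-1`` deme-B leaves,
    and ``n1+n2+i`` the node created by the ``i``-th merge.  The last
    node is the root.
    """

    merges: List[Tuple[int, int, float]]
    n1: int
    n2: int

    @property
    def n_leaves(self) -> int:
        return self.n1 + self.n2

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def tmrca(self) -> float:
        return self.merges[-1][2]

    def node_times(self) -> np.ndarray:
        times = np.zeros(self.n_nodes)
        for i, (_, _, t) in enumerate(self.merges):
            times[self.n_leaves + i] = t
        return times

    def parents(self) -> np.ndarray:
        """Parent node id per node; the root maps to -1."""
        par = np.full(self.n_nodes, -1, dtype=np.int64)
        for i, (c1, c2, _) in enumerate(self.merges):
            par[c1] = par[c2] = self.n_leaves + i
        return par

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (root: 0)."""
        times = self.node_times()
        par = self.parents()
        lens = np.zeros(self.n_nodes)
        has_parent = par >= 0
        lens[has_parent] = times[par[has_parent]] - times[has_parent]
        return lens

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_sets(self) -> List[frozenset]:
        """Set of subtended leaf ids for every node."""
        sets: List[frozenset] = [frozenset((i,)) for i in range(self.n_leaves)]
        for c1, c2, _ in self.merges:
            sets.append(sets[c1] | sets[c2])
        return sets

    def cell_lengths(self) -> np.ndarray:
        return branch_cell_lengths(self.merges, self.n1, self.n2)


def sample_locus_genealogy(
    params: DemographicParams,
    model: ModelSpec,
    deme_sizes: Tuple[int, int],
    barrier: bool = False,
    rng: Random | int | None = None,
) -> Genealogy:
    """Draw one locus genealogy under the structured coalescent.

    Parameters
    ----------
    params
        Demographic parameters; validated (epoch ordering, positive
        sizes, migration proportions in ``[0, 1)``).
    model
        Which migration epochs are active (see :mod:`divscan.models`).
    deme_sizes
        Haploid sample sizes ``(n1, n2)`` drawn from demes A and B.
    barrier
        If true, migration is locally suppressed regardless of the
        model — the genealogy of a barrier locus.
    rng
        A ``random.Random``, an integer seed, or ``None``.
    """
    params.validate()
    n1, n2 = deme_sizes
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages in total")
    if not isinstance(rng, Random):
        rng = Random(rng)
    merges = _merge_sequence(params, model, n1, n2, rng, barrier=barrier)
    return Genealogy(merges, n1, n2)
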