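"""Numba-accelerated structured-coalescent kernel.

Implements the same two-deme competing-risks simulation as
:mod:`divscan.coalescent` (rates ``k(k-1)/(4N)`` per deme, per-lineage
backward migration inside the model's window, pooling into the
ancestral deme at the split) but accumulates branch lengths into
joint-SFS cells directly, without Python objects.  Used by the
demographic-inference likelihood loop, where millions of genealogies
are drawn; the pure-Python engine remains the readable reference and
the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _cells_kernel(
    n1: int,
    n2: int,
    n_anc: float,
    n_pma: float,
    n_pja: float,
    t_split: float,
    mig_lo: float,
    mig_hi: float,
    m_a: float,  # backward migration rate of a deme-A lineage (-> B)
    m_b: float,  # backward migration rate of a deme-B lineage (-> A)
    n_loci: int,
    seed: int,
) -> np.ndarray:
    np.random.seed(seed)
    n = n1 + n2
    cells = np.zeros((n1 + 1) * (n2 + 1))
    w = n2 + 1
    deme0 = np.empty(2 * n, np.int64)
    deme1 = np.empty(2 * n, np.int64)
    count_a = np.empty(2 * n - 1, np.int64)
    count_b = np.empty(2 * n - 1, np.int64)
    birth = np.empty(2 * n - 1)
    inv4a = 1.0 / (4.0 * n_pma)
    inv4b = 1.0 / (4.0 * n_pja)
    inv4anc = 1.0 / (4.0 * n_anc)
    has_window = mig_hi > mig_lo

    for _ in range(n_loci):
        k0 = n1
        k1 = n2
        for i in range(n1):
            deme0[i] = i
        for i in range(n2):
            deme1[i] = n1 + i
        for i in range(n):
            count_a[i] = 1 if i < n1 else 0
            count_b[i] = 0 if i < n1 else 1
            birth[i] = 0.0
        t = 0.0
        next_id = n
        merged = False
        while k0 + k1 > 1:
            if (not merged) and t >= t_split:
                for i in range(k1):
                    deme0[k0 + i] = deme1[i]
                k0 += k1
                k1 = 0
                merged = True
            if merged:
                rate = k0 * (k0 - 1) * inv4anc
                t += -np.log(1.0 - np.random.random()) / rate
                i = np.random.randint(0, k0)
                j = np.random.randint(0, k0 - 1)
                if j >= i:
                    j += 1
                if i > j:
                    i, j = j, i
                c1 = deme0[i]
                c2 = deme0[j]
                # remove i < j, then append the parent node
                deme0[j] = deme0[k0 - 1]
                deme0[i] = deme0[k0 - 2]
                deme0[k0 - 2] = next_id
                k0 -= 1
                cells[count_a[c1] * w + count_b[c1]] += t - birth[c1]
                cells[count_a[c2] * w + count_b[c2]] += t - birth[c2]
                count_a[next_id] = count_a[c1] + count_a[c2]
                count_b[next_id] = count_b[c1] + count_b[c2]
                birth[next_id] = t
                next_id += 1
                continue

            c0r = k0 * (k0 - 1) * inv4a
            c1r = k1 * (k1 - 1) * inv4b
            mig_on = has_window and (mig_lo <= t < mig_hi)
            m0 = k0 * m_a if mig_on else 0.0
            m1 = k1 * m_b if mig_on else 0.0
            total = c0r + c1r + m0 + m1

            nb = t_split
            if has_window:
                if t < mig_lo and mig_lo < nb:
                    nb = mig_lo
                elif t < mig_hi and mig_hi < nb and t >= mig_lo:
                    nb = mig_hi
            if total <= 0.0:
                t = nb
                continue
            dt = -np.log(1.0 - np.random.random()) / total
            if t + dt >= nb:
                t = nb
                continue
            t += dt
            r = np.random.random() * total
            if r < c0r + c1r:
                if r < c0r:
                    pool = deme0
                    k = k0
                else:
                    pool = deme1
                    k = k1
                i = np.random.randint(0, k)
                j = np.random.randint(0, k - 1)
                if j >= i:
                    j += 1
                c1 = pool[i]
                c2 = pool[j]
                # remove i and j, append the parent
                if i > j:
                    i, j = j, i
                pool[j] = pool[k - 1]
                pool[i] = pool[k - 2]
                pool[k - 2] = next_id
                if r < c0r:
                    k0 -= 1
                else:
                    k1 -= 1
                cells[count_a[c1] * w + count_b[c1]] += t - birth[c1]
                cells[count_a[c2] * w + count_b[c2]] += t - birth[c2]
                count_a[next_id] = count_a[c1] + count_a[c2]
                count_b[next_id] = count_b[c1] + count_b[c2]
                birth[next_id] = t
                next_id += 1
            elif r < c0r + c1r + m0:
                i = np.random.randint(0, k0)
                moved = deme0[i]
                deme0[i] = deme0[k0 - 1]
                k0 -= 1
                deme1[k1] = moved
                k1 += 1
            else:
                i = np.random.randint(0, k1)
                moved = deme1[i]
                deme1[i] = deme1[k1 - 1]
                k1 -= 1
                deme0[k0] = moved
                k0 += 1
    return cells.reshape(n1 + 1, w)


def accumulate_cells_fast(params, model, n1, n2, n_loci, seed):
    """Sum of per-branch cell occupancies over ``n_loci`` genealogies."""
    window = model.migration_window(params)
    lo, hi = (0.0, 0.0) if window is None else window
    return _cells_kernel(
        n1,
        n2,
        params.n_anc,
        params.n_pma,
        params.n_pja,
        params.t_split,
        lo,
        hi,
        params.m_jm,
        params.m_mj,
        n_loci,
        seed & 0x7FFFFFFF,
    )
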