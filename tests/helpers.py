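"""Independent oracles and small utilities shared by the test suite."""

from functools import lru_cache
from itertools import combinations

import numpy as np


def brute_dtw(x, y) -> float:
    """Unconstrained DTW by direct recursive dynamic programming.

    Written independently of the package implementation: memoized recursion
    on (i, j) with the three admissible predecessor moves.
    """
    x = tuple(map(float, x))
    y = tuple(map(float, y))

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        d = (x[i] - y[j]) ** 2
        if i == 0 and j == 0:
            return d
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return d + best

    out = rec(len(x) - 1, len(y) - 1)
    rec.cache_clear()
    return out


def mw_exact_two_sided(a, b) -> float:
    """Exact two-sided Mann-Whitney p-value by full enumeration.

    Enumerates all C(n_a + n_b, n_a) group assignments of the pooled sample
    and counts arrangements at least as extreme (on either tail of U) as the
    observed one.  Valid for data without ties.
    """
    pooled = list(a) + list(b)
    na, nb = len(a), len(b)
    mn = na * nb

    def ustat(group_a_vals, group_b_vals):
        return sum(1.0 for u in group_a_vals for v in group_b_vals if u > v)

    u_obs = ustat(a, b)
    lo = min(u_obs, mn - u_obs)
    count = 0
    total = 0
    idx = range(na + nb)
    for comb in combinations(idx, na):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in idx if i not in comb]
        u = ustat(sa, sb)
        if u <= lo or u >= mn - lo:
            count += 1
        total += 1
    return count / total


def true_labels_for(sym_df, truth_df, field: str = "archetype") -> np.ndarray:
    """Ground-truth label of each detected cycle (nearest true t_in)."""
    det = sym_df["t_in_s"].to_numpy()
    tru = truth_df["t_in_s"].to_numpy()
    idx = np.abs(det[:, None] - tru[None, :]).argmin(axis=1)
    return truth_df[field].to_numpy()[idx]


def combined_symbols(sym_df) -> np.ndarray:
    return (sym_df["insp_symbol"].astype(str) + sym_df["exp_symbol"].astype(str)).to_numpy()
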