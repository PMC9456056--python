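"""Shared rank-sum testing machinery.

Two-sided Wilcoxon/Mann-Whitney p-values with an exact small-sample path:
when both groups have at most 8 observations the two-sided p-value is
computed by exhaustive enumeration of all C(n1+n2, n1) assignments of the
pooled (midrank-tied) ranks, which is tie-safe; larger groups use the
tie-corrected normal approximation with continuity correction via scipy.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 8


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumeration of all rank splits.

    Handles ties through midranks.  p = 2 * min(P(W <= w), P(W >= w)),
    capped at 1, where W is the group-1 rank sum under the permutation null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    idx = range(n1 + n2)
    total = lo = hi = 0
    for comb in combinations(idx, n1):
        w = ranks[list(comb)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            lo += 1
        if w >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def ranksum_p(x, y) -> tuple[float, float]:
    """(statistic U, two-sided p); exact when both groups are small."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    u = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return u, exact_ranksum_p(x, y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return u, 1.0
    p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return u, p


def ranksum_p_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values for matrices a (n1 x g), b (n2 x g)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[0], b.shape[0]
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return np.array([exact_ranksum_p(a[:, j], b[:, j]) for j in range(a.shape[1])])
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    # constant columns have undefined asymptotic p; by convention p = 1
    const = np.ptp(np.vstack([a, b]), axis=0) == 0
    p[const] = 1.0
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
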