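"""Rank tests for paired and two-sample density comparisons.

Implemented from first principles so the exact small-sample null
distributions are available: the Wilcoxon signed-rank test enumerates the
sign-flip null (via a dynamic-programming convolution over the observed
mid-ranks, equivalent to summing over all 2^n signings) for up to 25
non-zero pairs, and the Mann-Whitney U test enumerates all group labelings
for pooled sample sizes up to 12.  Larger samples use the tie-corrected
normal approximation with continuity correction.  Two-sided p-values are
twice the smaller tail mass, capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["RankTestResult", "wilcoxon_signed_rank", "mann_whitney_u"]

_WILCOXON_EXACT_MAX = 25   # max non-zero pairs for exact signed-rank null
_MWU_EXACT_MAX = 12        # max pooled size for exact Mann-Whitney null


@dataclass
class RankTestResult:
    statistic: float
    p: float
    n: int
    method: str            # "exact" | "normal" | "degenerate"
    degenerate: bool = False


def wilcoxon_signed_rank(a, b=None) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties among absolute differences are
    mid-ranked.  The statistic is W+, the sum of ranks of positive
    differences.  If every difference is zero the result is degenerate
    with p = 1.
    """
    a = np.asarray(a, dtype=float)
    if b is not None:
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
    else:
        d = a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return RankTestResult(statistic=0.0, p=1.0, n=0,
                              method="degenerate", degenerate=True)

    ranks = rankdata(np.abs(d))          # mid-ranks, multiples of 0.5
    w_plus = float(ranks[d > 0].sum())

    if n <= _WILCOXON_EXACT_MAX:
        p = _signed_rank_exact_p(ranks, w_plus)
        return RankTestResult(statistic=w_plus, p=p, n=n, method="exact")

    mu = n * (n + 1) / 4.0
    # Tie correction on the variance of W+ under random sign flips.
    sigma2 = float(np.sum(ranks**2)) / 4.0
    if sigma2 == 0:
        return RankTestResult(statistic=w_plus, p=1.0, n=n,
                              method="degenerate", degenerate=True)
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return RankTestResult(statistic=w_plus, p=p, n=n, method="normal")


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p under the sign-flip null.

    Ranks are mid-ranks on a half-integer grid; doubling them gives
    integers, so the null distribution of 2·W+ is a convolution of
    two-point distributions {0, 2r_i} computed by DP over all 2^n signings.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    upper = 0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:upper + r + 1] = counts[0:upper + 1]
        counts = counts + shifted
        upper += r
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    lower_tail = counts[: w2 + 1].sum()
    upper_tail = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower_tail, upper_tail)))


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    The statistic is U of the first sample.  Exact null by enumeration of
    all labelings when the pooled size is at most 12; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    n_total = nx + ny

    if n_total <= _MWU_EXACT_MAX:
        p = _mwu_exact_p(ranks, nx, u_x)
        return RankTestResult(statistic=u_x, p=p, n=n_total, method="exact")

    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = (nx * ny / 12.0) * (
        (n_total + 1) - tie_term / (n_total * (n_total - 1))
    )
    if sigma2 <= 0:
        return RankTestResult(statistic=u_x, p=1.0, n=n_total,
                              method="degenerate", degenerate=True)
    diff = u_x - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return RankTestResult(statistic=u_x, p=p, n=n_total, method="normal")


def _mwu_exact_p(ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all C(n, nx) group labelings."""
    n = ranks.size
    offset = nx * (nx + 1) / 2.0
    us = np.array([
        sum(ranks[i] for i in idx) - offset
        for idx in combinations(range(n), nx)
    ])
    m = us.size
    eps = 1e-9
    lower = np.count_nonzero(us <= u_obs + eps) / m
    upper = np.count_nonzero(us >= u_obs - eps) / m
    return float(min(1.0, 2.0 * min(lower, upper)))
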