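"""Rank-based tests and multiple-testing adjustments used across the pipeline.

The Wilcoxon rank-sum (Mann-Whitney) test here has two code paths: an exact
path that enumerates every assignment of the pooled observations to the two
groups (valid with ties, feasible for group sizes up to ~8), and the usual
tie-corrected normal approximation for larger groups.  The paired signed-rank
variant enumerates sign flips in its exact path.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankTestResult",
    "rank_sum_test",
    "signed_rank_test",
    "holm_adjust",
    "bh_adjust",
]

EXACT_MAX_N = 8


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # Mann-Whitney U of the first group (or signed-rank W+)
    pvalue: float
    method: str


def _mwu_from_ranks(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    ``method`` is ``"exact"`` (full enumeration of the C(n1+n2, n1) group
    assignments of the pooled values; handles ties), ``"asymptotic"``
    (tie-corrected normal approximation with continuity correction, via
    scipy), or ``"auto"`` (exact when both groups have <= 8 observations).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if max(n1, n2) <= EXACT_MAX_N else "asymptotic"
    if method == "asymptotic":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _mwu_from_ranks(ranks, n1)
    mu = n1 * n2 / 2.0
    # the permutation distribution of U is symmetric about n1*n2/2, so the
    # two-sided p is the fraction of assignments at least as far from the mean
    dev_obs = abs(u_obs - mu)
    n = n1 + n2
    count = 0
    total = 0
    idx = np.arange(n)
    for subset in combinations(idx, n1):
        r = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
        if abs(r - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return RankTestResult(u_obs, count / total, "exact")


def signed_rank_test(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> RankTestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Exact path enumerates all 2^n sign assignments of the non-zero paired
    differences (valid with tied magnitudes); otherwise the tie-corrected
    normal approximation from scipy is used.  Zero differences are dropped
    (the classic Wilcoxon convention).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return RankTestResult(0.0, 1.0, "degenerate")
    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "asymptotic"
    if method == "asymptotic":
        res = sps.wilcoxon(d, alternative="two-sided", method="approx")
        return RankTestResult(float(res.statistic), float(res.pvalue), "asymptotic")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    ranks = sps.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    for mask in range(2**n):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
    return RankTestResult(w_obs, count / 2**n, "exact")


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down family-wise adjustment."""
    p = np.asarray(pvalues, float)
    return multipletests(p, method="holm")[1] if p.size else p.copy()


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg false-discovery-rate adjustment."""
    p = np.asarray(pvalues, float)
    return multipletests(p, method="fdr_bh")[1] if p.size else p.copy()
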