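"""Small-sample rank statistics.

The exact two-sided Wilcoxon rank-sum (Mann-Whitney) test enumerates the
null distribution of U, so p-values on small tie-free cohorts are exact
rationals on the enumeration lattice rather than normal approximations.
Ties or large samples fall back to the tie-corrected normal approximation
with continuity correction; the :class:`~airwaycomp.types.TestResult`
``method`` flag records which path ran.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import TestResult

__all__ = ["wilcoxon_exact", "benjamini_hochberg", "exact_u_null_counts"]

#: default cap on n1+n2 for the exact enumeration path
EXACT_CAP = 30


@lru_cache(maxsize=64)
def exact_u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments yielding each U value, for tie-free data.

    Uses the recurrence f(a, b; u) = f(a-1, b; u-b) + f(a, b-1; u): the
    largest rank goes either to group 1 (adding b to U) or to group 2.
    Entry ``u`` of the result counts the C(n1+n2, n1) label assignments with
    Mann-Whitney U equal to ``u``; counts are exact in float64 for
    n1 + n2 <= 30.
    """
    dp = [np.array([1.0]) for _ in range(n1 + 1)]
    for b in range(1, n2 + 1):
        new = [np.array([1.0])]
        for a in range(1, n1 + 1):
            arr = np.zeros(a * b + 1)
            arr[b:] += new[a - 1]
            prev = dp[a]
            arr[: len(prev)] += prev
            new.append(arr)
        dp = new
    return dp[n1]


def _exact_two_sided_p(u: int, n1: int, n2: int) -> float:
    counts = exact_u_null_counts(n1, n2)
    total = counts.sum()
    cdf = counts[: u + 1].sum() / total
    sf = counts[u:].sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_exact(x, y, exact_cap: int = EXACT_CAP) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with an exact small-sample path.

    Parameters
    ----------
    x, y
        The two groups of observations (non-empty 1-d sequences).
    exact_cap
        Exact enumeration of the U null distribution is used when the data
        are tie-free and ``len(x) + len(y) <= exact_cap``; otherwise the
        tie-corrected normal approximation with continuity correction.

    Returns
    -------
    TestResult
        ``statistic`` is the Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be one-dimensional")
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and (n1 + n2) <= exact_cap:
        p = _exact_two_sided_p(int(round(u1)), n1, n2)
        # the minimum attainable two-sided p is 2/C(n1+n2, n1) > 0
        return TestResult(float(u1), p, "exact", n1, n2)

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        # all observations identical: no evidence either way
        return TestResult(float(u1), 1.0, "tie_corrected_normal", n1, n2)
    dev = abs(u1 - mu) - 0.5  # continuity correction
    if dev <= 0:
        p = 1.0
    else:
        p = min(1.0, 2.0 * sps.norm.sf(dev / np.sqrt(var)))
    p = max(p, np.finfo(float).tiny)
    return TestResult(float(u1), p, "tie_corrected_normal", n1, n2)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; values must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
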