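"""Exact rank-based hypothesis tests.

Electrophysiology comparisons in this toolkit involve small cell counts
(n of 7-11), where asymptotic rank tests are unreliable.  Both tests here
compute the exact permutation null whenever the combined sample size is at
most ``EXACT_LIMIT``, handling ties by midranks:

* Mann-Whitney U: the null distribution of the rank sum over all
  ``C(n1+n2, n1)`` group assignments is obtained by dynamic-programming
  subset counting over the pooled (mid)ranks — no explicit enumeration.
* Wilcoxon signed-rank: the null distribution of the positive-rank sum W
  over all 2^m sign patterns, again by subset-sum counting.

Above the exact limit a normal approximation with tie correction is used.
Two-sided p-values double the smaller tail and are capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = ["RankTestResult", "mann_whitney_exact", "wilcoxon_signed_exact", "exact_rank_tests"]

EXACT_LIMIT = 25


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal"


def _two_sided(p_le: float, p_ge: float) -> float:
    return min(1.0, 2.0 * min(p_le, p_ge))


def _subset_sum_counts(values: np.ndarray, k: int) -> dict[int, int]:
    """Number of size-k subsets of ``values`` (integers) by subset sum."""
    # dp[j] maps sum -> count for subsets of size j
    dp: list[dict[int, int]] = [{0: 1}] + [dict() for _ in range(k)]
    for v in values:
        v = int(v)
        for j in range(min(k, len(dp) - 1), 0, -1):
            src = dp[j - 1]
            dst = dp[j]
            for s, c in src.items():
                dst[s + v] = dst.get(s + v, 0) + c
    return dp[k]


def mann_whitney_exact(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test; exact for combined n <= 25.

    The statistic reported is U for the first sample.  Ties receive
    midranks; the exact null conditions on the observed (tied) rank multiset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if n1 + n2 <= EXACT_LIMIT:
        # doubled ranks are integers even with midranks
        ranks2 = np.rint(ranks * 2).astype(int)
        counts = _subset_sum_counts(ranks2, n1)
        total = sum(counts.values())
        r1_2 = int(round(r1 * 2))
        p_le = sum(c for s, c in counts.items() if s <= r1_2) / total
        p_ge = sum(c for s, c in counts.items() if s >= r1_2) / total
        return RankTestResult(float(u), _two_sided(p_le, p_ge), "exact")

    # normal approximation with tie correction and continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise ValueError("degenerate pooled sample: all values tied")
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return RankTestResult(float(u), min(1.0, p), "normal")


def wilcoxon_signed_exact(x, y=None) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test; exact for n <= 25 pairs.

    ``y`` may be omitted to test differences (or a single sample) against
    zero.  Zero differences are discarded; if all differences are zero the
    test is degenerate and an error is raised.  The statistic is W+, the sum
    of ranks of the positive differences.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: signed-rank test degenerate")
    m = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if m <= EXACT_LIMIT:
        ranks2 = np.rint(ranks * 2).astype(int)
        # distribution of W+ over all 2^m sign vectors
        counts: dict[int, int] = {0: 1}
        for r in ranks2:
            nxt: dict[int, int] = {}
            for s, c in counts.items():
                nxt[s] = nxt.get(s, 0) + c
                nxt[s + int(r)] = nxt.get(s + int(r), 0) + c
            counts = nxt
        total = 2**m
        w2 = int(round(w_plus * 2))
        p_le = sum(c for s, c in counts.items() if s <= w2) / total
        p_ge = sum(c for s, c in counts.items() if s >= w2) / total
        return RankTestResult(w_plus, _two_sided(p_le, p_ge), "exact")

    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        raise ValueError("degenerate differences: all magnitudes tied to zero variance")
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return RankTestResult(w_plus, min(1.0, p), "normal")


def exact_rank_tests(x, y, kind: str = "mann_whitney") -> RankTestResult:
    """Dispatch to :func:`mann_whitney_exact` or :func:`wilcoxon_signed_exact`."""
    if kind == "mann_whitney":
        return mann_whitney_exact(x, y)
    if kind == "wilcoxon_signed":
        return wilcoxon_signed_exact(x, y)
    raise ValueError(f"unknown test kind: {kind!r}")
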