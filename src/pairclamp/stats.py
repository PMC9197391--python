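"""Exact small-sample nonparametric tests and group summaries.

Both tests compute exact two-sided p-values by enumerating the permutation
null for small samples (via subset-sum dynamic programming over mid-rank
values, which is equivalent to full enumeration) and fall back on the
tie-corrected normal approximation for larger samples.  Group data are
summarized as median +/- SEM (SEM = sd/sqrt(n), mean-based, as commonly
printed alongside medians in electrophysiology reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "GroupComparison",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "summarize_group",
    "compare_groups",
]

WILCOXON_EXACT_MAX_N = 25
MANNWHITNEY_EXACT_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str  # "exact" or "normal_approx"
    diagnostic: Optional[str] = None


@dataclass(frozen=True)
class GroupComparison:
    """Before/after (paired) or between-group summary with test verdict."""

    labels: tuple[str, str]
    medians: tuple[float, float]
    sems: tuple[float, float]
    ns: tuple[int, int]
    test: str  # "wilcoxon_signed_rank" or "mann_whitney"
    p_value: float
    paired: bool


def _scaled_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks doubled to integers (half-ranks arise only with ties)."""
    r = 2.0 * rankdata(values)
    ri = np.rint(r).astype(np.int64)
    assert np.allclose(r, ri), "scaled mid-ranks must be integral"
    return ri


def _two_sided_p(cdf: np.ndarray, pmf: np.ndarray, stat: int) -> float:
    lo = cdf[stat]
    hi = 1.0 - cdf[stat] + pmf[stat]
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(diffs: Sequence[float]) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (the classical convention).  For n <= 25
    the p-value is exact over all 2**n sign assignments (computed by
    convolution over signed mid-ranks, which handles ties in |d| exactly);
    above that a tie-corrected normal approximation with continuity
    correction is used.  All differences zero returns p = 1 with a
    diagnostic.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult(0.0, 1.0, 0, "exact", "all differences zero")
    n = d.size
    ranks2 = _scaled_ranks(np.abs(d))  # 2 * midranks, integers
    w2 = int(ranks2[d > 0].sum())  # 2 * W+
    if n <= WILCOXON_EXACT_MAX_N:
        total = int(ranks2.sum())
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for r in ranks2:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: total + 1 - r]
            pmf = 0.5 * (pmf + shifted)
        cdf = np.cumsum(pmf)
        p = _two_sided_p(cdf, pmf, w2)
        return TestResult(w2 / 2.0, p, n, "exact")
    # Normal approximation with tie correction.
    mu = ranks2.sum() / 2.0 / 2.0  # E[W+] = sum(ranks)/2, ranks = ranks2/2
    var = float(np.sum((ranks2 / 2.0) ** 2)) / 4.0
    w = w2 / 2.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * _norm_sf(abs(z))))
    return TestResult(w, p, n, "normal_approx")


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Exact two-sided Mann-Whitney (rank-sum) test.

    For n_a + n_b <= 20 the p-value is exact over all C(n, n_a) group
    assignments (dynamic programming over pooled mid-ranks; ties handled
    exactly as a permutation test).  Larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks2 = _scaled_ranks(pooled)
    wa2 = int(ranks2[:na].sum())  # 2 * rank-sum of group a
    if n <= MANNWHITNEY_EXACT_MAX_N:
        total = int(ranks2.sum())
        # counts[c, s] = number of c-subsets of pooled scaled ranks summing to s
        counts = np.zeros((na + 1, total + 1))
        counts[0, 0] = 1.0
        for r in ranks2:
            cmax = na
            for c in range(cmax, 0, -1):
                counts[c, r:] += counts[c - 1, : total + 1 - r]
        dist = counts[na]
        dist /= dist.sum()
        cdf = np.cumsum(dist)
        p = _two_sided_p(cdf, dist, wa2)
        return TestResult(wa2 / 2.0, p, n, "exact")
    ranks = ranks2 / 2.0
    wa = wa2 / 2.0
    mu = na * (n + 1) / 2.0
    # Tie-corrected variance of the rank sum.
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    z = (wa - mu - 0.5 * np.sign(wa - mu)) / math.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * _norm_sf(abs(z))))
    return TestResult(wa, p, n, "normal_approx")


def summarize_group(values: Sequence[float]) -> tuple[float, float, int]:
    """Return (median, SEM, n) with SEM = sd/sqrt(n); n = 1 gives SEM 0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    if v.size == 1:
        return float(v[0]), 0.0, 1
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size))
    return float(np.median(v)), sem, int(v.size)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    paired: bool = False,
) -> GroupComparison:
    """Summarize two groups and test them (paired Wilcoxon or Mann-Whitney)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    med_a, sem_a, na = summarize_group(a)
    med_b, sem_b, nb = summarize_group(b)
    if paired:
        if na != nb:
            raise ValueError("paired comparison requires equal group sizes")
        res = wilcoxon_signed_rank(b - a)
        test = "wilcoxon_signed_rank"
    else:
        res = mann_whitney(a, b)
        test = "mann_whitney"
    return GroupComparison(
        labels=labels,
        medians=(med_a, med_b),
        sems=(sem_a, sem_b),
        ns=(na, nb),
        test=test,
        p_value=res.p_value,
        paired=paired,
    )
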