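"""Configuration-comparison statistics: summaries and exact nonparametric tests.

The signed-rank and rank-sum tests are implemented by explicit enumeration
of the permutation null for small samples (sign assignments over nonzero
differences; rank-sum over all group assignments), with a normal
approximation (tie-corrected) for larger rank-sum samples. Two-sided
p-values follow the doubling convention: twice the smaller tail, capped at
1. Zero differences are dropped before signed-ranking; ties receive
mid-ranks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata

MOTION_METRICS = (
    "completion_percentage",
    "selection_time_s",
    "realtime_accuracy",
    "completion_time_s",
    "offline_accuracy",
)


@dataclass
class ComparisonResult:
    metric: str
    test_type: str  # "signed_rank" | "rank_sum"
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    significant: bool

    @classmethod
    def build(cls, metric: str, test_type: str, p_raw: float, m: int,
              alpha: float = 0.05) -> "ComparisonResult":
        p_adj = min(1.0, m * p_raw)
        return cls(metric=metric, test_type=test_type, p_raw=p_raw,
                   p_adjusted=p_adj, m_comparisons=m, significant=p_adj < alpha)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean and standard error (sample SD / sqrt(n), ddof=1).

    With a single row the SE is undefined and reported as NaN.
    """
    if len(table) == 0:
        raise ValueError("need at least one row")
    mean = table.mean(axis=0)
    if len(table) > 1:
        se = table.std(axis=0, ddof=1) / np.sqrt(len(table))
    else:
        se = pd.Series(np.nan, index=table.columns)
    return pd.DataFrame({"mean": mean, "se": se})


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = rankdata(np.abs(diffs))  # mid-ranks on ties
    w_pos = float(np.sum(ranks[diffs > 0]))
    return w_pos, ranks


def wilcoxon_signed_rank(a, b) -> float:
    """Exact two-sided signed-rank p for paired samples.

    Zero differences are dropped; the null is enumerated over all 2^n sign
    assignments of the remaining absolute-difference ranks. Returns
    2 * min(P(W+ <= w), P(W+ >= w)) capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("paired samples must have equal length >= 1")
    diffs = a - b
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if n > 25:
        return _signed_rank_normal(diffs)
    w_obs, ranks = _signed_rank_statistic(diffs)
    total = 2**n
    n_le = n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs + 1e-12:
            n_le += 1
        if w >= w_obs - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def _signed_rank_normal(diffs: np.ndarray) -> float:
    n = diffs.size
    w_obs, ranks = _signed_rank_statistic(diffs)
    mu = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
    z = (w_obs - mu) / sqrt(var)
    return min(1.0, 2.0 * (1.0 - _phi(abs(z))))


def _phi(z: float) -> float:
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def wilcoxon_rank_sum(a, b, exact_limit: int = 20) -> float:
    """Two-sided rank-sum p for independent samples.

    Exact permutation enumeration when n_a + n_b <= exact_limit (mid-ranks
    on ties), tie-corrected normal approximation otherwise. Two-sided p is
    twice the smaller tail probability of the observed rank sum, capped
    at 1. Complete separation of two size-6 samples attains the floor
    2 / C(12, 6) ~= 0.00216.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = float(np.sum(ranks[:n_a]))
    if n_a + n_b <= exact_limit:
        n_le = n_ge = 0
        total = comb(n_a + n_b, n_a)
        for combo in itertools.combinations(ranks, n_a):
            w = sum(combo)
            if w <= w_obs + 1e-12:
                n_le += 1
            if w >= w_obs - 1e-12:
                n_ge += 1
        return min(1.0, 2.0 * min(n_le, n_ge) / total)
    n = n_a + n_b
    mu = n_a * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    z = (w_obs - mu) / sqrt(var)
    return min(1.0, 2.0 * (1.0 - _phi(abs(z))))


def bonferroni(p_values, m: int) -> list[float]:
    """Multiply each raw p by the family size m, capping at 1."""
    p_values = list(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than {len(p_values)} p-values")
    return [min(1.0, m * p) for p in p_values]


def compare_conditions(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    paired: bool,
    metrics: tuple[str, ...] = MOTION_METRICS,
    m: int | None = None,
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Metric-by-metric comparison of two condition tables (rows = subjects).

    Paired conditions use the signed-rank test, independent ones the
    rank-sum test; the Bonferroni family defaults to the number of metrics.
    """
    metrics = tuple(c for c in metrics if c in table_a.columns and c in table_b.columns)
    if m is None:
        m = len(metrics)
    results = []
    for metric in metrics:
        va = table_a[metric].dropna().to_numpy()
        vb = table_b[metric].dropna().to_numpy()
        if paired:
            p = wilcoxon_signed_rank(va, vb)
            test = "signed_rank"
        else:
            p = wilcoxon_rank_sum(va, vb)
            test = "rank_sum"
        results.append(ComparisonResult.build(metric, test, p, m, alpha))
    return results


def comparison_report(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
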