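"""Study-level statistics: nonparametric group comparisons, Bonferroni
correction, Pearson correlation, and threshold-rule diagnostic performance.

Conventions follow common clinical-pathology practice: two-sided p-values
throughout, significance at p < 0.05, Bonferroni correction across the
marker family. The Mann-Whitney test takes the exact permutation
distribution of U when the combined sample is small (n <= 12) and the
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "DiagnosticPerformance",
    "compare_groups",
    "mann_whitney",
    "bonferroni_adjust",
    "pearson_correlation",
    "diagnostic_performance",
    "EXACT_MW_MAX_N",
]

# Largest combined sample for which the Mann-Whitney permutation
# distribution is enumerated exactly (C(12, 6) = 924 assignments).
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float
    p_value: float
    p_adjusted: float
    test_name: str
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class DiagnosticPerformance:
    """2x2 confusion tallies and predictive values of a threshold rule.

    ``ppv`` / ``npv`` are None (undefined) when the corresponding
    denominator is zero — never silently 0.
    """

    threshold_pct: float
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float | None
    npv: float | None


def _ranks_with_ties(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p-value for the Mann-Whitney U of the
    first group, by enumerating all group assignments of the pooled
    midranks (valid under ties)."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _ranks_with_ties(pooled)
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    n = n1 + n2
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)]
    )
    n_perm = len(us)
    # Tolerant comparison: rank sums are multiples of 0.5, exact in floats.
    p_low = np.count_nonzero(us <= u_obs) / n_perm
    p_high = np.count_nonzero(us >= u_obs) / n_perm
    return float(u_obs), float(min(1.0, 2.0 * min(p_low, p_high)))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns (U of the first sample, p). Exact permutation distribution
    when ``len(x) + len(y) <= EXACT_MW_MAX_N``; otherwise the normal
    approximation with tie correction (scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if len(x) + len(y) <= EXACT_MW_MAX_N:
        return _exact_mann_whitney(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values_by_group: Sequence[Sequence[float]],
    test: str,
    m_comparisons: int = 1,
) -> GroupComparisonResult:
    """Run the named group-comparison test and Bonferroni-adjust its p.

    ``test`` is one of ``mann_whitney`` (exactly 2 groups),
    ``kruskal_wallis`` (chi-square approximation), ``t_test`` (Student,
    pooled variance), or ``chi_square`` (contingency table of counts, no
    continuity correction). ``m_comparisons`` is the Bonferroni family
    size applied to ``p_adjusted``.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    sizes = tuple(len(g) for g in groups)

    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        stat, p = mann_whitney(groups[0], groups[1])
    elif test == "kruskal_wallis":
        stat, p = sps.kruskal(*groups)
        stat, p = float(stat), float(p)
    elif test == "t_test":
        if len(groups) != 2:
            raise ValueError("t_test requires exactly two groups")
        res = sps.ttest_ind(groups[0], groups[1], equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "chi_square":
        table = np.asarray(values_by_group, dtype=float)
        if not np.all(table == np.round(table)) or np.any(table < 0):
            raise ValueError("chi_square requires a table of non-negative counts")
        res = sps.chi2_contingency(table, correction=False)
        stat, p = float(res[0]), float(res[1])
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparisonResult(
        statistic=stat,
        p_value=p,
        p_adjusted=bonferroni_adjust([p], m_comparisons)[0],
        test_name=test,
        group_sizes=sizes,
    )


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni correction: each p becomes min(1, m·p), order preserved."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError(f"m = {m} is smaller than the number of p-values ({len(p_values)})")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
    return [min(1.0, m * p) for p in p_values]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-test p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def diagnostic_performance(
    scores: Sequence[float],
    labels: Sequence[bool],
    threshold_pct: float,
) -> DiagnosticPerformance:
    """Evaluate the "score > threshold means disease" rule.

    ``labels`` are the true disease states. PPV = tp/(tp+fp) and
    NPV = tn/(tn+fn); either is None when no sample is predicted in that
    direction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both disease classes must be present")
    predicted = scores > threshold_pct
    tp = int((predicted & labels).sum())
    fp = int((predicted & ~labels).sum())
    tn = int((~predicted & ~labels).sum())
    fn = int((~predicted & labels).sum())
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    return DiagnosticPerformance(
        threshold_pct=float(threshold_pct), tp=tp, fp=fp, tn=tn, fn=fn, ppv=ppv, npv=npv
    )
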