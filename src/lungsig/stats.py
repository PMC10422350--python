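"""Two-group comparison of per-cycle cumulative AUCs: one-way ANOVA F test,
F critical values, and five-number box-plot summaries.

The F value is the ratio of between-group to within-group mean squares with
degrees of freedom (1, n_a + n_b - 2) for two groups; a value above the
upper-alpha F quantile (the critical value) marks a significant difference
between the groups' mean AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats as sstats

from .errors import ConfigurationError

__all__ = ["GroupComparison", "BoxplotSummary", "one_way_f_test", "f_critical",
           "boxplot_summary"]


@dataclass
class BoxplotSummary:
    """Five-number summary with 1.5 x IQR outliers (quartiles by linear interpolation)."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: List[float]


@dataclass
class GroupComparison:
    """One-way two-group ANOVA result plus per-group box summaries."""

    group_labels: Tuple[str, str]
    n_per_group: Tuple[int, int]
    f_value: float
    p_value: float
    f_critical: float
    alpha: float
    df: Tuple[int, int]
    degenerate: bool = False
    summary_a: Optional[BoxplotSummary] = None
    summary_b: Optional[BoxplotSummary] = None


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-alpha quantile of the F(df1, df2) distribution."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ConfigurationError("degrees of freedom must be >= 1")
    return float(sstats.f.ppf(1.0 - alpha, df1, df2))


def boxplot_summary(values) -> BoxplotSummary:
    """Five-number summary; points beyond Q1 - 1.5 IQR or Q3 + 1.5 IQR are outliers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigurationError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return BoxplotSummary(float(values.min()), float(q1), float(med), float(q3),
                          float(values.max()), [float(v) for v in outliers])


def one_way_f_test(group_a, group_b, alpha: float = 0.05,
                   labels: Tuple[str, str] = ("group_a", "group_b")) -> GroupComparison:
    """Classical one-way ANOVA between two groups.

    F = MS_between / MS_within with df (1, n_a + n_b - 2); p is the upper
    tail of the F distribution. With zero within-group variance the test is
    degenerate: identical constant groups are rejected as an error, separated
    constant groups report F = inf, p = 0 with the ``degenerate`` flag set.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs at least 2 values")
    n = a.size + b.size
    df1, df2 = 1, n - 2
    grand = (a.sum() + b.sum()) / n
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    crit = f_critical(alpha, df1, df2)
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ConfigurationError(
                "both groups are identical constants; the F test is undefined")
        f_val, p_val, degenerate = float("inf"), 0.0, True
    else:
        f_val = (ss_between / df1) / (ss_within / df2)
        p_val = float(sstats.f.sf(f_val, df1, df2))
        degenerate = False
    return GroupComparison(
        group_labels=tuple(labels),
        n_per_group=(a.size, b.size),
        f_value=float(f_val),
        p_value=p_val,
        f_critical=crit,
        alpha=alpha,
        df=(df1, df2),
        degenerate=degenerate,
        summary_a=boxplot_summary(a),
        summary_b=boxplot_summary(b),
    )
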