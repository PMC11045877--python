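"""Group comparisons and boxplot summaries.

The statistical unit is the cell: each observation is one cell's mean
relative BiAD signal (or, for allelic analyses, one spot's Xa-normalised
value).  Replicates are recorded for plotting but pooled for testing, as in
the source workflow.  Two-group contrasts use a two-tailed unpaired t test
(Welch by default, Student's available); three or more groups use one-way
ANOVA with Tukey's HSD posttest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateDataError

__all__ = [
    "GroupComparison",
    "BoxplotSummary",
    "compare_two_groups",
    "compare_multi_groups",
    "summarize_boxplot",
]


@dataclass
class GroupComparison:
    test_name: str
    group_labels: list[str]
    group_means: list[float]
    statistic: float
    p_value: float
    pairwise: list[tuple[tuple[str, str], float]] | None = None


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    points: list[tuple[float, str]] = field(default_factory=list)


def compare_two_groups(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "welch",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-tailed unpaired t test between two groups of per-cell values.

    ``variant='welch'`` (default) does not assume equal variances;
    ``variant='student'`` is the classical pooled-variance test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        raise DegenerateDataError("both groups constant and equal; t test undefined")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(
        test_name="t_test_two_tailed_unpaired",
        group_labels=list(labels),
        group_means=[float(a.mean()), float(b.mean())],
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def compare_multi_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA with Tukey HSD adjusted pairwise p values (>= 3 groups)."""
    if len(groups) < 3:
        raise ValueError(
            f"got {len(groups)} groups; use compare_two_groups for two-group contrasts"
        )
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(arr.size < 2 for arr in arrays):
        raise ValueError("each group needs at least 2 observations")
    f_stat, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    group_idx = np.concatenate([np.full(arr.size, lab, dtype=object)
                                for arr, lab in zip(arrays, labels)])
    tukey = pairwise_tukeyhsd(values, group_idx)
    # summary rows: group1, group2, meandiff, p-adj, lower, upper, reject
    pairwise = [
        ((str(row[0]), str(row[1])), float(row[3]))
        for row in tukey.summary().data[1:]
    ]
    return GroupComparison(
        test_name="anova_tukey",
        group_labels=labels,
        group_means=[float(arr.mean()) for arr in arrays],
        statistic=float(f_stat),
        p_value=float(p),
        pairwise=pairwise,
    )


def summarize_boxplot(
    values: Sequence[float],
    replicate_ids: Sequence[str] | None = None,
) -> BoxplotSummary:
    """Five-number boxplot summary with Tukey whiskers.

    Quartiles use linear-interpolation quantiles; whiskers extend to the most
    extreme observed points within 1.5 interquartile ranges of the box.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    reps = list(replicate_ids) if replicate_ids is not None else [""] * vals.size
    if len(reps) != vals.size:
        raise ValueError("replicate_ids length must match values")
    return BoxplotSummary(
        median=med,
        q1=q1,
        q3=q3,
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        points=list(zip(vals.tolist(), reps)),
    )
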