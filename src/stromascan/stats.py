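"""Group-comparison statistics: one-way ANOVA followed by pairwise t-tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import f_oneway, ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = ["PairwiseTest", "GroupComparison", "compare_groups"]


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    t_p: float
    welch: bool
    significant: bool


@dataclass
class GroupComparison:
    """Omnibus ANOVA plus pairwise two-sample t-tests for one metric.

    Pairwise results are only meaningful alongside the omnibus p-value;
    both are always reported together.  No multiplicity correction is
    applied by default; Holm-adjusted p-values are used when
    ``holm=True`` was requested.
    """

    metric: str
    groups: dict[str, np.ndarray]
    anova_p: float
    pairwise: list[PairwiseTest]
    alpha: float = 0.05
    holm: bool = False


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    metric: str = "metric",
    alpha: float = 0.05,
    welch: bool = True,
    holm: bool = False,
) -> GroupComparison:
    """One-way ANOVA across conditions, then all pairwise t-tests.

    Welch's unequal-variance t-test is the default variant; set
    ``welch=False`` for the pooled-variance test.  ``holm=True`` applies a
    Holm step-down correction to the pairwise p-values (recommended, but
    off by default).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 values")

    anova_p = float(f_oneway(*groups.values()).pvalue)
    pairs = list(combinations(sorted(groups), 2))
    raw_p = [
        float(ttest_ind(groups[a], groups[b], equal_var=not welch).pvalue)
        for a, b in pairs
    ]
    adj_p = list(multipletests(raw_p, method="holm")[1]) if holm and raw_p else raw_p
    pairwise = [
        PairwiseTest(
            group_a=a, group_b=b, t_p=p, welch=welch, significant=p < alpha
        )
        for (a, b), p in zip(pairs, adj_p)
    ]
    return GroupComparison(
        metric=metric, groups=groups, anova_p=anova_p, pairwise=pairwise,
        alpha=alpha, holm=holm,
    )
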