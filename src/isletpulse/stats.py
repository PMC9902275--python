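"""Group comparison used throughout the figures: unpaired two-tailed t test
with the conventional star levels (* p<0.05, ** p<0.01, *** p<0.001)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "star_level"]


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    stars: str
    equal_var: bool = True


def star_level(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(a, b, label_a: str = "a", label_b: str = "b",
                   equal_var: bool = True) -> GroupComparison:
    """Unpaired two-tailed Student t test (classical pooled variance by
    default; set ``equal_var=False`` for Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance, identical groups
        t, p = 0.0, 1.0
    return GroupComparison(label_a=label_a, label_b=label_b,
                           n_a=int(a.size), n_b=int(b.size),
                           t_statistic=t, p_value=p, stars=star_level(p),
                           equal_var=equal_var)
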