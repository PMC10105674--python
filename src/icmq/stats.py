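"""Group statistics on per-animal summaries.

The experimental unit is the animal: every value entering a test is one
pooled mean per animal, and n is the number of animals.  Two groups are
compared with an unpaired pooled-variance (Student's) t-test, three or more
with one-way ANOVA followed by a Holm-Sidak step-down post-test; all tests
are two-sided with significance declared at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

__all__ = [
    "ALPHA",
    "GroupComparison",
    "group_mean_se",
    "unpaired_t",
    "one_way_anova",
    "holm_sidak",
    "compare_groups",
]


@dataclass
class GroupComparison:
    """Result of comparing per-animal group means for one metric."""

    metric: str
    groups: list[str]
    means: dict[str, float]
    ses: dict[str, float]
    ns: dict[str, int]
    test: str  # "t" or "anova_holm_sidak"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None  # pairwise raw/adjusted p (ANOVA post-test)
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _as_array(values, name="group"):
    arr = np.asarray(list(values), dtype=float)
    if len(arr) < 2:
        raise ValueError(f"{name} needs n >= 2 values (n = animals)")
    return arr


def group_mean_se(values) -> tuple[float, float]:
    """Mean and standard error (SD/sqrt(n), sample SD) of one group."""
    arr = _as_array(values)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))


def unpaired_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided unpaired t-test (pooled variance by default; Welch optional).

    Zero-variance edge cases are resolved before delegating to scipy: equal
    constant groups give (0, 1); unequal constant groups give (+/-inf, 0).
    """
    a, b = _as_array(a, "a"), _as_array(b, "b")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across >= 2 groups.

    Degenerate cases mirror ``unpaired_t``: no variability at all gives
    (0, 1); zero within-group variance with distinct means gives (inf, 0).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrs = [_as_array(g) for g in groups]
    grand = np.concatenate(arrs)
    ss_total = float(((grand - grand.mean()) ** 2).sum())
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    if ss_total == 0:
        return 0.0, 1.0
    if ss_within == 0:
        return float("inf"), 0.0
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def holm_sidak(raw_pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in input order.

    Sorted ascending, adjusted_i = 1 - (1 - p_i)^(m - i + 1), then made
    monotone non-decreasing along the sorted order (so tied raw p-values end
    up with equal adjusted values).
    """
    p = np.asarray(list(raw_pvalues), dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a 1-D, non-empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=ALPHA, method="holm-sidak")[1]


def compare_groups(table: pd.DataFrame, metric: str, by: str = "group") -> GroupComparison:
    """Compare per-animal values of ``metric`` across the levels of ``by``.

    Two groups -> unpaired Student's t-test; more -> one-way ANOVA with a
    Holm-Sidak-adjusted all-pairs t post-test.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table")
    clean = table.dropna(subset=[metric])
    levels = sorted(clean[by].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups to compare")
    data = {g: clean.loc[clean[by].astype(str) == g, metric].to_numpy(float) for g in levels}
    means, ses, ns = {}, {}, {}
    for g, v in data.items():
        means[g], ses[g] = group_mean_se(v)
        ns[g] = len(v)
    if len(levels) == 2:
        t, p = unpaired_t(data[levels[0]], data[levels[1]])
        return GroupComparison(metric, levels, means, ses, ns, "t", t, p)
    f, p = one_way_anova(*data.values())
    pairs = [(levels[i], levels[j]) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    raw = [unpaired_t(data[a], data[b])[1] for a, b in pairs]
    adj = holm_sidak(raw)
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "raw_p": raw,
            "adjusted_p": adj,
            "significant": adj < ALPHA,
        }
    )
    return GroupComparison(metric, levels, means, ses, ns, "anova_holm_sidak", f, p, pairwise)
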