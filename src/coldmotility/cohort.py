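"""Group-level comparisons: Welch's t-test, significance stars, fold changes.

Tests are two-sided throughout, no multiple-testing correction is applied
across temperature panels (each panel is tested on its own; see the methods
note for the caveat), and cohort summaries report mean +/- SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConditionGroup",
    "ComparisonResult",
    "welch_t_test",
    "significance_stars",
    "fold_change",
    "summarize_conditions",
]

#: star thresholds, most extreme first; strict inequalities
_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class ConditionGroup:
    """Per-cell (or per-well) measurements of one metric under one condition.

    ``label`` identifies the panel (typically the temperature), ``arm`` the
    group within the panel (e.g. "non-AC" vs "AC").
    """

    label: str
    values: tuple[float, ...]
    arm: str = ""

    def __init__(self, label, values: Sequence[float], arm: str = ""):
        object.__setattr__(self, "label", str(label))
        object.__setattr__(self, "values", tuple(float(v) for v in values))
        object.__setattr__(self, "arm", arm)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else np.nan


@dataclass
class ComparisonResult:
    t_statistic: float
    welch_df: float
    p_value: float
    stars: str
    fold_change: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Two-sided Welch's t-test of b vs a (unequal variances).

    Degrees of freedom follow Welch--Satterthwaite.  Both groups constant and
    equal yields t = 0, p = 1 with a warning.  The fold change is
    ``mean(b) / mean(a)`` when ``mean(a) > 0``, else NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2 (got {a.size} and {b.size})")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain only finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn(
                "both groups constant and equal; returning t=0, p=1",
                RuntimeWarning,
                stacklevel=2,
            )
            t, p, df = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            raise ValueError("both groups have zero variance with unequal means")
    else:
        res = stats.ttest_ind(b, a, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    fc = float(b.mean() / a.mean()) if a.mean() > 0 else np.nan
    return ComparisonResult(
        t_statistic=t,
        welch_df=df,
        p_value=p,
        stars=significance_stars(p),
        fold_change=fc,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
    )


def significance_stars(p: float) -> str:
    """Map a p-value to ns/*/**/***/**** (strict thresholds, most extreme wins)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    for thresh, label in _STAR_LEVELS:
        if p < thresh:
            return label
    return "ns"


def fold_change(reference: ConditionGroup, test: ConditionGroup) -> float:
    """``mean(test) / mean(reference)``; undefined for non-positive reference."""
    if reference.mean <= 0:
        raise ValueError(
            f"fold change undefined: reference group {reference.label!r} has "
            f"mean {reference.mean} <= 0"
        )
    return test.mean / reference.mean


def summarize_conditions(
    groups: Sequence[ConditionGroup],
    reference_arm: str = "non-AC",
    test_arm: str = "AC",
) -> pd.DataFrame:
    """Per-label comparison table of a two-arm condition sweep.

    For every label (e.g. temperature) present: mean +/- SD per arm, Welch p,
    stars, and fold change test/reference.  Labels with a missing arm are
    emitted with the comparison fields empty (NaN).
    """
    by_label: dict[str, dict[str, ConditionGroup]] = {}
    for g in groups:
        by_label.setdefault(g.label, {})[g.arm] = g
    rows = []
    for label in by_label:
        ref = by_label[label].get(reference_arm)
        tst = by_label[label].get(test_arm)
        row = {"label": label}
        for arm_name, g in ((reference_arm, ref), (test_arm, tst)):
            row[f"mean_{arm_name}"] = g.mean if g else np.nan
            row[f"sd_{arm_name}"] = g.sd if g else np.nan
            row[f"n_{arm_name}"] = g.n if g else 0
        if ref is not None and tst is not None:
            cmp = welch_t_test(ref.values, tst.values)
            row.update(
                p_value=cmp.p_value,
                stars=cmp.stars,
                fold_change=cmp.fold_change,
            )
        else:
            row.update(p_value=np.nan, stars="", fold_change=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
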