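"""Diagnostic accuracy of the rule and two-group marker comparisons.

Sensitivity and specificity are computed from the 2x2 cross-tabulation of
the tool's decision-time indication against the adjudicated full-stay need
for urinary-pathogen treatment. Confidence intervals default to exact
Clopper-Pearson at 95%: the specificity estimate sits at the boundary
(100%), where Wald intervals degenerate.

Marker comparisons follow the study's analysis plan: Pearson chi-square on
2x2 tables for binary urinalysis markers (continuity correction off by
default, switchable) and a two-sample t test for leukocyte counts (Welch
by default; the pooled-variance variant is available). Records missing the
relevant measurement are excluded from the affected comparison only.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .adjudication import TruthLabel
from .engine import CDSTDecision


class ConfusionMatrix(BaseModel):
    """Tool indication vs adjudicated true need."""

    tp: int = Field(ge=0)
    fp: int = Field(ge=0)
    fn: int = Field(ge=0)
    tn: int = Field(ge=0)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class AccuracyEstimate(BaseModel):
    sensitivity: float = Field(ge=0, le=1)
    specificity: float = Field(ge=0, le=1)
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]

    @model_validator(mode="after")
    def _point_inside_interval(self) -> "AccuracyEstimate":
        for point, (low, high) in (
            (self.sensitivity, self.sensitivity_ci),
            (self.specificity, self.specificity_ci),
        ):
            if not (0.0 <= low <= point <= high <= 1.0):
                raise ValueError("point estimate must lie inside its interval within [0,1]")
        return self


class GroupComparison(BaseModel):
    """Two-group comparison of one marker.

    ``group_a_value``/``group_b_value`` are proportions for binary markers
    and means (cells/µL) for continuous ones.
    """

    marker: str
    group_a_value: float
    group_b_value: float
    statistic: float
    p_value: float = Field(ge=0, le=1)


def confusion(
    decisions: Sequence[CDSTDecision], truths: Sequence[TruthLabel]
) -> ConfusionMatrix:
    """Cross-tabulate tool indication against the reference standard."""
    if len(decisions) != len(truths):
        raise ValueError(
            f"decision/truth length mismatch: {len(decisions)} vs {len(truths)}"
        )
    tp = fp = fn = tn = 0
    for decision, truth in zip(decisions, truths):
        if decision.indicated and truth.truly_needed:
            tp += 1
        elif decision.indicated:
            fp += 1
        elif truth.truly_needed:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def accuracy(
    cm: ConfusionMatrix, ci_level: float = 0.95, ci_method: str = "clopper_pearson"
) -> AccuracyEstimate:
    """Sensitivity, specificity and exact binomial confidence intervals."""
    if cm.tp + cm.fn == 0:
        raise ValueError("sensitivity undefined: no truly-needed cases (tp+fn=0)")
    if cm.tn + cm.fp == 0:
        raise ValueError("specificity undefined: no not-needed cases (tn+fp=0)")
    if ci_method not in ("clopper_pearson", "beta"):
        raise ValueError(f"unsupported ci_method {ci_method!r}")
    alpha = 1.0 - ci_level
    sens_ci = proportion_confint(cm.tp, cm.tp + cm.fn, alpha=alpha, method="beta")
    spec_ci = proportion_confint(cm.tn, cm.tn + cm.fp, alpha=alpha, method="beta")
    return AccuracyEstimate(
        sensitivity=cm.tp / (cm.tp + cm.fn),
        specificity=cm.tn / (cm.tn + cm.fp),
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )


def _drop_missing(values: Sequence[Optional[object]]) -> list:
    return [v for v in values if v is not None]


def compare_proportions(
    group_a: Sequence[Optional[bool]],
    group_b: Sequence[Optional[bool]],
    marker: str = "",
    continuity_correction: bool = False,
) -> GroupComparison:
    """Pearson chi-square comparison of a binary marker between two groups.

    Missing values (``None``) are excluded. A marker that is constant
    across both groups carries no association: statistic 0, p = 1.
    """
    a = _drop_missing(group_a)
    b = _drop_missing(group_b)
    if not a or not b:
        raise ValueError(f"marker {marker!r}: a group is empty after missing-data exclusion")
    table = np.array(
        [[sum(a), len(a) - sum(a)], [sum(b), len(b) - sum(b)]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():  # constant marker: zero column margin
        statistic, p_value = 0.0, 1.0
    else:
        result = stats.chi2_contingency(table, correction=continuity_correction)
        statistic, p_value = float(result.statistic), float(result.pvalue)
    return GroupComparison(
        marker=marker,
        group_a_value=sum(a) / len(a),
        group_b_value=sum(b) / len(b),
        statistic=statistic,
        p_value=min(p_value, 1.0),
    )


def compare_means(
    group_a: Sequence[Optional[float]],
    group_b: Sequence[Optional[float]],
    marker: str = "",
    equal_var: bool = False,
) -> GroupComparison:
    """Two-sample t test of a continuous marker (Welch by default)."""
    a = [float(v) for v in _drop_missing(group_a)]
    b = [float(v) for v in _drop_missing(group_b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"marker {marker!r}: each group needs >= 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        statistic, p_value = 0.0, 1.0  # identical constant groups
    else:
        result = stats.ttest_ind(a, b, equal_var=equal_var)
        statistic, p_value = float(result.statistic), float(result.pvalue)
    return GroupComparison(
        marker=marker,
        group_a_value=float(np.mean(a)),
        group_b_value=float(np.mean(b)),
        statistic=statistic,
        p_value=min(p_value, 1.0),
    )


def percent(fraction: float, ndigits: int = 1) -> float:
    """Format a proportion as a percentage, rounded half-up.

    Half-up (not banker's) rounding matches clinical reporting convention:
    73/74 -> 98.6.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(fraction * 100).quantize(quantum, rounding=ROUND_HALF_UP))
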