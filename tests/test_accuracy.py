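"""Diagnostic accuracy: confusion matrix, exact CIs, and group comparisons,
each checked against an independent closed-form oracle."""

import itertools
import math

import pytest
from scipy import stats

from uti_cdst import (
    ConfusionMatrix,
    TruthLabel,
    accuracy,
    compare_means,
    compare_proportions,
    confusion,
    percent,
)
from uti_cdst.engine import NO_QUESTION, Q2, CDSTDecision


def decision(indicated):
    return CDSTDecision(
        indicated=indicated, fired_question=Q2 if indicated else NO_QUESTION
    )


def test_confusion_brute_force_over_all_assignments():
    """All 4^3 (indication, need) assignments for 3 records vs hand counts."""
    options = [(i, t) for i in (False, True) for t in (False, True)]
    for assignment in itertools.product(options, repeat=3):
        cm = confusion(
            [decision(i) for i, _ in assignment],
            [TruthLabel(truly_needed=t) for _, t in assignment],
        )
        want = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for indicated, needed in assignment:
            key = ("t" if indicated == needed else "f") + ("p" if indicated else "n")
            want[key] += 1
        assert cm.model_dump() == want
        assert cm.total == 3


def test_confusion_all_agree_has_no_errors():
    cm = confusion([decision(x) for x in (True, True, False, False)],
                   [TruthLabel(truly_needed=x) for x in (True, True, False, False)])
    assert (cm.fp, cm.fn) == (0, 0)


def test_confusion_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        confusion([decision(True)], [])


def cp_interval_oracle(x, n, level=0.95):
    """Clopper-Pearson via direct beta-quantile evaluation."""
    alpha = 1 - level
    low = 0.0 if x == 0 else stats.beta.ppf(alpha / 2, x, n - x + 1)
    high = 1.0 if x == n else stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return low, high


@pytest.mark.parametrize(
    "cm, sens, spec",
    [
        (ConfusionMatrix(tp=73, fp=0, fn=1, tn=50), 73 / 74, 1.0),
        (ConfusionMatrix(tp=1, fp=1, fn=1, tn=1), 0.5, 0.5),
        (ConfusionMatrix(tp=9, fp=3, fn=2, tn=30), 9 / 11, 30 / 33),
    ],
)
def test_accuracy_estimates_and_exact_intervals(cm, sens, spec):
    est = accuracy(cm)
    assert est.sensitivity == pytest.approx(sens)
    assert est.specificity == pytest.approx(spec)
    assert est.sensitivity_ci == pytest.approx(cp_interval_oracle(cm.tp, cm.tp + cm.fn))
    assert est.specificity_ci == pytest.approx(cp_interval_oracle(cm.tn, cm.tn + cm.fp))


@pytest.mark.parametrize("tp, tn", [(1, 1), (5, 3), (73, 50)])
def test_perfect_classifier(tp, tn):
    est = accuracy(ConfusionMatrix(tp=tp, fp=0, fn=0, tn=tn))
    assert (est.sensitivity, est.specificity) == (1.0, 1.0)


def test_accuracy_undefined_margins_are_named():
    with pytest.raises(ValueError, match="sensitivity"):
        accuracy(ConfusionMatrix(tp=0, fp=1, fn=0, tn=1))
    with pytest.raises(ValueError, match="specificity"):
        accuracy(ConfusionMatrix(tp=1, fp=0, fn=1, tn=0))


class TestCompareProportions:
    def test_identical_proportions_show_no_association(self):
        result = compare_proportions([True] * 5 + [False] * 5, [True] * 5 + [False] * 5)
        assert (result.statistic, result.p_value) == (0.0, 1.0)

    def test_toy_table_matches_hand_computed_chi_square(self):
        """8/10 vs 2/10: all expected cells are 5, chi2 = 4*(3^2/5) = 7.2."""
        result = compare_proportions([True] * 8 + [False] * 2, [True] * 2 + [False] * 8)
        assert result.statistic == pytest.approx(7.2)
        assert result.p_value == pytest.approx(stats.chi2.sf(7.2, df=1))
        assert (result.group_a_value, result.group_b_value) == (0.8, 0.2)

    def test_constant_marker_degenerates_to_null(self):
        result = compare_proportions([True] * 4, [True] * 6)
        assert (result.statistic, result.p_value) == (0.0, 1.0)

    def test_missing_values_excluded(self):
        result = compare_proportions([True, None, False], [False, True, None])
        assert (result.group_a_value, result.group_b_value) == (0.5, 0.5)

    def test_all_missing_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compare_proportions([None, None], [True, False])

    def test_swap_symmetry(self):
        a, b = [True] * 7 + [False] * 3, [True] * 3 + [False] * 9
        fwd, rev = compare_proportions(a, b), compare_proportions(b, a)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.statistic == pytest.approx(rev.statistic)
        assert (fwd.group_a_value, fwd.group_b_value) == (rev.group_b_value, rev.group_a_value)

    def test_power_grows_with_sample_size(self):
        """The same 0.6-vs-0.4 contrast yields smaller p at larger n."""
        p_values = []
        for n in (20, 40, 80, 160):
            a = [True] * int(0.6 * n) + [False] * (n - int(0.6 * n))
            b = [True] * int(0.4 * n) + [False] * (n - int(0.4 * n))
            p_values.append(compare_proportions(a, b).p_value)
        assert p_values == sorted(p_values, reverse=True)
        assert p_values[-1] < p_values[0]


class TestCompareMeans:
    def test_identical_groups(self):
        result = compare_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_welch_statistic_matches_closed_form(self):
        """{1,2,3} vs {4,5,6}: s^2 = 1 each, t = -3 / sqrt(2/3), df = 4."""
        result = compare_means([1, 2, 3], [4, 5, 6])
        t_expected = -3.0 / math.sqrt(2.0 / 3.0)
        assert result.statistic == pytest.approx(t_expected)
        assert result.p_value == pytest.approx(2 * stats.t.sf(abs(t_expected), df=4))
        assert (result.group_a_value, result.group_b_value) == (2.0, 5.0)

    def test_shift_increases_statistic_monotonically(self):
        base = [1.0, 2.0, 3.0, 4.0]
        magnitudes = [
            abs(compare_means(base, [v + shift for v in base]).statistic)
            for shift in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert magnitudes == sorted(magnitudes)

    def test_swap_negates_statistic_keeps_p(self):
        fwd = compare_means([1, 2, 3], [4, 5, 7])
        rev = compare_means([4, 5, 7], [1, 2, 3])
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_means([1.0], [1.0, 2.0])


def test_percent_rounds_half_up():
    assert percent(73 / 74) == 98.6
    assert percent(1.0) == 100.0
    assert percent(0.625, ndigits=0) == 63.0  # half-up, not banker's (62)
    assert percent(265 / 787) == 33.7
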