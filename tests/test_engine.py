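"""The 3-question rule engine against an independent brute-force oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uti_cdst import evaluate, evaluate_cohort
from uti_cdst.engine import NO_QUESTION, Q1, Q2, Q3
from uti_cdst.models import LOCALIZED_SYMPTOMS, SYSTEMIC_SIGNS

from conftest import make_record

SPECIAL_FLAGS = ("pregnant", "pre_endourological_procedure", "renal_transplant_within_60_days")


def oracle(special, localized, systemic, alternate_present):
    """Independent nested-conditional restatement of the clinical logic:
    treat ASB only in special populations; any localized urinary symptom
    means UTI; otherwise unexplained systemic illness makes UTI a diagnosis
    of exclusion worth testing for."""
    if special["pregnant"] or special["pre_endourological_procedure"] or special["renal_transplant_within_60_days"]:
        return True, Q1
    if (
        localized["urgency"]
        or localized["frequency"]
        or localized["dysuria"]
        or localized["suprapubic_pain"]
        or localized["pelvic_discomfort"]
        or localized["flank_pain"]
    ):
        return True, Q2
    if systemic["fever"] or systemic["clinical_instability"] or systemic["acute_mental_status_change"]:
        if not alternate_present:
            return True, Q3
        return False, NO_QUESTION
    return False, NO_QUESTION


def build(special_bits, localized_bits, systemic_bits, alternate_present):
    special = dict(zip(SPECIAL_FLAGS, special_bits))
    localized = dict(zip(LOCALIZED_SYMPTOMS, localized_bits))
    systemic = dict(zip(SYSTEMIC_SIGNS, systemic_bits))
    symptoms = {**localized, **systemic}
    if alternate_present:
        symptoms["alternate_explanation_for_systemic"] = "non-urinary cause"
    return make_record(special=special, symptoms=symptoms), special, localized, systemic


def test_exhaustive_truth_table_matches_oracle():
    """All 2^12 flag combinations x alternate-explanation presence."""
    bits = [False, True]
    checked = 0
    for special_bits in itertools.product(bits, repeat=3):
        for localized_bits in itertools.product(bits, repeat=6):
            for systemic_bits in itertools.product(bits, repeat=3):
                for alternate in (False, True):
                    if alternate and not any(systemic_bits):
                        continue  # invalid by the symptom-set invariant
                    record, special, localized, systemic = build(
                        special_bits, localized_bits, systemic_bits, alternate
                    )
                    decision = evaluate(record)
                    want_indicated, want_q = oracle(special, localized, systemic, alternate)
                    assert (decision.indicated, decision.fired_question) == (
                        want_indicated,
                        want_q,
                    ), record
                    checked += 1
    assert checked == 2**12 + sum(1 for s in itertools.product(bits, repeat=3) if any(s)) * 2**9


@pytest.mark.parametrize(
    "special, symptoms, indicated, question",
    [
        ({"pre_endourological_procedure": True}, {}, True, Q1),
        ({}, {}, False, NO_QUESTION),
        ({}, {"dysuria": True}, True, Q2),
        ({}, {"fever": True, "alternate_explanation_for_systemic": "pneumonia"}, False, NO_QUESTION),
        ({}, {"fever": True}, True, Q3),
        ({}, {"acute_mental_status_change": True, "poor_historian": True}, True, Q3),
    ],
)
def test_clinical_scenarios(special, symptoms, indicated, question):
    decision = evaluate(make_record(special=special, symptoms=symptoms))
    assert (decision.indicated, decision.fired_question) == (indicated, question)


def test_decision_ignores_adjudication():
    """Only decision-time information is used: flipping the reference
    standard never changes the decision."""
    a = make_record(symptoms={"dysuria": True}, truly_needed=True)
    b = make_record(symptoms={"dysuria": True}, truly_needed=False)
    assert evaluate(a) == evaluate(b)


@st.composite
def record_bits(draw):
    special = draw(st.tuples(*[st.booleans()] * 3))
    localized = draw(st.tuples(*[st.booleans()] * 6))
    systemic = draw(st.tuples(*[st.booleans()] * 3))
    alternate = draw(st.booleans()) and any(systemic)
    return special, localized, systemic, alternate


@settings(max_examples=200, derandomize=True)
@given(record_bits(), st.integers(min_value=0, max_value=8))
def test_monotonicity_in_indication_flags(bits, flip_index):
    """Turning on any special or localized flag never revokes an indication."""
    record, *_ = build(*bits)
    before = evaluate(record).indicated
    flag_names = SPECIAL_FLAGS + LOCALIZED_SYMPTOMS
    name = flag_names[flip_index]
    if flip_index < 3:
        setattr(record.special, name, True)
    else:
        setattr(record.symptoms, name, True)
    after = evaluate(record).indicated
    assert after or not before


@settings(max_examples=100, derandomize=True)
@given(st.tuples(*[st.booleans()] * 3).filter(any))
def test_q3_gating_by_alternate_explanation(systemic_bits):
    """With only systemic positives, the alternate explanation alone flips
    the decision."""
    record, *_ = build((False,) * 3, (False,) * 6, systemic_bits, False)
    assert evaluate(record).fired_question == Q3
    record.symptoms.alternate_explanation_for_systemic = "documented other cause"
    assert evaluate(record).indicated is False


def test_cohort_evaluation_is_elementwise():
    records = [build(s, l, y, False)[0] for s, l, y in [
        ((True, False, False), (False,) * 6, (False,) * 3),
        ((False,) * 3, (True, False, False, False, False, False), (False,) * 3),
        ((False,) * 3, (False,) * 6, (True, False, False)),
        ((False,) * 3, (False,) * 6, (False,) * 3),
    ]]
    assert evaluate_cohort(records) == [evaluate(r) for r in records]
    assert evaluate_cohort([]) == []
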