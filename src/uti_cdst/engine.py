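"""The 3-question decision-support rule.

The rule gates urine studies and antibiotic treatment for suspected UTI in
newly hospitalized adults without indwelling catheters. It is evaluated
strictly on information available at decision time (the full-stay
adjudication fields are never read) and asks, in order:

Q1. Is the patient in a population where asymptomatic bacteriuria itself
    warrants treatment (pregnancy, impending endourological procedure,
    renal transplant within 60 days)?
Q2. Are localized urinary symptoms documented (urgency, frequency,
    dysuria, suprapubic pain, pelvic discomfort, flank pain)?
Q3. Are systemic signs present (fever, clinical instability, acute mental
    status change) WITHOUT a documented alternate explanation?

An affirmative answer to any question makes testing and treatment
indicated; the questions short-circuit, so ``fired_question`` is the
lowest-numbered affirmative. Poor historians are handled implicitly: Q2
evaluates documented flags only, and an inability to report symptoms is
not itself an indication — such patients reach Q3.
"""

from __future__ import annotations

from typing import Iterable

from pydantic import BaseModel, model_validator

from .models import PatientRecord

Q1 = "Q1_special_population"
Q2 = "Q2_localized_symptoms"
Q3 = "Q3_systemic_no_alternate"
NO_QUESTION = "none"


class CDSTDecision(BaseModel):
    """Decision-time output of the rule for one record."""

    indicated: bool
    fired_question: str  # {Q1_special_population, Q2_localized_symptoms, Q3_systemic_no_alternate, none}
    rationale: str = ""

    @model_validator(mode="after")
    def _consistent(self) -> "CDSTDecision":
        if self.indicated != (self.fired_question != NO_QUESTION):
            raise ValueError("indicated must be true iff a question fired")
        return self


def evaluate(record: PatientRecord) -> CDSTDecision:
    """Apply the 3-question rule to a single record.

    Deterministic, side-effect-free, and total on valid records.
    """
    special = record.special
    symptoms = record.symptoms

    if special.any():
        flags = [
            name
            for name in ("pregnant", "pre_endourological_procedure", "renal_transplant_within_60_days")
            if getattr(special, name)
        ]
        return CDSTDecision(
            indicated=True,
            fired_question=Q1,
            rationale=f"special population: {', '.join(flags)}",
        )

    if symptoms.any_localized():
        present = [
            name
            for name in ("urgency", "frequency", "dysuria", "suprapubic_pain", "pelvic_discomfort", "flank_pain")
            if getattr(symptoms, name)
        ]
        return CDSTDecision(
            indicated=True,
            fired_question=Q2,
            rationale=f"localized urinary symptoms: {', '.join(present)}",
        )

    if symptoms.any_systemic():
        if symptoms.alternate_explanation_for_systemic is None:
            present = [
                name
                for name in ("fever", "clinical_instability", "acute_mental_status_change")
                if getattr(symptoms, name)
            ]
            return CDSTDecision(
                indicated=True,
                fired_question=Q3,
                rationale=f"systemic signs without alternate explanation: {', '.join(present)}",
            )
        return CDSTDecision(
            indicated=False,
            fired_question=NO_QUESTION,
            rationale=(
                "systemic signs explained by "
                f"{symptoms.alternate_explanation_for_systemic}"
            ),
        )

    return CDSTDecision(
        indicated=False,
        fired_question=NO_QUESTION,
        rationale="no special indication, localized symptoms, or unexplained systemic signs",
    )


def evaluate_cohort(records: Iterable[PatientRecord]) -> list[CDSTDecision]:
    """Element-wise :func:`evaluate`, order preserved."""
    return [evaluate(record) for record in records]
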