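"""Syndrome classification and the treatment-need reference standard.

Each case is assigned exactly one syndrome label with the precedence

    other_infection > pyelonephritis > cystitis > asb

A documented non-urinary infection source is resolved first because the
pyelonephritis definition carries the clause "without another etiology";
note that a case with a documented non-urinary source is classified
``other_infection`` even when the full-stay review ultimately found a
urinary pathogen needed treatment too (a concurrent UTI, e.g. pneumonia
with secondary E. coli bacteremia and bacteriuria, stays in the
other-infection stratum — the reference standard, not the syndrome label,
carries the treatment need).

Definitions:

* pyelonephritis — flank pain, or fever/clinical instability without an
  alternate etiology;
* cystitis — localized urinary symptoms (dysuria et al.) without fever;
* asb — the all-negative residual: no documented urinary symptoms, and no
  fever or instability attributable to the urinary tract (systemic signs
  carrying a documented alternate explanation do not preclude ASB).
"""

from __future__ import annotations

from pydantic import BaseModel, model_validator

from .engine import evaluate
from .models import PatientRecord

ASB = "asb"
CYSTITIS = "cystitis"
PYELONEPHRITIS = "pyelonephritis"
OTHER_INFECTION = "other_infection"

SYNDROMES = (ASB, CYSTITIS, PYELONEPHRITIS, OTHER_INFECTION)


class SyndromeLabel(BaseModel):
    label: str
    asb_with_treatment_indication: bool = False

    @model_validator(mode="after")
    def _check(self) -> "SyndromeLabel":
        if self.label not in SYNDROMES:
            raise ValueError(f"unknown syndrome {self.label!r}")
        if self.asb_with_treatment_indication and self.label != ASB:
            raise ValueError("asb_with_treatment_indication implies label=asb")
        return self


class TruthLabel(BaseModel):
    """The adjudicated need for urinary-pathogen treatment (reference standard)."""

    truly_needed: bool


def classify_syndrome(record: PatientRecord) -> SyndromeLabel:
    """Assign the clinical syndrome for one case (see module docstring)."""
    symptoms = record.symptoms
    if record.adjudication.documented_non_urinary_source is not None:
        return SyndromeLabel(label=OTHER_INFECTION)
    unexplained_systemic = (
        (symptoms.fever or symptoms.clinical_instability)
        and symptoms.alternate_explanation_for_systemic is None
    )
    if symptoms.flank_pain or unexplained_systemic:
        return SyndromeLabel(label=PYELONEPHRITIS)
    if symptoms.any_localized() and not symptoms.fever:
        return SyndromeLabel(label=CYSTITIS)
    return SyndromeLabel(label=ASB, asb_with_treatment_indication=record.special.any())


def true_need(record: PatientRecord) -> TruthLabel:
    """Return the full-stay reference standard for one record.

    Exists as a named operation so downstream accuracy code is decoupled
    from the record schema.
    """
    if record.adjudication is None:  # defensive; schema makes it mandatory
        raise ValueError(f"record {record.record_id!r} lacks adjudication fields")
    return TruthLabel(truly_needed=record.adjudication.urinary_pathogen_treatment_truly_needed)


def inappropriate_treatment_flag(record: PatientRecord, syndrome: SyndromeLabel) -> bool:
    """True iff the case was treated without any documented indication.

    The flag captures ASB without a treatment indication, without a
    documented non-urinary infection source, and without an adjudicated
    true need — i.e. antibiotic exposure with no justification anywhere in
    the record. Symptomatic cases are never flagged.
    """
    return (
        syndrome.label == ASB
        and not syndrome.asb_with_treatment_indication
        and record.adjudication.documented_non_urinary_source is None
        and not record.adjudication.urinary_pathogen_treatment_truly_needed
    )


def adjudicate_cohort(records: list[PatientRecord]) -> list[dict]:
    """Per-record adjudication summary rows (used by the CLI and reports)."""
    rows = []
    for record in records:
        syndrome = classify_syndrome(record)
        rows.append(
            {
                "record_id": record.record_id,
                "syndrome": syndrome.label,
                "asb_with_treatment_indication": syndrome.asb_with_treatment_indication,
                "truly_needed": true_need(record).truly_needed,
                "inappropriate": inappropriate_treatment_flag(record, syndrome),
                "tool_indicated": evaluate(record).indicated,
            }
        )
    return rows
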