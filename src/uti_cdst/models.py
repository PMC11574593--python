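"""Domain model for antibiotic-treated suspected-UTI cases.

Each :class:`PatientRecord` is one hospitalized adult treated with
antibiotics for a UTI indication. The model separates three layers of
information that the decision-support rule, the syndrome adjudication and
the accuracy evaluation consume at different times:

* decision-time inputs — special-population flags, documented symptoms,
  urinalysis values;
* treatment data — antibiotic courses with class-level day counts;
* full-stay adjudication — the chart-review reference standard for whether
  treatment of a urinary pathogen was truly needed.

Absence of documentation is first-class here: an undocumented symptom is
*not* the same thing as a symptom the patient denied, and a "poor
historian" (a patient unable to communicate symptoms, e.g. advanced
dementia or intoxication) may have localized symptoms that are simply not
documentable. Serialization therefore distinguishes an empty cell
(absent) from an explicit ``false``.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field, model_validator

#: Canonical antibiotic-class labels used in the burden stratification.
AGENT_THIRD_GEN_CEPH = "third_generation_cephalosporin"
AGENT_AMOX_CLAV = "amoxicillin_clavulanate"
AGENT_OTHER = "other"

#: Documented non-urinary infection sources recognized by the adjudication.
NON_URINARY_SOURCES = (
    "pneumonia",
    "intra_abdominal",
    "osteomyelitis_decubitus",
    "covid19",
    "cellulitis",
    "epididymitis",
)

#: Localized urinary symptoms (rule Question 2).
LOCALIZED_SYMPTOMS = (
    "urgency",
    "frequency",
    "dysuria",
    "suprapubic_pain",
    "pelvic_discomfort",
    "flank_pain",
)

#: Systemic signs (rule Question 3).
SYSTEMIC_SIGNS = ("fever", "clinical_instability", "acute_mental_status_change")


class SpecialIndication(BaseModel):
    """Populations in which asymptomatic bacteriuria itself warrants treatment.

    These are the guideline exceptions: pregnancy, an impending
    endourological procedure, and renal transplantation within the last 60
    days. All three are explicit booleans; a reader encountering missing
    information codes ``False`` and logs a warning rather than storing an
    absent value.
    """

    pregnant: bool = False
    pre_endourological_procedure: bool = False
    renal_transplant_within_60_days: bool = False

    def any(self) -> bool:
        return (
            self.pregnant
            or self.pre_endourological_procedure
            or self.renal_transplant_within_60_days
        )


class SymptomSet(BaseModel):
    """Documented symptoms at the time the culture/antibiotic was ordered.

    ``alternate_explanation_for_systemic`` is a free-text label present iff
    a non-urinary cause for the systemic signs is documented (e.g.
    "pneumonia", "seizure"); it gates Question 3 of the rule. It may only
    be present when at least one systemic sign is true.
    """

    urgency: bool = False
    frequency: bool = False
    dysuria: bool = False
    suprapubic_pain: bool = False
    pelvic_discomfort: bool = False
    flank_pain: bool = False

    fever: bool = False
    clinical_instability: bool = False
    acute_mental_status_change: bool = False

    alternate_explanation_for_systemic: Optional[str] = None
    poor_historian: bool = False

    @model_validator(mode="after")
    def _alternate_requires_systemic(self) -> "SymptomSet":
        if self.alternate_explanation_for_systemic is not None and not self.any_systemic():
            raise ValueError(
                "alternate_explanation_for_systemic requires at least one systemic sign"
            )
        return self

    def any_localized(self) -> bool:
        return any(getattr(self, name) for name in LOCALIZED_SYMPTOMS)

    def any_systemic(self) -> bool:
        return any(getattr(self, name) for name in SYSTEMIC_SIGNS)


class UrinalysisResult(BaseModel):
    """Urinalysis findings before antibiotic initiation, when obtained."""

    available: bool = False
    leukocyturia: Optional[bool] = None
    bacteria_seen: Optional[bool] = None
    nitrites_positive: Optional[bool] = None
    leukocyte_count: Optional[float] = Field(default=None, ge=0)  # cells/µL

    @model_validator(mode="after")
    def _absent_when_unavailable(self) -> "UrinalysisResult":
        if not self.available:
            for name in ("leukocyturia", "bacteria_seen", "nitrites_positive", "leukocyte_count"):
                if getattr(self, name) is not None:
                    raise ValueError(f"{name} must be absent when urinalysis is unavailable")
        return self


class AntibioticCourse(BaseModel):
    """Class-level antibiotic exposure: calendar days of therapy per agent class.

    A patient on two agent classes for three days each accrues two courses
    of three days (six days of therapy in total).
    """

    agent_class: str
    days_of_therapy: int = Field(ge=1)


class AdjudicationFields(BaseModel):
    """Full-stay chart-review outcome — the reference standard.

    ``urinary_pathogen_treatment_truly_needed`` is the reviewer's
    determination, using the complete hospitalization, of whether treatment
    for a urinary pathogen was needed. It is an input field, never
    computed: the truth came from human review.
    """

    documented_non_urinary_source: Optional[str] = None
    urinary_pathogen_treatment_truly_needed: bool
    notes: str = ""

    @model_validator(mode="after")
    def _normalize_source(self) -> "AdjudicationFields":
        if self.documented_non_urinary_source in ("", "none"):
            self.documented_non_urinary_source = None
        return self


class AdmissionMetadata(BaseModel):
    """Admission-level flags used only by eligibility filtering."""

    admitted: bool = True
    observation_only: bool = False
    onetime_order: bool = False


class PatientRecord(BaseModel):
    """One suspected-UTI case."""

    record_id: str
    age_years: float = Field(gt=0)
    sex: str  # {"female", "male"}
    special: SpecialIndication = Field(default_factory=SpecialIndication)
    symptoms: SymptomSet = Field(default_factory=SymptomSet)
    urinalysis: UrinalysisResult = Field(default_factory=UrinalysisResult)
    courses: list[AntibioticCourse] = Field(default_factory=list)
    adjudication: AdjudicationFields

    @model_validator(mode="after")
    def _check_sex(self) -> "PatientRecord":
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        return self
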