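"""Synthetic cohorts: a seeded generator and the deterministic study fixture.

Two entry points:

* :func:`generate` samples line-level cohorts with the study's statistical
  structure (syndrome mix, special-population fractions, urinalysis marker
  probabilities, antibiotic class mix) from a :class:`CohortConfig`. The
  defaults are the study conditions: a 124-patient cohort with syndrome
  probabilities 50/15/13/46 over pyelonephritis/cystitis/other-infection/
  ASB, 8 of 46 ASB carrying a procedural treatment indication, 36 of 124
  poor historians, and a class mix reproducing the 203/51/533 split of the
  787 antibiotic days.

* :func:`build_fixture` deterministically compiles the 124-record cohort
  whose marginals match every printed study count simultaneously: syndromes
  50/15/13/46; 8 procedural-ASB; 36 poor historians; 38 ASB treated without
  indication; 9 ASB with altered mental status explained by other causes;
  tool-validation margins 73/0/1/50; 787 antibiotic days of which 265 on
  inappropriate records, with class strata (203, 91) for third-generation
  cephalosporins and (51, 21) for amoxicillin-clavulanate; 75 female
  including 1 pregnant patient (classified cystitis); median age 64 (IQR
  46-74.25). Quantities the study does not print (per-patient course
  durations, the poor-historian allocation across strata, urinalysis
  values) are filled by fixed deterministic schedules documented inline;
  only the printed totals are load-bearing. A consistency self-check runs
  at build time and raises if any marginal fails.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .adjudication import (
    ASB,
    CYSTITIS,
    OTHER_INFECTION,
    PYELONEPHRITIS,
    classify_syndrome,
    inappropriate_treatment_flag,
    true_need,
)
from .engine import evaluate_cohort
from .models import (
    AGENT_AMOX_CLAV,
    AGENT_OTHER,
    AGENT_THIRD_GEN_CEPH,
    AdjudicationFields,
    AntibioticCourse,
    NON_URINARY_SOURCES,
    PatientRecord,
    SpecialIndication,
    SymptomSet,
    UrinalysisResult,
)

_SYNDROME_ORDER = (PYELONEPHRITIS, CYSTITIS, OTHER_INFECTION, ASB)

#: Alternate (non-urinary) etiologies for altered mental status in ASB cases:
#: neurological, psychiatric, metabolic, and hypoperfusion causes.
_AMS_ETIOLOGIES = (
    "seizure",
    "psychotic_event",
    "severe_hyponatremia",
    "hyperammonemia",
    "alcohol_intoxication",
    "cardiogenic_shock",
    "hypovolemic_shock",
    "seizure",
    "alcohol_intoxication",
)


class CohortConfig(BaseModel):
    """Parameters of the synthetic-cohort sampler (defaults = study conditions)."""

    n: int = Field(default=124, ge=0)
    syndrome_probabilities: dict[str, float] = Field(
        default_factory=lambda: {
            PYELONEPHRITIS: 50 / 124,
            CYSTITIS: 15 / 124,
            OTHER_INFECTION: 13 / 124,
            ASB: 46 / 124,
        }
    )
    asb_procedural_indication_fraction: float = Field(default=8 / 46, ge=0, le=1)
    poor_historian_fraction: float = Field(default=36 / 124, ge=0, le=1)
    asb_altered_mental_status_fraction: float = Field(default=9 / 46, ge=0, le=1)
    urinalysis_availability: float = Field(default=85 / 124, ge=0, le=1)
    #: P(marker positive) per group; "uti" covers pyelonephritis+cystitis,
    #: "asb" covers everything else.
    marker_probabilities: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "uti": {"leukocyturia": 0.953, "bacteria_seen": 0.594, "nitrites_positive": 0.219},
            "asb": {"leukocyturia": 0.946, "bacteria_seen": 0.684, "nitrites_positive": 0.184},
        }
    )
    #: Log-normal location/scale (of log cells/µL) per group. Heavy right
    #: skew: group means ~860 vs ~165 cells/µL with overlapping spreads.
    leukocyte_count_distribution: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "uti": {"mu": 5.64, "sigma": 1.5},
            "asb": {"mu": 3.98, "sigma": 1.5},
        }
    )
    #: Mean course length (days) per agent class for the shifted-Poisson
    #: day-count model dot ~ 1 + Poisson(mean_days - 1).
    dot_distribution: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            AGENT_THIRD_GEN_CEPH: {"mean_days": 4.2},
            AGENT_AMOX_CLAV: {"mean_days": 4.2},
            AGENT_OTHER: {"mean_days": 4.2},
        }
    )
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {
            AGENT_THIRD_GEN_CEPH: 203 / 787,
            AGENT_AMOX_CLAV: 51 / 787,
            AGENT_OTHER: 533 / 787,
        }
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        total = sum(self.syndrome_probabilities.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"syndrome probabilities must sum to 1, got {total}")
        if set(self.syndrome_probabilities) != set(_SYNDROME_ORDER):
            raise ValueError("syndrome_probabilities must cover exactly the four syndromes")
        for prob in self.syndrome_probabilities.values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("syndrome probabilities must lie in [0,1]")
        if not math.isclose(sum(self.class_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must sum to 1")
        return self

    @property
    def inappropriate_fraction(self) -> float:
        """Configured probability a record is ASB without a treatment indication."""
        return self.syndrome_probabilities[ASB] * (1 - self.asb_procedural_indication_fraction)


def _sample_courses(config: CohortConfig, rng: np.random.Generator) -> list[AntibioticCourse]:
    classes = list(config.class_mix)
    mix = np.array([config.class_mix[c] for c in classes])
    n_courses = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
    chosen = rng.choice(len(classes), size=min(n_courses, len(classes)), replace=False, p=mix)
    courses = []
    for idx in chosen:
        agent = classes[int(idx)]
        mean = config.dot_distribution.get(agent, {"mean_days": 4.2})["mean_days"]
        days = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
        courses.append(AntibioticCourse(agent_class=agent, days_of_therapy=days))
    return courses


def _sample_urinalysis(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> UrinalysisResult:
    if rng.random() >= config.urinalysis_availability:
        return UrinalysisResult(available=False)
    markers = config.marker_probabilities[group]
    dist = config.leukocyte_count_distribution[group]
    return UrinalysisResult(
        available=True,
        leukocyturia=bool(rng.random() < markers["leukocyturia"]),
        bacteria_seen=bool(rng.random() < markers["bacteria_seen"]),
        nitrites_positive=bool(rng.random() < markers["nitrites_positive"]),
        leukocyte_count=round(float(np.exp(rng.normal(dist["mu"], dist["sigma"]))), 1),
    )


def generate(config: Optional[CohortConfig] = None) -> list[PatientRecord]:
    """Sample a synthetic cohort; identical seed gives an identical cohort.

    Records are mutually consistent with their syndrome: pyelonephritis
    records carry flank pain and/or fever without alternate explanation and
    are adjudicated truly needed; cystitis records carry dysuria without
    fever; other-infection records carry fever explained by the documented
    non-urinary source; ASB records are symptom-free (or carry altered
    mental status with a documented alternate cause) and truly need
    treatment only when a procedural indication is present.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    probs = np.array([config.syndrome_probabilities[s] for s in _SYNDROME_ORDER])
    records: list[PatientRecord] = []
    for i in range(config.n):
        syndrome = _SYNDROME_ORDER[int(rng.choice(len(_SYNDROME_ORDER), p=probs))]
        age = float(np.clip(round(rng.normal(60.5, 19.0), 1), 18.0, 98.0))
        sex = "female" if rng.random() < 75 / 124 else "male"
        special = SpecialIndication()
        symptoms = dict.fromkeys(
            (
                "urgency",
                "frequency",
                "dysuria",
                "suprapubic_pain",
                "pelvic_discomfort",
                "flank_pain",
                "fever",
                "clinical_instability",
                "acute_mental_status_change",
            ),
            False,
        )
        alternate: Optional[str] = None
        source: Optional[str] = None
        truly_needed = False
        group = "asb"

        if syndrome == PYELONEPHRITIS:
            group = "uti"
            truly_needed = True
            symptoms["flank_pain"] = bool(rng.random() < 0.6)
            symptoms["fever"] = bool(rng.random() < 0.7)
            if not (symptoms["flank_pain"] or symptoms["fever"]):
                symptoms["clinical_instability"] = True
        elif syndrome == CYSTITIS:
            group = "uti"
            truly_needed = True
            symptoms["dysuria"] = True
            symptoms["urgency"] = bool(rng.random() < 0.4)
            symptoms["frequency"] = bool(rng.random() < 0.4)
        elif syndrome == OTHER_INFECTION:
            source = str(rng.choice(NON_URINARY_SOURCES))
            symptoms["fever"] = True
            alternate = source
        else:  # ASB
            if rng.random() < config.asb_procedural_indication_fraction:
                special = SpecialIndication(pre_endourological_procedure=True)
                truly_needed = True
            if rng.random() < config.asb_altered_mental_status_fraction:
                symptoms["acute_mental_status_change"] = True
                alternate = str(rng.choice(_AMS_ETIOLOGIES))

        records.append(
            PatientRecord(
                record_id=f"S{i + 1:05d}",
                age_years=age,
                sex=sex,
                special=special,
                symptoms=SymptomSet(
                    **symptoms,
                    alternate_explanation_for_systemic=alternate,
                    poor_historian=bool(rng.random() < config.poor_historian_fraction),
                ),
                urinalysis=_sample_urinalysis(config, group, rng),
                courses=_sample_courses(config, rng),
                adjudication=AdjudicationFields(
                    documented_non_urinary_source=source,
                    urinary_pathogen_treatment_truly_needed=truly_needed,
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Deterministic study fixture
# ---------------------------------------------------------------------------


def _spread(total: int, n: int) -> list[int]:
    """Split ``total`` into ``n`` near-equal non-negative integers (desc order)."""
    base, extra = divmod(total, n)
    return [base + 1] * extra + [base] * (n - extra)


def _fixture_ages() -> list[float]:
    """124 sorted ages pinned to median 64 and IQR 46-74.25 (linear quantiles)."""
    ages: list[float] = []
    ages += [round(v, 1) for v in np.linspace(19.0, 45.0, 30)]        # ranks 0-29
    ages += [46.0, 46.0]                                              # ranks 30-31 -> Q1
    ages += [round(v, 1) for v in np.linspace(47.0, 63.0, 29)]        # ranks 32-60
    ages += [64.0, 64.0]                                              # ranks 61-62 -> median
    ages += [round(v, 1) for v in np.linspace(65.0, 73.5, 29)]        # ranks 63-91
    ages += [74.0, 75.0]                                              # ranks 92-93 -> Q3
    ages += [round(v, 1) for v in np.linspace(75.5, 97.0, 30)]        # ranks 94-123
    assert len(ages) == 124
    return ages


def _fixture_courses(n_records: int, quota_3gc: int, quota_ac: int, quota_other: int):
    """Fixed per-record course schedules hitting exact class-day quotas."""
    per_3gc = _spread(quota_3gc, n_records)
    per_other = _spread(quota_other, n_records)
    schedules = []
    for i in range(n_records):
        courses = []
        if per_3gc[i]:
            courses.append(
                AntibioticCourse(agent_class=AGENT_THIRD_GEN_CEPH, days_of_therapy=per_3gc[i])
            )
        if i < quota_ac:  # amoxicillin-clavulanate: one day to the first `quota_ac` records
            courses.append(AntibioticCourse(agent_class=AGENT_AMOX_CLAV, days_of_therapy=1))
        if per_other[i]:
            courses.append(AntibioticCourse(agent_class=AGENT_OTHER, days_of_therapy=per_other[i]))
        schedules.append(courses)
    return schedules


def build_fixture() -> list[PatientRecord]:
    """Compile the deterministic 124-record study cohort (no randomness).

    List layout: 50 pyelonephritis, 15 cystitis (first one pregnant), 13
    other infections (first pneumonia record is the concurrent-UTI false
    negative), 8 procedural-indication ASB, 38 ASB without indication
    (9 altered-mental-status with alternate etiologies, 2 shock with
    alternate explanations, 1 kidney-laceration trauma annotated in notes,
    26 symptom-free). Raises ``AssertionError`` if any printed marginal
    fails the built-in self-check.
    """
    specs: list[dict] = []

    # -- 50 pyelonephritis: 20 flank pain only, 20 flank pain + fever, 10 fever only
    for i in range(50):
        specs.append(
            {
                "syndrome": PYELONEPHRITIS,
                "symptoms": {
                    "flank_pain": i < 40,
                    "fever": i >= 20,
                },
                "truly_needed": True,
            }
        )

    # -- 15 cystitis: dysuria without fever; the first is the pregnant patient
    for i in range(15):
        specs.append(
            {
                "syndrome": CYSTITIS,
                "symptoms": {"dysuria": True, "urgency": i % 3 == 0, "frequency": i % 4 == 0},
                "pregnant": i == 0,
                "truly_needed": True,
            }
        )

    # -- 13 other infections; first pneumonia record is the false negative
    #    (E. coli bacteremia + bacteriuria: concurrent UTI found on full-stay review)
    other_sources = (
        ["pneumonia"] * 4
        + ["intra_abdominal"] * 4
        + ["osteomyelitis_decubitus"] * 2
        + ["covid19", "cellulitis", "epididymitis"]
    )
    for i, source in enumerate(other_sources):
        specs.append(
            {
                "syndrome": OTHER_INFECTION,
                "symptoms": {"fever": True},
                "alternate": source,
                "source": source,
                "truly_needed": i == 0,
                "notes": (
                    "E. coli bacteremia and bacteriuria during pneumonia treatment; "
                    "concurrent UTI on full-stay review"
                )
                if i == 0
                else "",
            }
        )

    # -- 8 ASB with a procedural treatment indication
    for _ in range(8):
        specs.append({"syndrome": ASB, "procedural": True, "truly_needed": True})

    # -- 38 ASB without indication (the inappropriately treated stratum)
    for i, etiology in enumerate(_AMS_ETIOLOGIES):  # 9 altered-mental-status cases
        specs.append(
            {
                "syndrome": ASB,
                "symptoms": {"acute_mental_status_change": True},
                "alternate": etiology,
                "truly_needed": False,
            }
        )
    for alternate in ("cardiac_arrest_cardiogenic_shock", "trauma_hypovolemic_shock"):
        specs.append(
            {
                "syndrome": ASB,
                "symptoms": {"clinical_instability": True},
                "alternate": alternate,
                "truly_needed": False,
            }
        )
    specs.append(
        {
            "syndrome": ASB,
            "truly_needed": False,
            # pelvic pain attributed to the trauma, not coded as a urinary symptom
            "notes": "pelvic pain after trauma with kidney laceration",
        }
    )
    for _ in range(26):
        specs.append({"syndrome": ASB, "truly_needed": False})

    assert len(specs) == 124

    # Poor historians (36 total): the 11 ASB cases with explained systemic
    # signs, 13 further symptom-free ASB cases, the 10 fever-only
    # pyelonephritis cases, and 2 other-infection cases. The study prints
    # only the total; this allocation is one consistent choice.
    poor_idx = set(range(86, 110)) | set(range(40, 50)) | {66, 67}
    assert len(poor_idx) == 36

    # Urinalysis: data available for 58 UTI cases (all pyelonephritis + 8
    # cystitis) and 27 ASB cases, mirroring the analyzed subgroups; values
    # follow fixed patterns of the observed magnitudes (not load-bearing).
    ua_uti = set(range(0, 58))
    ua_asb = set(range(86, 113))

    # Antibiotic-day schedules. Inappropriate stratum (records 86-123, 38
    # records): 91 third-generation-cephalosporin + 21 amoxicillin-
    # clavulanate + 153 other-class days = 265. Remaining 86 records:
    # 112 + 30 + 380 = 522. Totals: 787 = 203 + 51 + 533.
    approp_courses = _fixture_courses(86, 203 - 91, 51 - 21, 533 - 153)
    inapprop_courses = _fixture_courses(38, 91, 21, 153)

    ages_sorted = _fixture_ages()

    records: list[PatientRecord] = []
    for i, spec in enumerate(specs):
        symptoms = dict(spec.get("symptoms", {}))
        symptoms["poor_historian"] = i in poor_idx
        symptoms["alternate_explanation_for_systemic"] = spec.get("alternate")

        if i in ua_uti:
            urinalysis = UrinalysisResult(
                available=True,
                leukocyturia=i % 19 != 0,                  # ~95% positive
                bacteria_seen=i % 5 < 3,                   # ~60% positive
                nitrites_positive=i % 9 == 0,              # ~22% positive
                leukocyte_count=float(120 + (i * 157) % 2600),
            )
        elif i in ua_asb:
            j = i - 86
            urinalysis = UrinalysisResult(
                available=True,
                leukocyturia=j % 19 != 1,
                bacteria_seen=j % 3 < 2,                   # ~67% positive
                nitrites_positive=j % 6 == 0,              # ~19% positive
                leukocyte_count=float(25 + (j * 31) % 420),
            )
        else:
            urinalysis = UrinalysisResult(available=False)

        courses = inapprop_courses[i - 86] if i >= 86 else approp_courses[i]

        records.append(
            PatientRecord(
                record_id=f"F{i + 1:03d}",
                # ages scattered over strata by a fixed bijection (53 ⟂ 124)
                age_years=ages_sorted[(i * 53) % 124],
                # 75 female: all even ranks plus odd ranks <= 25
                sex="female" if (i % 2 == 0 or i <= 25) else "male",
                special=SpecialIndication(
                    pregnant=bool(spec.get("pregnant", False)),
                    pre_endourological_procedure=bool(spec.get("procedural", False)),
                ),
                symptoms=SymptomSet(**symptoms),
                urinalysis=urinalysis,
                courses=courses,
                adjudication=AdjudicationFields(
                    documented_non_urinary_source=spec.get("source"),
                    urinary_pathogen_treatment_truly_needed=spec["truly_needed"],
                    notes=spec.get("notes", ""),
                ),
            )
        )

    _verify_fixture(records)
    return records


def _verify_fixture(records: list[PatientRecord]) -> None:
    """Assert every printed study marginal on the compiled fixture."""
    from .accuracy import confusion  # deferred: accuracy imports nothing from here
    from .burden import burden

    assert len(records) == 124
    assert len({r.record_id for r in records}) == 124

    labels = [classify_syndrome(r) for r in records]
    counts = {s: sum(1 for l in labels if l.label == s) for s in _SYNDROME_ORDER}
    assert counts == {PYELONEPHRITIS: 50, CYSTITIS: 15, OTHER_INFECTION: 13, ASB: 46}, counts
    assert sum(1 for l in labels if l.asb_with_treatment_indication) == 8

    flags = [inappropriate_treatment_flag(r, l) for r, l in zip(records, labels)]
    assert sum(flags) == 38
    assert sum(1 for r in records if r.symptoms.poor_historian) == 36
    assert (
        sum(
            1
            for r, l in zip(records, labels)
            if l.label == ASB
            and r.symptoms.acute_mental_status_change
            and r.symptoms.alternate_explanation_for_systemic is not None
        )
        == 9
    )

    decisions = evaluate_cohort(records)
    cm = confusion(decisions, [true_need(r) for r in records])
    assert (cm.tp, cm.fp, cm.fn, cm.tn) == (73, 0, 1, 50), cm

    summary = burden(records, flags)
    assert summary.total_days == 787 and summary.unjustified_days == 265, summary
    assert summary.by_class[AGENT_THIRD_GEN_CEPH] == (203, 91)
    assert summary.by_class[AGENT_AMOX_CLAV] == (51, 21)

    ages = np.array([r.age_years for r in records])
    assert float(np.median(ages)) == 64.0
    q1, q3 = np.percentile(ages, [25, 75])
    assert (float(q1), float(q3)) == (46.0, 74.25), (q1, q3)

    assert sum(1 for r in records if r.sex == "female") == 75
    pregnant = [r for r in records if r.special.pregnant]
    assert len(pregnant) == 1
    assert classify_syndrome(pregnant[0]).label == CYSTITIS
    assert all(r.age_years >= 18.0 for r in records)
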