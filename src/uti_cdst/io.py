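"""Cohort I/O: delimited tabular and structured-record (JSON) formats.

The tabular dialect is comma-separated UTF-8 with one header row. The
missing-value token is the *empty cell*, which is distinct from an explicit
``false``: the study design distinguishes "no symptoms documented" from
"patient unable to report" (poor historian), so absence must be
representable. Booleans are serialized as literal ``true``/``false``
strings (case-insensitive on read) to avoid 0/1-vs-blank ambiguity.

Antibiotic courses are flattened as up to three repeated column groups
``agent_class_k`` / ``dot_k`` plus an ``other_dot`` spillover; courses
beyond three are merged under the class label "other". Multiple courses of
the same class are summed on read (day totals are class-level).

Round-trip is lossless for every field, including absent optionals, for
records with at most three courses.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from pydantic import ValidationError

from .models import (
    AdjudicationFields,
    AdmissionMetadata,
    AGENT_OTHER,
    AntibioticCourse,
    LOCALIZED_SYMPTOMS,
    PatientRecord,
    SpecialIndication,
    SymptomSet,
    UrinalysisResult,
)

logger = logging.getLogger(__name__)

MISSING = ""  # the tabular missing-value token: an empty cell

_N_COURSE_SLOTS = 3

_SPECIAL_FIELDS = ("pregnant", "pre_endourological_procedure", "renal_transplant_within_60_days")
_SYMPTOM_BOOL_FIELDS = (
    "urgency",
    "frequency",
    "dysuria",
    "suprapubic_pain",
    "pelvic_discomfort",
    "flank_pain",
    "fever",
    "clinical_instability",
    "acute_mental_status_change",
    "poor_historian",
)

TABULAR_COLUMNS = (
    "record_id",
    "age_years",
    "sex",
    *_SPECIAL_FIELDS,
    *_SYMPTOM_BOOL_FIELDS[:-1],
    "alternate_explanation_for_systemic",
    "poor_historian",
    "urinalysis_available",
    "leukocyturia",
    "bacteria_seen",
    "nitrites_positive",
    "leukocyte_count",
    *(f"agent_class_{k}" for k in range(1, _N_COURSE_SLOTS + 1)),
    *(f"dot_{k}" for k in range(1, _N_COURSE_SLOTS + 1)),
    "other_dot",
    "documented_non_urinary_source",
    "truly_needed",
    "notes",
)


class CohortParseError(ValueError):
    """Malformed file content; carries the offending line number."""


class CohortValidationError(ValueError):
    """Structurally parseable but semantically invalid cohort."""


def _parse_bool(token: str) -> Optional[bool]:
    t = token.strip().lower()
    if t == MISSING:
        return None
    if t == "true":
        return True
    if t == "false":
        return False
    raise ValueError(f"not a boolean literal: {token!r}")


def _fmt_bool(value: Optional[bool]) -> str:
    return MISSING if value is None else ("true" if value else "false")


def _fmt_opt(value) -> str:
    return MISSING if value is None else str(value)


def _record_to_row(record: PatientRecord) -> dict[str, str]:
    row = {
        "record_id": record.record_id,
        "age_years": str(record.age_years),
        "sex": record.sex,
        "alternate_explanation_for_systemic": _fmt_opt(
            record.symptoms.alternate_explanation_for_systemic
        ),
        "urinalysis_available": _fmt_bool(record.urinalysis.available),
        "leukocyturia": _fmt_bool(record.urinalysis.leukocyturia),
        "bacteria_seen": _fmt_bool(record.urinalysis.bacteria_seen),
        "nitrites_positive": _fmt_bool(record.urinalysis.nitrites_positive),
        "leukocyte_count": _fmt_opt(record.urinalysis.leukocyte_count),
        "documented_non_urinary_source": _fmt_opt(
            record.adjudication.documented_non_urinary_source
        ),
        "truly_needed": _fmt_bool(record.adjudication.urinary_pathogen_treatment_truly_needed),
        "notes": record.adjudication.notes,
    }
    for name in _SPECIAL_FIELDS:
        row[name] = _fmt_bool(getattr(record.special, name))
    for name in _SYMPTOM_BOOL_FIELDS:
        row[name] = _fmt_bool(getattr(record.symptoms, name))
    spill = 0
    for k in range(1, _N_COURSE_SLOTS + 1):
        row[f"agent_class_{k}"] = MISSING
        row[f"dot_{k}"] = MISSING
    for i, course in enumerate(record.courses):
        if i < _N_COURSE_SLOTS:
            row[f"agent_class_{i + 1}"] = course.agent_class
            row[f"dot_{i + 1}"] = str(course.days_of_therapy)
        else:
            spill += course.days_of_therapy
    row["other_dot"] = str(spill) if spill else MISSING
    return row


def _merge_courses(pairs: Iterable[tuple[str, int]]) -> list[AntibioticCourse]:
    """Sum day counts per agent class, preserving first-seen class order."""
    totals: "OrderedDict[str, int]" = OrderedDict()
    for agent, days in pairs:
        totals[agent] = totals.get(agent, 0) + days
    return [AntibioticCourse(agent_class=a, days_of_therapy=d) for a, d in totals.items()]


def _row_to_record(row: Mapping[str, str], line_no: int) -> PatientRecord:
    rid = (row.get("record_id") or "").strip()
    if not rid:
        raise CohortParseError(f"line {line_no}: missing mandatory field 'record_id'")

    def mandatory(field: str) -> str:
        value = (row.get(field) or "").strip()
        if value == MISSING:
            raise CohortParseError(
                f"line {line_no}: record {rid!r} missing mandatory field {field!r}"
            )
        return value

    def optional_bool(field: str, default: Optional[bool] = None) -> Optional[bool]:
        try:
            value = _parse_bool(row.get(field) or "")
        except ValueError:
            logger.warning(
                "record %s: unparseable %s=%r treated as absent", rid, field, row.get(field)
            )
            return default
        return default if value is None else value

    try:
        age = float(mandatory("age_years"))
    except ValueError as exc:
        raise CohortParseError(f"line {line_no}: record {rid!r} bad age_years") from exc
    sex = mandatory("sex").lower()

    special_kwargs = {}
    for name in _SPECIAL_FIELDS:
        value = optional_bool(name)
        if value is None:
            logger.warning(
                "record %s: special indication %s undocumented; coded false", rid, name
            )
            value = False
        special_kwargs[name] = value

    symptom_kwargs = {name: optional_bool(name, default=False) for name in _SYMPTOM_BOOL_FIELDS}
    alt = (row.get("alternate_explanation_for_systemic") or "").strip()
    symptom_kwargs["alternate_explanation_for_systemic"] = alt or None
    if symptom_kwargs["poor_historian"] and not any(
        symptom_kwargs[name] for name in LOCALIZED_SYMPTOMS
    ):
        logger.info(
            "record %s: poor historian with no localized flags — localized symptoms are "
            "not documentable rather than absent",
            rid,
        )

    available = optional_bool("urinalysis_available", default=False)
    if available:
        count_token = (row.get("leukocyte_count") or "").strip()
        count: Optional[float] = None
        if count_token:
            try:
                count = float(count_token)
            except ValueError:
                logger.warning(
                    "record %s: unparseable leukocyte_count=%r treated as absent",
                    rid,
                    count_token,
                )
        urinalysis = UrinalysisResult(
            available=True,
            leukocyturia=optional_bool("leukocyturia"),
            bacteria_seen=optional_bool("bacteria_seen"),
            nitrites_positive=optional_bool("nitrites_positive"),
            leukocyte_count=count,
        )
    else:
        urinalysis = UrinalysisResult(available=False)

    pairs: list[tuple[str, int]] = []
    for k in range(1, _N_COURSE_SLOTS + 1):
        agent = (row.get(f"agent_class_{k}") or "").strip()
        dot = (row.get(f"dot_{k}") or "").strip()
        if not agent and not dot:
            continue
        if not agent or not dot:
            raise CohortParseError(
                f"line {line_no}: record {rid!r} course slot {k} is half-filled"
            )
        try:
            pairs.append((agent, int(dot)))
        except ValueError as exc:
            raise CohortParseError(
                f"line {line_no}: record {rid!r} bad day count in dot_{k}"
            ) from exc
    other = (row.get("other_dot") or "").strip()
    if other:
        try:
            pairs.append((AGENT_OTHER, int(other)))
        except ValueError as exc:
            raise CohortParseError(f"line {line_no}: record {rid!r} bad other_dot") from exc

    truly = _parse_bool(mandatory("truly_needed"))
    source = (row.get("documented_non_urinary_source") or "").strip() or None

    try:
        return PatientRecord(
            record_id=rid,
            age_years=age,
            sex=sex,
            special=SpecialIndication(**special_kwargs),
            symptoms=SymptomSet(**symptom_kwargs),
            urinalysis=urinalysis,
            courses=_merge_courses(pairs),
            adjudication=AdjudicationFields(
                documented_non_urinary_source=source,
                urinary_pathogen_treatment_truly_needed=truly,
                notes=(row.get("notes") or ""),
            ),
        )
    except ValidationError as exc:
        raise CohortValidationError(f"line {line_no}: record {rid!r}: {exc}") from exc


def read_cohort(path: Union[str, Path], format: str = "tabular") -> list[PatientRecord]:
    """Read a cohort file into a list of :class:`PatientRecord`, in file order.

    Unparseable optional fields become absent with a logged warning; a
    missing mandatory field raises :class:`CohortParseError` naming the
    record and field; a duplicate ``record_id`` raises
    :class:`CohortValidationError`.
    """
    path = Path(path)
    if format == "structured":
        with path.open(encoding="utf-8") as handle:
            try:
                payload = json.load(handle)
            except json.JSONDecodeError as exc:
                raise CohortParseError(f"line {exc.lineno}: {exc.msg}") from exc
        if not isinstance(payload, list):
            raise CohortParseError("structured cohort must be a JSON array of patient objects")
        try:
            records = [PatientRecord.model_validate(obj) for obj in payload]
        except ValidationError as exc:
            raise CohortValidationError(str(exc)) from exc
    elif format == "tabular":
        records = []
        with path.open(encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None:
                return []
            unknown = set(reader.fieldnames) - set(TABULAR_COLUMNS)
            if unknown:
                logger.warning("ignoring unknown columns: %s", sorted(unknown))
            for row in reader:
                records.append(_row_to_record(row, reader.line_num))
    else:
        raise ValueError(f"unknown cohort format {format!r}")

    seen: set[str] = set()
    for record in records:
        if record.record_id in seen:
            raise CohortValidationError(f"duplicate record_id {record.record_id!r}")
        seen.add(record.record_id)
    return records


def write_cohort(
    records: Iterable[PatientRecord], path: Union[str, Path], format: str = "tabular"
) -> None:
    """Serialize a cohort; ``read_cohort(write_cohort(x))`` reproduces ``x``."""
    path = Path(path)
    records = list(records)
    if format == "structured":
        payload = [record.model_dump(mode="json") for record in records]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    elif format == "tabular":
        with path.open("w", encoding="utf-8", newline="") as handle:
            writer = csv.DictWriter(handle, fieldnames=TABULAR_COLUMNS)
            writer.writeheader()
            for record in records:
                writer.writerow(_record_to_row(record))
    else:
        raise ValueError(f"unknown cohort format {format!r}")


def apply_eligibility(
    records: Iterable[PatientRecord],
    metadata: Optional[Mapping[str, AdmissionMetadata]] = None,
) -> list[PatientRecord]:
    """Apply the study's eligibility filter, preserving order.

    Retains adults (age >= 18) who were admitted (not discharged from the
    emergency department), not on 24-hour observation, and not on a onetime
    antibiotic order. Records without admission metadata are assumed to be
    ordinary inpatient admissions. Idempotent; exclusion counts are logged.
    """
    metadata = metadata or {}
    kept: list[PatientRecord] = []
    reasons = {"age_under_18": 0, "ed_discharge": 0, "observation_only": 0, "onetime_order": 0}
    for record in records:
        meta = metadata.get(record.record_id, AdmissionMetadata())
        if record.age_years < 18.0:
            reasons["age_under_18"] += 1
        elif not meta.admitted:
            reasons["ed_discharge"] += 1
        elif meta.observation_only:
            reasons["observation_only"] += 1
        elif meta.onetime_order:
            reasons["onetime_order"] += 1
        else:
            kept.append(record)
    excluded = sum(reasons.values())
    if excluded:
        logger.info("eligibility filter excluded %d records: %s", excluded, reasons)
    return kept
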