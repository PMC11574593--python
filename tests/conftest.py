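import pytest

from uti_cdst import (
    AdjudicationFields,
    PatientRecord,
    SpecialIndication,
    SymptomSet,
    build_fixture,
)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 124-record study cohort."""
    return build_fixture()


def make_record(
    record_id="R1",
    age=60.0,
    sex="female",
    special=None,
    symptoms=None,
    truly_needed=False,
    source=None,
    courses=(),
    notes="",
):
    """Minimal valid record with everything defaulted to negative/absent."""
    return PatientRecord(
        record_id=record_id,
        age_years=age,
        sex=sex,
        special=SpecialIndication(**(special or {})),
        symptoms=SymptomSet(**(symptoms or {})),
        courses=list(courses),
        adjudication=AdjudicationFields(
            documented_non_urinary_source=source,
            urinary_pathogen_treatment_truly_needed=truly_needed,
            notes=notes,
        ),
    )
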