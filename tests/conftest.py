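import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from morbiscan.codes import CodeSystem, normalize
from morbiscan.records import Diagnosis, DiagnosisRole, EncounterRecord, PersonHistory
from morbiscan.registry import Source, load_default_registry

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=150,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


def make_encounter(
    record_id,
    date,
    source=Source.HOSPITALIZATION,
    codes=("25001",),
    system=CodeSystem.ICD9CM,
    role=DiagnosisRole.OTHER,
    person_id="p1",
    specialty="",
    ed_flag=False,
    procedures=(),
):
    """Compact encounter-record builder for tests."""
    if isinstance(codes, str):
        codes = (codes,)
    diagnoses = tuple(
        Diagnosis(code=normalize(c, system), role=role) if isinstance(c, str) else Diagnosis(*c)
        for c in codes
    )
    return EncounterRecord(
        record_id=record_id,
        person_id=person_id,
        date=date if isinstance(date, dt.date) else dt.date.fromisoformat(date),
        source=source,
        diagnoses=diagnoses,
        specialty=specialty,
        ed_flag=ed_flag,
        procedures=tuple(procedures),
    )


def history(*encounters, labs=(), person_id="p1"):
    return PersonHistory(
        person_id=person_id,
        encounters=tuple(sorted(encounters, key=lambda r: (r.date, r.record_id))),
        labs=tuple(sorted(labs, key=lambda l: (l.date, l.analyte.value, l.value))),
    )
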