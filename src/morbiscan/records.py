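"""Data model and CSV I/O for encounter, laboratory, and demographic inputs.

Input files are plain (optionally gzip-compressed) CSV:

``encounters.csv``
    record_id,person_id,date,source,dx_codes,specialty,ed_flag,procedures
    where ``dx_codes`` is a pipe-separated list of ``system:code:role``
    triplets (role M = most responsible, 2 = post-admit, O = other; role
    may be omitted and defaults to O) and ``procedures`` is a
    pipe-separated list of procedure codes.
``labs.csv``
    person_id,date,analyte,value  (analyte EGFR in mL/min/1.73 m2, ACR in mg/g)
``demographics.csv``
    person_id,birth_date,sex  (sex F/M/U)

Dates are ISO-8601 calendar dates.  Malformed rows are rejected row-by-row
and collected in a :class:`RejectReport`; a missing mandatory column is a
hard error.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from dateutil.relativedelta import relativedelta

from .codes import CodeSystem, NormalizedCode, normalize
from .registry import Source

__all__ = [
    "DiagnosisRole",
    "Sex",
    "Analyte",
    "Diagnosis",
    "EncounterRecord",
    "LabResult",
    "PersonDemographics",
    "PersonHistory",
    "RejectReport",
    "read_encounters",
    "read_labs",
    "read_demographics",
    "write_encounters",
    "write_labs",
    "write_demographics",
    "build_histories",
    "filter_cohort",
]


class DiagnosisRole(str, enum.Enum):
    MOST_RESPONSIBLE = "M"
    POST_ADMIT = "2"
    OTHER = "O"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    U = "U"


class Analyte(str, enum.Enum):
    EGFR = "EGFR"
    ACR = "ACR"


@dataclass(frozen=True, slots=True)
class Diagnosis:
    code: NormalizedCode
    role: DiagnosisRole = DiagnosisRole.OTHER


@dataclass(frozen=True, slots=True)
class EncounterRecord:
    """One dated coded event from one administrative source."""

    record_id: str
    person_id: str
    date: dt.date
    source: Source
    diagnoses: tuple[Diagnosis, ...]
    specialty: str = ""  # claims only; case-folded
    ed_flag: bool = False  # ambulatory only
    procedures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.source, Source):
            object.__setattr__(self, "source", _SOURCE_ALIASES[str(self.source).strip().upper()])
        if not self.diagnoses:
            raise ValueError(f"record {self.record_id!r}: at least one diagnosis required")


@dataclass(frozen=True, slots=True)
class LabResult:
    person_id: str
    date: dt.date
    analyte: Analyte
    value: float

    def __post_init__(self) -> None:
        if not isinstance(self.analyte, Analyte):
            object.__setattr__(self, "analyte", Analyte(str(self.analyte).strip().upper()))
        if not self.value > 0:
            raise ValueError(f"lab result for {self.person_id!r}: value must be positive")


@dataclass(frozen=True, slots=True)
class PersonDemographics:
    person_id: str
    birth_date: Optional[dt.date]
    sex: Sex = Sex.U


@dataclass(frozen=True, slots=True)
class PersonHistory:
    """All of one person's records, date-sorted (stable by record id)."""

    person_id: str
    encounters: tuple[EncounterRecord, ...] = ()
    labs: tuple[LabResult, ...] = ()


@dataclass
class RejectReport:
    """Row-level rejects collected while reading input files."""

    rows: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, filename: str, row_number: int, reason: str) -> None:
        self.rows.append((filename, row_number, reason))

    def __len__(self) -> int:
        return len(self.rows)

    def render(self) -> str:
        if not self.rows:
            return "no rejected rows"
        return "\n".join(f"{f}:{n}: {r}" for f, n, r in self.rows)


_SOURCE_ALIASES = {
    "HOSPITALIZATION": Source.HOSPITALIZATION,
    "HOSP": Source.HOSPITALIZATION,
    "CLAIM": Source.CLAIM,
    "CLAIMS": Source.CLAIM,
    "AMBULATORY": Source.AMBULATORY,
    "ACCS": Source.AMBULATORY,
}

_TRUE = {"1", "TRUE", "T", "Y", "YES"}
_FALSE = {"", "0", "FALSE", "F", "N", "NO"}


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


def _check_header(reader: csv.DictReader, required: Iterable[str], filename: str) -> None:
    have = set(reader.fieldnames or ())
    missing = [c for c in required if c not in have]
    if missing:
        raise ValueError(f"{filename}: missing mandatory column(s): {', '.join(missing)}")


def _parse_dx_codes(text: str) -> tuple[Diagnosis, ...]:
    out = []
    for triplet in text.split("|"):
        triplet = triplet.strip()
        if not triplet:
            continue
        parts = triplet.split(":")
        if len(parts) == 2:
            system, code = parts
            role = "O"
        elif len(parts) == 3:
            system, code, role = parts
        else:
            raise ValueError(f"malformed dx triplet {triplet!r}")
        out.append(
            Diagnosis(
                code=normalize(code, CodeSystem(system.strip().upper())),
                role=DiagnosisRole(role.strip().upper() or "O"),
            )
        )
    if not out:
        raise ValueError("no diagnosis codes")
    return tuple(out)


def _norm_proc(p: str) -> str:
    return p.strip().upper().replace(".", "")


def read_encounters(path: str | Path, rejects: Optional[RejectReport] = None):
    """Read encounter records from CSV.  Returns ``(records, rejects)``.

    Well-formed rows yield one record each, with diagnosis codes normalized
    on ingest; malformed rows (bad date, unknown source, no diagnoses, ...)
    are collected in the reject report.  When ``record_id`` is empty the row
    number is used.
    """
    rejects = rejects if rejects is not None else RejectReport()
    name = Path(path).name
    records: list[EncounterRecord] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, ["record_id", "person_id", "date", "source", "dx_codes"], name)
        for i, row in enumerate(reader, start=2):
            try:
                source = _SOURCE_ALIASES[row["source"].strip().upper()]
                ed_raw = (row.get("ed_flag") or "").strip().upper()
                if ed_raw in _TRUE:
                    ed = True
                elif ed_raw in _FALSE:
                    ed = False
                else:
                    raise ValueError(f"bad ed_flag {ed_raw!r}")
                records.append(
                    EncounterRecord(
                        record_id=row["record_id"].strip() or f"row{i}",
                        person_id=row["person_id"].strip(),
                        date=dt.date.fromisoformat(row["date"].strip()),
                        source=source,
                        diagnoses=_parse_dx_codes(row["dx_codes"]),
                        specialty=(row.get("specialty") or "").strip().casefold(),
                        ed_flag=ed,
                        procedures=tuple(
                            _norm_proc(p) for p in (row.get("procedures") or "").split("|") if p.strip()
                        ),
                    )
                )
            except (KeyError, ValueError) as e:
                rejects.add(name, i, str(e))
    return records, rejects


def read_labs(path: str | Path, rejects: Optional[RejectReport] = None):
    rejects = rejects if rejects is not None else RejectReport()
    name = Path(path).name
    labs: list[LabResult] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, ["person_id", "date", "analyte", "value"], name)
        for i, row in enumerate(reader, start=2):
            try:
                labs.append(
                    LabResult(
                        person_id=row["person_id"].strip(),
                        date=dt.date.fromisoformat(row["date"].strip()),
                        analyte=Analyte(row["analyte"].strip().upper()),
                        value=float(row["value"]),
                    )
                )
            except ValueError as e:
                rejects.add(name, i, str(e))
    return labs, rejects


def read_demographics(path: str | Path, rejects: Optional[RejectReport] = None):
    rejects = rejects if rejects is not None else RejectReport()
    name = Path(path).name
    out: dict[str, PersonDemographics] = {}
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        _check_header(reader, ["person_id", "birth_date", "sex"], name)
        for i, row in enumerate(reader, start=2):
            try:
                pid = row["person_id"].strip()
                bd_raw = row["birth_date"].strip()
                out[pid] = PersonDemographics(
                    person_id=pid,
                    birth_date=dt.date.fromisoformat(bd_raw) if bd_raw else None,
                    sex=Sex((row["sex"].strip().upper() or "U")),
                )
            except ValueError as e:
                rejects.add(name, i, str(e))
    return out, rejects


def write_encounters(records: Iterable[EncounterRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["record_id", "person_id", "date", "source", "dx_codes",
                    "specialty", "ed_flag", "procedures"])
        for r in records:
            dx = "|".join(f"{d.code.system.value}:{d.code.text}:{d.role.value}" for d in r.diagnoses)
            w.writerow([r.record_id, r.person_id, r.date.isoformat(), r.source.value,
                        dx, r.specialty, int(r.ed_flag), "|".join(r.procedures)])


def write_labs(labs: Iterable[LabResult], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["person_id", "date", "analyte", "value"])
        for l in labs:
            w.writerow([l.person_id, l.date.isoformat(), l.analyte.value, f"{l.value:g}"])


def write_demographics(demographics: Iterable[PersonDemographics], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["person_id", "birth_date", "sex"])
        for d in demographics:
            w.writerow([d.person_id, d.birth_date.isoformat() if d.birth_date else "", d.sex.value])


def build_histories(
    encounters: Iterable[EncounterRecord],
    labs: Iterable[LabResult] = (),
    demographics: Optional[dict[str, PersonDemographics]] = None,
):
    """Group records into per-person histories.

    Partition-complete: every input record lands in exactly one history.
    Histories are sorted by date (ties broken by record id, so the result is
    independent of input order).  Returns ``(histories, missing_demographics)``
    where the second element lists person ids seen in the records but absent
    from ``demographics`` (they are kept, only flagged).
    """
    enc_by_person: dict[str, list[EncounterRecord]] = {}
    labs_by_person: dict[str, list[LabResult]] = {}
    for r in encounters:
        enc_by_person.setdefault(r.person_id, []).append(r)
    for l in labs:
        labs_by_person.setdefault(l.person_id, []).append(l)
    histories: dict[str, PersonHistory] = {}
    for pid in sorted(set(enc_by_person) | set(labs_by_person)):
        histories[pid] = PersonHistory(
            person_id=pid,
            encounters=tuple(sorted(enc_by_person.get(pid, []), key=lambda r: (r.date, r.record_id))),
            labs=tuple(sorted(labs_by_person.get(pid, []),
                              key=lambda l: (l.date, l.analyte.value, l.value))),
        )
    missing = []
    if demographics is not None:
        missing = [pid for pid in histories if pid not in demographics]
    return histories, missing


def age_at(birth_date: dt.date, on: dt.date) -> int:
    """Completed years of age on a given date."""
    return relativedelta(on, birth_date).years


def filter_cohort(
    histories: dict[str, PersonHistory],
    demographics: dict[str, PersonDemographics],
    as_of: dt.date,
    min_age: int = 18,
):
    """Retain persons aged >= ``min_age`` completed years at ``as_of``.

    Persons without a known birth date cannot be age-checked and are
    excluded; their ids are returned separately.
    """
    kept: dict[str, PersonHistory] = {}
    no_birth_date: list[str] = []
    for pid, hist in histories.items():
        demo = demographics.get(pid)
        if demo is None or demo.birth_date is None:
            no_birth_date.append(pid)
            continue
        if age_at(demo.birth_date, as_of) >= min_age:
            kept[pid] = hist
    return kept, no_birth_date
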