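"""Reproducible synthetic cohorts with planted per-person condition truth.

The generator emulates the *structure* of multi-source coded encounter data
— hospital discharge abstracts with typed diagnosis roles, physician claims
with provider specialty, ambulatory/ED records, and laboratory results —
without attempting billing-level realism.  For each person and condition it
plants, with configured probabilities, one of:

CASE           a record chain that minimally satisfies one evidence rule
               (exactly ``min_count`` records, span strictly inside the
               window, restrictions honoured);
NEAR_MISS      a chain violating exactly one requirement (one record short,
               one day beyond the window, wrong diagnosis role, wrong
               specialty, or surgery-tainted hospitalization);
EXCLUDED_CASE  a qualifying chain plus an unconditional-exclusion code
               (only for conditions that define such exclusions).

Construction guarantees exact recoverability: planted codes are
instantiated to full-length descendants that match no *other* condition's
code set (code families shared between conditions are avoided), noise codes
match no condition at all, and condition pairs whose code sets would
trigger each other's exclusions are never co-planted in one person.  Truth
is defined with respect to ascertainment over all sources plus labs.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codes import CodePattern, CodeSystem, NormalizedCode, matches
from .engine import AscertainmentResult
from .records import (
    Analyte,
    Diagnosis,
    DiagnosisRole,
    EncounterRecord,
    LabResult,
    PersonDemographics,
    PersonHistory,
    Sex,
    write_demographics,
    write_encounters,
    write_labs,
)
from .registry import (
    ConditionDefinition,
    ConditionRegistry,
    DxRole,
    EvidenceRule,
    Source,
    WindowConvention,
    load_default_registry,
    with_surgery_procedures,
)

__all__ = [
    "PlantStatus",
    "Violation",
    "SimulationConfig",
    "Planted",
    "CohortTruth",
    "SyntheticCohort",
    "CohortGenerator",
    "generate",
    "recovery_report",
    "RecoveryReport",
]


class PlantStatus(str, enum.Enum):
    CASE = "CASE"
    NEAR_MISS = "NEAR_MISS"
    EXCLUDED_CASE = "EXCLUDED_CASE"


class Violation(str, enum.Enum):
    ONE_SHORT = "ONE_SHORT"
    WINDOW_PLUS_ONE_DAY = "WINDOW_PLUS_ONE_DAY"
    WRONG_ROLE = "WRONG_ROLE"
    WRONG_SPECIALTY = "WRONG_SPECIALTY"
    SURGERY_TAINTED = "SURGERY_TAINTED"


LAB_RULE_ID = "lab"

# Benign candidate codes for noise records; filtered at generator start so
# that none matches any registry include, exclusion, companion, or aux code.
_NOISE_CANDIDATES = {
    CodeSystem.ICD10: ["Z000", "J069", "S7200", "R51", "L239", "H6690",
                       "K021", "T784", "M1700", "O80", "B349", "A090"],
    CodeSystem.ICD9CM: ["V700", "4659", "84500", "5259", "3829", "78400",
                        "0088", "52100", "9953"],
}

_BENIGN_SPECIALTIES = ("internal medicine", "family practice", "orthopedics")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    ``prevalence`` maps condition id to the probability of planting a CASE
    (default 0.04 for every condition); ``near_miss_rate`` and
    ``excluded_case_rate`` are per person-condition probabilities;
    ``noise_rate`` is the expected number of non-matching singleton codes
    per person-year and ``lab_noise_rate`` the expected number of
    normal-range laboratory results per person-year (persons with planted
    kidney-disease chains receive no extra labs, so planted lab means are
    never diluted).
    """

    n_persons: int = 1000
    seed: int = 0
    period: tuple[dt.date, dt.date] = (dt.date(2008, 4, 1), dt.date(2009, 3, 31))
    data_start: dt.date = dt.date(2004, 4, 1)
    prevalence: Optional[dict[str, float]] = None
    default_prevalence: float = 0.04
    near_miss_rate: float = 0.02
    excluded_case_rate: float = 0.02
    noise_rate: float = 1.0
    lab_noise_rate: float = 0.3
    rule_weights: Optional[dict[str, dict[str, float]]] = None
    surgery_procedure_codes: tuple[str, ...] = ("CCP871", "CCP902")
    min_age: int = 18
    max_age: int = 90
    convention: WindowConvention = WindowConvention.CALENDAR

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for name in ("default_prevalence", "near_miss_rate", "excluded_case_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for pid, p in (self.prevalence or {}).items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {pid!r} must be a probability, got {p}")
        if self.noise_rate < 0 or self.lab_noise_rate < 0:
            raise ValueError("noise rates must be non-negative")
        if (self.period[1] - self.data_start).days < 1200:
            raise ValueError("data_start must precede the period end by at least 1200 days")


@dataclass(frozen=True)
class Planted:
    condition_id: str
    status: PlantStatus
    rule_id: str
    violation: Optional[Violation] = None
    index_date: Optional[dt.date] = None
    record_ids: tuple[str, ...] = ()


@dataclass
class CohortTruth:
    """Planted condition labels per person (the generator's ground truth)."""

    persons: dict[str, list[Planted]]

    def to_json(self) -> dict:
        return {
            "persons": {
                pid: [
                    {
                        "condition_id": p.condition_id,
                        "status": p.status.value,
                        "rule": p.rule_id,
                        "violation": p.violation.value if p.violation else None,
                        "index_date": p.index_date.isoformat() if p.index_date else None,
                        "record_ids": list(p.record_ids),
                    }
                    for p in plants
                ]
                for pid, plants in self.persons.items()
            }
        }

    @classmethod
    def from_json(cls, doc: dict) -> "CohortTruth":
        persons = {}
        for pid, plants in doc["persons"].items():
            persons[pid] = [
                Planted(
                    condition_id=p["condition_id"],
                    status=PlantStatus(p["status"]),
                    rule_id=p["rule"],
                    violation=Violation(p["violation"]) if p.get("violation") else None,
                    index_date=dt.date.fromisoformat(p["index_date"]) if p.get("index_date") else None,
                    record_ids=tuple(p.get("record_ids", ())),
                )
                for p in plants
            ]
        return cls(persons=persons)


@dataclass
class SyntheticCohort:
    encounters: list[EncounterRecord]
    labs: list[LabResult]
    demographics: dict[str, PersonDemographics]
    truth: CohortTruth
    registry: ConditionRegistry  # registry with the configured surgery codes
    config: SimulationConfig

    def histories(self) -> dict[str, PersonHistory]:
        from .records import build_histories

        hist, _ = build_histories(self.encounters, self.labs, self.demographics)
        # persons with no records at all still belong to the cohort
        for pid in self.demographics:
            hist.setdefault(pid, PersonHistory(person_id=pid))
        return hist

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "encounters": out / "encounters.csv",
            "labs": out / "labs.csv",
            "demographics": out / "demographics.csv",
            "truth": out / "truth.json",
        }
        write_encounters(self.encounters, paths["encounters"])
        write_labs(self.labs, paths["labs"])
        write_demographics(
            sorted(self.demographics.values(), key=lambda d: d.person_id), paths["demographics"]
        )
        paths["truth"].write_text(json.dumps(self.truth.to_json(), indent=0, sort_keys=True) + "\n")
        return paths


def _role_for(restriction: DxRole, rng: np.random.Generator) -> DiagnosisRole:
    if restriction is DxRole.MOST_RESPONSIBLE:
        return DiagnosisRole.MOST_RESPONSIBLE
    if restriction is DxRole.MOST_RESPONSIBLE_OR_POST_ADMIT:
        return (DiagnosisRole.MOST_RESPONSIBLE, DiagnosisRole.POST_ADMIT)[int(rng.integers(2))]
    return (DiagnosisRole.OTHER, DiagnosisRole.MOST_RESPONSIBLE)[int(rng.integers(2))]


class CohortGenerator:
    """Deterministic planted-truth cohort generator.

    All randomness flows through one seeded ``numpy`` generator, so equal
    configurations produce byte-identical output files.
    """

    def __init__(self, config: SimulationConfig, registry: Optional[ConditionRegistry] = None):
        self.config = config
        base = registry if registry is not None else load_default_registry()
        self.registry = with_surgery_procedures(base, config.surgery_procedure_codes)
        known = set(self.registry.ids)
        for pid in (config.prevalence or {}):
            if pid not in known:
                raise ValueError(f"unknown condition id in prevalence config: {pid!r}")
        for pid in (config.rule_weights or {}):
            if pid not in known:
                raise ValueError(f"unknown condition id in rule_weights config: {pid!r}")
        self._all_includes = [p for c in self.registry.conditions for p in c.codes]
        self._other_includes = {
            c.id: tuple(p for o in self.registry.conditions if o.id != c.id for p in o.codes)
            for c in self.registry.conditions
        }
        self._conflicts = self._conflict_pairs()
        self._near_miss_options = {
            c.id: self._applicable_violations(c) for c in self.registry.conditions
        }
        self._noise_pool = self._build_noise_pool()
        self._rec_counter = 0

    # -- static audits -----------------------------------------------------

    def _conflict_pairs(self) -> set[frozenset[str]]:
        """Condition pairs that may not be co-planted in one person because
        one's code set could trigger the other's unconditional exclusions."""
        from .codes import patterns_overlap

        pairs: set[frozenset[str]] = set()
        for a in self.registry.conditions:
            for b in self.registry.conditions:
                if a.id == b.id or not a.exclusions.unconditional:
                    continue
                for pb in b.codes:
                    if any(patterns_overlap(pb, pa) for pa in a.exclusions.unconditional):
                        pairs.add(frozenset((a.id, b.id)))
                        break
        return pairs

    def _applicable_violations(self, cond: ConditionDefinition) -> list[tuple[Violation, str]]:
        out: list[tuple[Violation, str]] = []
        for rule in cond.rules:
            if rule.min_count >= 2:
                out.append((Violation.ONE_SHORT, rule.id))
                out.append((Violation.WINDOW_PLUS_ONE_DAY, rule.id))
            if rule.dx_role is not DxRole.ANY:
                out.append((Violation.WRONG_ROLE, rule.id))
            if rule.specialties is not None:
                out.append((Violation.WRONG_SPECIALTY, rule.id))
            if rule.exclude_if_surgery:
                out.append((Violation.SURGERY_TAINTED, rule.id))
        if cond.uses_lab_criteria:
            out.append((Violation.ONE_SHORT, LAB_RULE_ID))
            out.append((Violation.WINDOW_PLUS_ONE_DAY, LAB_RULE_ID))
        return out

    def _forbidden_for_noise(self) -> list[CodePattern]:
        pats: list[CodePattern] = []
        for c in self.registry.conditions:
            pats.extend(c.codes)
            pats.extend(c.exclusions.unconditional)
            for ce in c.exclusions.conditional:
                pats.append(ce.code)
                pats.extend(ce.companions)
            for aux in c.aux:
                pats.extend(aux.codes)
        return pats

    def _build_noise_pool(self) -> list[NormalizedCode]:
        forbidden = self._forbidden_for_noise()
        pool = []
        for system, texts in _NOISE_CANDIDATES.items():
            for t in texts:
                code = NormalizedCode(system=system, text=t)
                if not any(matches(code, p) for p in forbidden):
                    pool.append(code)
        if not pool:
            raise RuntimeError("no benign noise codes survive the registry filter")
        return pool

    # -- code instantiation ------------------------------------------------

    def _instantiate(
        self,
        pattern: CodePattern,
        rng: np.random.Generator,
        forbidden: Sequence[CodePattern],
    ) -> Optional[NormalizedCode]:
        """Turn a pattern into a plausible full-length code matching it but
        matching none of ``forbidden``.  Returns None when impossible."""
        max_len = 5 if pattern.system is CodeSystem.ICD9CM else 6
        for _ in range(60):
            text = "".join(
                str(int(rng.integers(10))) if ch == "?" else ch for ch in pattern.pattern
            )
            if not pattern.exact:
                room = max_len - len(text)
                extra = int(rng.integers(0, min(room, 2) + 1)) if room > 0 else 0
                text += "".join(str(int(rng.integers(10))) for _ in range(extra))
            code = NormalizedCode(system=pattern.system, text=text)
            if not matches(code, pattern):
                continue
            if not any(matches(code, f) for f in forbidden):
                return code
        return None

    def _evidence_code(
        self, cond: ConditionDefinition, rng: np.random.Generator,
        extra_forbidden: Sequence[CodePattern] = (),
    ) -> NormalizedCode:
        forbidden = list(self._other_includes[cond.id]) + list(cond.exclusions.unconditional) + list(extra_forbidden)
        order = rng.permutation(len(cond.codes))
        for idx in order:
            code = self._instantiate(cond.codes[int(idx)], rng, forbidden)
            if code is not None:
                return code
        raise RuntimeError(f"cannot instantiate a safe evidence code for {cond.id}")

    # -- record builders ---------------------------------------------------

    def _next_record_id(self) -> str:
        self._rec_counter += 1
        return f"r{self._rec_counter:07d}"

    def _make_record(
        self,
        person_id: str,
        date: dt.date,
        rule: EvidenceRule,
        code: NormalizedCode,
        rng: np.random.Generator,
        role: Optional[DiagnosisRole] = None,
        specialty: Optional[str] = None,
        ed: Optional[bool] = None,
        procedures: tuple[str, ...] = (),
    ) -> EncounterRecord:
        if role is None:
            role = (
                _role_for(rule.dx_role, rng)
                if rule.source is not Source.CLAIM
                else DiagnosisRole.OTHER
            )
        if specialty is None:
            if rule.specialties is not None:
                specialty = rule.specialties[int(rng.integers(len(rule.specialties)))]
            elif rule.source is Source.CLAIM:
                specialty = _BENIGN_SPECIALTIES[int(rng.integers(len(_BENIGN_SPECIALTIES)))]
            else:
                specialty = ""
        if ed is None:
            ed = bool(rule.ed_only) or (
                rule.source is Source.AMBULATORY and bool(rng.integers(2))
            )
        return EncounterRecord(
            record_id=self._next_record_id(),
            person_id=person_id,
            date=date,
            source=rule.source,
            diagnoses=(Diagnosis(code=code, role=role),),
            specialty=specialty,
            ed_flag=ed if rule.source is Source.AMBULATORY else False,
            procedures=procedures,
        )

    def _chain_dates(
        self, rule: EvidenceRule, start: dt.date, rng: np.random.Generator,
        count: Optional[int] = None, overshoot: bool = False,
    ) -> list[dt.date]:
        k = count if count is not None else rule.min_count
        if k <= 1 and not overshoot:
            return [start]
        assert rule.window is not None
        end = rule.window.end(start, self.config.convention)
        span = (end - start).days
        if overshoot:
            last = span + 1
            inner = sorted(rng.choice(np.arange(1, span), size=k - 2, replace=False).tolist()) if k > 2 else []
            offsets = inner + [last]
        else:
            offsets = sorted(rng.choice(np.arange(1, span), size=k - 1, replace=False).tolist())
        return [start] + [start + dt.timedelta(days=int(o)) for o in offsets]

    def plant_case(
        self,
        cond: ConditionDefinition,
        rule_id: str,
        start: dt.date,
        rng: np.random.Generator,
        person_id: str,
        extra_forbidden: Sequence[CodePattern] = (),
    ) -> tuple[list[EncounterRecord], list[LabResult], dt.date]:
        """Record chain minimally satisfying one rule (or the lab pathway)."""
        if rule_id == LAB_RULE_ID:
            if not cond.uses_lab_criteria:
                raise ValueError(f"{cond.id} has no laboratory pathway")
            return self._plant_lab(person_id, start, rng, qualify=True)
        rule = self._rule(cond, rule_id)
        dates = self._chain_dates(rule, start, rng)
        records = [
            self._make_record(person_id, d, rule, self._evidence_code(cond, rng, extra_forbidden), rng)
            for d in dates
        ]
        return records, [], start

    def plant_near_miss(
        self,
        cond: ConditionDefinition,
        rule_id: str,
        violation: Violation,
        start: dt.date,
        rng: np.random.Generator,
        person_id: str,
        extra_forbidden: Sequence[CodePattern] = (),
    ) -> tuple[list[EncounterRecord], list[LabResult]]:
        """Record chain failing the rule for exactly the stated reason."""
        if (violation, rule_id) not in self._near_miss_options[cond.id]:
            raise ValueError(f"violation {violation.value} not applicable to {cond.id}/{rule_id}")
        if rule_id == LAB_RULE_ID:
            records, labs, _ = self._plant_lab(
                person_id, start, rng, qualify=False, violation=violation
            )
            return records, labs
        rule = self._rule(cond, rule_id)
        code = lambda: self._evidence_code(cond, rng, extra_forbidden)  # noqa: E731
        if violation is Violation.ONE_SHORT:
            dates = self._chain_dates(rule, start, rng, count=rule.min_count - 1)
            return [self._make_record(person_id, d, rule, code(), rng) for d in dates], []
        if violation is Violation.WINDOW_PLUS_ONE_DAY:
            dates = self._chain_dates(rule, start, rng, overshoot=True)
            return [self._make_record(person_id, d, rule, code(), rng) for d in dates], []
        if violation is Violation.WRONG_ROLE:
            dates = self._chain_dates(rule, start, rng)
            return [
                self._make_record(person_id, d, rule, code(), rng, role=DiagnosisRole.OTHER)
                for d in dates
            ], []
        if violation is Violation.WRONG_SPECIALTY:
            dates = self._chain_dates(rule, start, rng)
            return [
                self._make_record(person_id, d, rule, code(), rng, specialty="orthopedics")
                for d in dates
            ], []
        # SURGERY_TAINTED: qualifying hospitalization carrying a surgery code
        dates = self._chain_dates(rule, start, rng)
        procs = (self.config.surgery_procedure_codes[
            int(rng.integers(len(self.config.surgery_procedure_codes)))],)
        return [
            self._make_record(person_id, d, rule, code(), rng, procedures=procs) for d in dates
        ], []

    def _plant_lab(
        self, person_id: str, start: dt.date, rng: np.random.Generator,
        qualify: bool, violation: Optional[Violation] = None,
    ) -> tuple[list[EncounterRecord], list[LabResult], dt.date]:
        analyte = Analyte.EGFR if rng.integers(2) == 0 else Analyte.ACR
        low = lambda: float(rng.uniform(25, 55)) if analyte is Analyte.EGFR else float(rng.uniform(60, 300))  # noqa: E731
        if qualify:
            gap = int(rng.integers(30, 330))
            labs = [
                LabResult(person_id, start, analyte, round(low(), 1)),
                LabResult(person_id, start + dt.timedelta(days=gap), analyte, round(low(), 1)),
            ]
            return [], labs, start
        if violation is Violation.ONE_SHORT:
            return [], [LabResult(person_id, start, analyte, round(low(), 1))], start
        # WINDOW_PLUS_ONE_DAY: two abnormal values just over 12 months apart
        if self.config.convention is WindowConvention.CALENDAR:
            from dateutil.relativedelta import relativedelta

            second = start + relativedelta(months=12) + dt.timedelta(days=1)
        else:
            second = start + dt.timedelta(days=361)
        return [], [
            LabResult(person_id, start, analyte, round(low(), 1)),
            LabResult(person_id, second, analyte, round(low(), 1)),
        ], start

    def _plant_exclusion_record(
        self,
        cond: ConditionDefinition,
        rng: np.random.Generator,
        person_id: str,
        date: dt.date,
        other_planted: Sequence[ConditionDefinition],
    ) -> Optional[EncounterRecord]:
        forbidden = list(self._all_includes)
        for other in other_planted:
            if other.id != cond.id:
                forbidden.extend(other.exclusions.unconditional)
        order = rng.permutation(len(cond.exclusions.unconditional))
        for idx in order:
            code = self._instantiate(cond.exclusions.unconditional[int(idx)], rng, forbidden)
            if code is not None:
                return EncounterRecord(
                    record_id=self._next_record_id(),
                    person_id=person_id,
                    date=date,
                    source=Source.CLAIM,
                    diagnoses=(Diagnosis(code=code, role=DiagnosisRole.OTHER),),
                    specialty=_BENIGN_SPECIALTIES[int(rng.integers(len(_BENIGN_SPECIALTIES)))],
                )
        return None

    # -- helpers -----------------------------------------------------------

    def _rule(self, cond: ConditionDefinition, rule_id: str) -> EvidenceRule:
        for r in cond.rules:
            if r.id == rule_id:
                return r
        raise ValueError(f"rule {rule_id!r} does not belong to condition {cond.id!r}")

    def _choose_rule(self, cond: ConditionDefinition, rng: np.random.Generator) -> str:
        options = [r.id for r in cond.rules]
        if cond.uses_lab_criteria:
            options.append(LAB_RULE_ID)
        weights = (self.config.rule_weights or {}).get(cond.id)
        if weights:
            w = np.array([weights.get(o, 0.0) for o in options], dtype=float)
            if w.sum() <= 0:
                raise ValueError(f"rule_weights for {cond.id} assign no mass to any rule")
            w /= w.sum()
            return options[int(rng.choice(len(options), p=w))]
        return options[int(rng.integers(len(options)))]

    def _chain_start(self, rng: np.random.Generator, windowed: bool) -> dt.date:
        cfg = self.config
        margin = 1130 if windowed else 0  # room for a 3-year chain plus overshoot
        latest = (cfg.period[1] - cfg.data_start).days - margin
        return cfg.data_start + dt.timedelta(days=int(rng.integers(0, latest + 1)))

    # -- main entry --------------------------------------------------------

    def generate(self) -> SyntheticCohort:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        prevalence = {
            c.id: (cfg.prevalence or {}).get(c.id, cfg.default_prevalence)
            for c in self.registry.conditions
        }
        ages = np.where(
            rng.random(cfg.n_persons) < 0.65,
            rng.integers(cfg.min_age, 56, size=cfg.n_persons),
            rng.integers(50, cfg.max_age + 1, size=cfg.n_persons),
        )
        ages = np.clip(ages, cfg.min_age, cfg.max_age)
        weights = np.exp((ages - 50.0) / 30.0)
        wbar = float(weights.mean())

        encounters: list[EncounterRecord] = []
        labs: list[LabResult] = []
        demographics: dict[str, PersonDemographics] = {}
        truth: dict[str, list[Planted]] = {}
        years = (cfg.period[1] - cfg.data_start).days / 365.25

        for i in range(cfg.n_persons):
            pid = f"p{i + 1:06d}"
            age = int(ages[i])
            birth = cfg.period[0] - dt.timedelta(days=int(round(age * 365.25)) + int(rng.integers(0, 365)))
            demographics[pid] = PersonDemographics(
                person_id=pid, birth_date=birth,
                sex=Sex.F if rng.integers(2) == 0 else Sex.M,
            )
            plants: list[Planted] = []
            planted_conds: list[ConditionDefinition] = []
            statuses: list[tuple[ConditionDefinition, PlantStatus]] = []
            for cond in self.registry.conditions:
                if any(
                    frozenset((cond.id, other.id)) in self._conflicts for other in planted_conds
                ):
                    continue
                u = rng.random()
                p_case = min(prevalence[cond.id] * weights[i] / wbar, 0.95)
                status: Optional[PlantStatus] = None
                if u < p_case:
                    status = PlantStatus.CASE
                elif u < p_case + cfg.near_miss_rate and self._near_miss_options[cond.id]:
                    status = PlantStatus.NEAR_MISS
                elif (
                    u < p_case + cfg.near_miss_rate + cfg.excluded_case_rate
                    and cond.exclusions.unconditional
                ):
                    status = PlantStatus.EXCLUDED_CASE
                if status is not None:
                    statuses.append((cond, status))
                    planted_conds.append(cond)

            planted_ckd = any(c.uses_lab_criteria for c, _ in statuses)
            for cond, status in statuses:
                if status is PlantStatus.NEAR_MISS:
                    kind, rule_id = self._near_miss_options[cond.id][
                        int(rng.integers(len(self._near_miss_options[cond.id])))
                    ]
                    start = self._chain_start(rng, windowed=True)
                    recs, lab_rows = self.plant_near_miss(
                        cond, rule_id, kind, start, rng, pid
                    )
                    encounters.extend(recs)
                    labs.extend(lab_rows)
                    plants.append(Planted(cond.id, status, rule_id, violation=kind,
                                          record_ids=tuple(r.record_id for r in recs)))
                    continue
                rule_id = self._choose_rule(cond, rng)
                if status is PlantStatus.EXCLUDED_CASE and rule_id == LAB_RULE_ID:
                    rule_id = cond.rules[0].id  # exclusions act on coded records
                windowed = rule_id == LAB_RULE_ID or self._rule(cond, rule_id).window is not None
                start = self._chain_start(rng, windowed=windowed)
                recs, lab_rows, index = self.plant_case(cond, rule_id, start, rng, pid)
                if status is PlantStatus.EXCLUDED_CASE:
                    excl_date = start + dt.timedelta(days=int(rng.integers(0, 200)))
                    excl_rec = self._plant_exclusion_record(cond, rng, pid, excl_date, planted_conds)
                    if excl_rec is None:
                        continue  # no safe exclusion code; drop this planting
                    recs = recs + [excl_rec]
                    plants.append(Planted(cond.id, status, rule_id,
                                          record_ids=tuple(r.record_id for r in recs)))
                else:
                    plants.append(Planted(cond.id, status, rule_id, index_date=index,
                                          record_ids=tuple(r.record_id for r in recs)))
                encounters.extend(recs)
                labs.extend(lab_rows)

            # non-matching singleton noise codes
            n_noise = int(rng.poisson(cfg.noise_rate * years))
            for _ in range(n_noise):
                date = cfg.data_start + dt.timedelta(
                    days=int(rng.integers(0, (cfg.period[1] - cfg.data_start).days + 1))
                )
                source = (Source.HOSPITALIZATION, Source.CLAIM, Source.AMBULATORY)[
                    int(rng.integers(3))
                ]
                code = self._noise_pool[int(rng.integers(len(self._noise_pool)))]
                encounters.append(
                    EncounterRecord(
                        record_id=self._next_record_id(),
                        person_id=pid,
                        date=date,
                        source=source,
                        diagnoses=(Diagnosis(code=code, role=(
                            DiagnosisRole.MOST_RESPONSIBLE if rng.integers(2) else DiagnosisRole.OTHER
                        )),),
                        specialty=_BENIGN_SPECIALTIES[int(rng.integers(len(_BENIGN_SPECIALTIES)))]
                        if source is Source.CLAIM else "",
                        ed_flag=bool(rng.integers(2)) if source is Source.AMBULATORY else False,
                    )
                )
            # normal-range laboratory noise (not for persons with planted CKD)
            if not planted_ckd:
                n_lab = int(rng.poisson(cfg.lab_noise_rate * years))
                for _ in range(n_lab):
                    date = cfg.data_start + dt.timedelta(
                        days=int(rng.integers(0, (cfg.period[1] - cfg.data_start).days + 1))
                    )
                    if rng.integers(2):
                        labs.append(LabResult(pid, date, Analyte.EGFR, round(float(rng.uniform(75, 115)), 1)))
                    else:
                        labs.append(LabResult(pid, date, Analyte.ACR, round(float(rng.uniform(2, 20)), 1)))

            truth[pid] = plants

        return SyntheticCohort(
            encounters=encounters,
            labs=labs,
            demographics=demographics,
            truth=CohortTruth(persons=truth),
            registry=self.registry,
            config=cfg,
        )


def generate(config: SimulationConfig, out_dir: Optional[str | Path] = None) -> SyntheticCohort:
    """Generate a synthetic cohort; optionally write the four output files
    (encounters.csv, labs.csv, demographics.csv, truth.json)."""
    cohort = CohortGenerator(config).generate()
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


# ---------------------------------------------------------------------------
# Recovery


@dataclass
class RecoveryReport:
    """Comparison of engine output against planted truth."""

    per_condition: dict[str, dict[str, int]]
    index_date_mismatches: list[tuple[str, str, Optional[dt.date], Optional[dt.date]]]
    false_positives: list[tuple[str, str]]
    orphans: list[str]

    @property
    def exact_match(self) -> bool:
        if self.index_date_mismatches or self.false_positives:
            return False
        for stats in self.per_condition.values():
            if stats["cases"] != stats["cases_detected"]:
                return False
            if stats["near_misses"] != stats["near_misses_rejected"]:
                return False
            if stats["excluded_cases"] != stats["excluded_cases_rejected"]:
                return False
        return True

    def summary(self) -> dict[str, float]:
        tot = {k: 0 for k in ("cases", "cases_detected", "near_misses",
                              "near_misses_rejected", "excluded_cases",
                              "excluded_cases_rejected")}
        for stats in self.per_condition.values():
            for k in tot:
                tot[k] += stats[k]
        pct = lambda a, b: round(100.0 * a / b, 1) if b else 100.0  # noqa: E731
        return {
            "case_detection_pct": pct(tot["cases_detected"], tot["cases"]),
            "near_miss_rejection_pct": pct(tot["near_misses_rejected"], tot["near_misses"]),
            "excluded_case_rejection_pct": pct(tot["excluded_cases_rejected"], tot["excluded_cases"]),
            "index_date_mismatches": len(self.index_date_mismatches),
            "false_positives": len(self.false_positives),
            "planted_cases": tot["cases"],
        }


def recovery_report(
    truth: CohortTruth, results: Sequence[AscertainmentResult]
) -> RecoveryReport:
    """Per-condition confusion between planted truth and engine results.

    Cases must be detected with the planted index date; near-misses and
    excluded-cases must be rejected; a detection with nothing planted is a
    false positive.  Truth persons absent from the results are reported as
    orphans, not failures.
    """
    by_key: dict[tuple[str, str], AscertainmentResult] = {
        (r.person_id, r.condition_id): r for r in results
    }
    result_persons = {r.person_id for r in results}
    per_condition: dict[str, dict[str, int]] = {}
    mismatches: list[tuple[str, str, Optional[dt.date], Optional[dt.date]]] = []
    false_pos: list[tuple[str, str]] = []
    orphans = [pid for pid in truth.persons if pid not in result_persons]

    planted_keys = set()
    for pid, plants in truth.persons.items():
        if pid not in result_persons:
            continue
        for p in plants:
            planted_keys.add((pid, p.condition_id))
            stats = per_condition.setdefault(p.condition_id, {
                "cases": 0, "cases_detected": 0,
                "near_misses": 0, "near_misses_rejected": 0,
                "excluded_cases": 0, "excluded_cases_rejected": 0,
            })
            res = by_key.get((pid, p.condition_id))
            detected = bool(res and res.present)
            if p.status is PlantStatus.CASE:
                stats["cases"] += 1
                if detected:
                    stats["cases_detected"] += 1
                    if res.index_date != p.index_date:
                        mismatches.append((pid, p.condition_id, p.index_date, res.index_date))
                else:
                    mismatches.append((pid, p.condition_id, p.index_date, None))
            elif p.status is PlantStatus.NEAR_MISS:
                stats["near_misses"] += 1
                if not detected:
                    stats["near_misses_rejected"] += 1
            else:
                stats["excluded_cases"] += 1
                if not detected:
                    stats["excluded_cases_rejected"] += 1
    for (pid, cid), res in by_key.items():
        if res.present and (pid, cid) not in planted_keys and pid in truth.persons:
            false_pos.append((pid, cid))
    return RecoveryReport(
        per_condition=per_condition,
        index_date_mismatches=mismatches,
        false_positives=false_pos,
        orphans=orphans,
    )
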