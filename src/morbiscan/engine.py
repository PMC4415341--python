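"""Temporal evidence-rule engine: apply one condition definition to one
person's history.

A condition is present when, using only the active data sources, (a) no
person-level exclusion code appears anywhere in the history and (b) at
least one of the condition's evidence rules is satisfied — N records from
the rule's source stream, on distinct service dates, spanning at most the
rule's window, with any diagnosis-role / specialty / emergency-department /
no-surgery restriction honoured.  The index date is the date of the first
record of the earliest qualifying evidence set, minimized over rules.

Chronic kidney disease additionally has a laboratory pathway: presence of a
12-month window holding at least two measurements of one analyte whose mean
crosses the threshold (eGFR < 60 mL/min/1.73 m2 or ACR > 30 mg/g).  The
combined condition is administrative OR laboratory, indexed at the earlier
pathway.

Window arithmetic defaults to calendar anniversaries ("within 2 years" =
second date on or before the 2-year anniversary of the first, inclusive);
a fixed day-count convention (365 d/year, 30 d/month) is available as a
configuration switch.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from dateutil.relativedelta import relativedelta

from .codes import CodePattern, CodeSystem, NormalizedCode, matches
from .records import (
    Analyte,
    Diagnosis,
    DiagnosisRole,
    EncounterRecord,
    LabResult,
    PersonHistory,
)
from .registry import (
    ConditionDefinition,
    ConditionRegistry,
    DxRole,
    EvidenceRule,
    Permanence,
    Source,
    WindowConvention,
)

__all__ = [
    "SourceSet",
    "AscertainmentResult",
    "EGFR_THRESHOLD",
    "ACR_THRESHOLD",
    "evaluate_rule",
    "ascertain",
    "ascertain_all",
    "lab_ckd",
    "active_at",
    "relevant_code_dates",
    "evaluate_aux",
]

EGFR_THRESHOLD = 60.0  # mL/min/1.73 m2, mean below => CKD
ACR_THRESHOLD = 30.0  # mg/g, mean above => CKD
LAB_WINDOW_MONTHS = 12
MIN_LAB_MEASUREMENTS = 2

ALL_SOURCES = frozenset(Source)


@dataclass(frozen=True, slots=True)
class SourceSet:
    """Which administrative streams (and labs) ascertainment may use."""

    included: frozenset[Source] = ALL_SOURCES
    use_labs: bool = True

    def __post_init__(self) -> None:
        if not self.included:
            raise ValueError("source set must include at least one source")

    @classmethod
    def of(cls, *names: str, use_labs: bool = False) -> "SourceSet":
        aliases = {"hosp": Source.HOSPITALIZATION, "claim": Source.CLAIM,
                   "claims": Source.CLAIM, "accs": Source.AMBULATORY,
                   "ambulatory": Source.AMBULATORY}
        return cls(frozenset(aliases[n.lower()] for n in names), use_labs=use_labs)

    def label(self) -> str:
        order = [Source.HOSPITALIZATION, Source.CLAIM, Source.AMBULATORY]
        short = {Source.HOSPITALIZATION: "hosp", Source.CLAIM: "claim", Source.AMBULATORY: "accs"}
        bits = [short[s] for s in order if s in self.included]
        if self.use_labs:
            bits.append("labs")
        return "+".join(bits)


@dataclass(frozen=True, slots=True)
class AscertainmentResult:
    person_id: str
    condition_id: str
    present: bool
    index_date: Optional[dt.date] = None
    satisfied_rule: Optional[str] = None
    supporting_record_ids: tuple[str, ...] = ()
    excluded_by: Optional[str] = None
    lab_based: bool = False


# ---------------------------------------------------------------------------
# Compiled pattern sets (hot path: startswith on a tuple is C-speed)


class _CompiledCodeSet:
    __slots__ = ("prefixes", "special")

    def __init__(self, patterns: Sequence[CodePattern]):
        by_system: dict[CodeSystem, list[str]] = {}
        special: dict[CodeSystem, list[CodePattern]] = {}
        for p in patterns:
            if p.exact or "?" in p.pattern:
                special.setdefault(p.system, []).append(p)
            else:
                by_system.setdefault(p.system, []).append(p.pattern)
        self.prefixes = {s: tuple(v) for s, v in by_system.items()}
        self.special = {s: tuple(v) for s, v in special.items()}

    def matches(self, code: NormalizedCode) -> bool:
        pref = self.prefixes.get(code.system)
        if pref and code.text.startswith(pref):
            return True
        spec = self.special.get(code.system)
        if spec:
            return any(matches(code, p) for p in spec)
        return False


@lru_cache(maxsize=256)
def _compiled(patterns: tuple[CodePattern, ...]) -> _CompiledCodeSet:
    return _CompiledCodeSet(patterns)


def _role_ok(role: DiagnosisRole, restriction: DxRole) -> bool:
    if restriction is DxRole.ANY:
        return True
    if restriction is DxRole.MOST_RESPONSIBLE:
        return role is DiagnosisRole.MOST_RESPONSIBLE
    return role in (DiagnosisRole.MOST_RESPONSIBLE, DiagnosisRole.POST_ADMIT)


def _dx_conditionally_voided(dx: Diagnosis, record: EncounterRecord, cond: ConditionDefinition) -> bool:
    # A carve-out like "560.9 if 789.01" voids only this diagnosis on this
    # record; other qualifying diagnoses on the same record still count.
    for ce in cond.exclusions.conditional:
        if matches(dx.code, ce.code) and any(
            matches(other.code, comp) for other in record.diagnoses for comp in ce.companions
        ):
            return True
    return False


def _is_surgical(record: EncounterRecord, cond: ConditionDefinition) -> bool:
    procs = cond.exclusions.surgery_procedures
    if not procs:
        return False
    return any(p.startswith(procs) for p in record.procedures)


def _record_qualifies(record: EncounterRecord, rule: EvidenceRule, cond: ConditionDefinition,
                      include: _CompiledCodeSet) -> bool:
    if record.source is not rule.source:
        return False
    if rule.ed_only and not record.ed_flag:
        return False
    if rule.specialties is not None and record.specialty not in rule.specialties:
        return False
    if rule.exclude_if_surgery and _is_surgical(record, cond):
        return False
    for dx in record.diagnoses:
        if (
            include.matches(dx.code)
            and _role_ok(dx.role, rule.dx_role)
            and not _dx_conditionally_voided(dx, record, cond)
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# Rule evaluation


def evaluate_rule(
    records: Sequence[EncounterRecord],
    rule: EvidenceRule,
    convention: WindowConvention = WindowConvention.CALENDAR,
) -> Optional[list[EncounterRecord]]:
    """Earliest qualifying evidence set for a rule, or ``None``.

    ``records`` must already be filtered to the rule's source and
    restrictions and sorted ascending by (date, record_id).  A qualifying
    set is ``min_count`` records on *distinct* service dates whose span is
    at most the rule's window (inclusive); same-day duplicates never count
    twice.  Among qualifying sets the one with the lexicographically
    earliest date tuple is returned, i.e. the earliest run of consecutive
    distinct dates that fits the window.
    """
    if not records:
        return None
    if rule.min_count == 1:
        return [records[0]]
    first_on_date: dict[dt.date, EncounterRecord] = {}
    dates: list[dt.date] = []
    for r in records:
        if r.date not in first_on_date:
            first_on_date[r.date] = r
            dates.append(r.date)
    k = rule.min_count
    assert rule.window is not None
    for i in range(len(dates) - k + 1):
        if dates[i + k - 1] <= rule.window.end(dates[i], convention):
            return [first_on_date[d] for d in dates[i : i + k]]
    return None


def lab_ckd(
    labs: Sequence[LabResult],
    convention: WindowConvention = WindowConvention.CALENDAR,
) -> tuple[bool, Optional[dt.date]]:
    """Laboratory criteria for chronic kidney disease.

    Present iff some 12-month window contains at least two measurements of
    one analyte whose mean crosses the threshold (mean eGFR < 60, or mean
    ACR > 30).  A window's content is a run of consecutive measurements, so
    all runs with span <= 12 months are examined; the index date is the
    first measurement date of the earliest qualifying window.
    """
    best: Optional[dt.date] = None
    for analyte in (Analyte.EGFR, Analyte.ACR):
        series = sorted(
            ((l.date, l.value) for l in labs if l.analyte is analyte),
            key=lambda t: t[0],
        )
        n = len(series)
        found = None
        for i in range(n - 1):
            if convention is WindowConvention.CALENDAR:
                end = series[i][0] + relativedelta(months=LAB_WINDOW_MONTHS)
            else:
                end = series[i][0] + dt.timedelta(days=30 * LAB_WINDOW_MONTHS)
            total = series[i][1]
            count = 1
            for j in range(i + 1, n):
                if series[j][0] > end:
                    break
                total += series[j][1]
                count += 1
                if count >= MIN_LAB_MEASUREMENTS:
                    mean = total / count
                    if (analyte is Analyte.EGFR and mean < EGFR_THRESHOLD) or (
                        analyte is Analyte.ACR and mean > ACR_THRESHOLD
                    ):
                        found = series[i][0]
                        break
            if found is not None:
                break
        if found is not None and (best is None or found < best):
            best = found
    return (best is not None, best)


def _person_level_exclusion(
    history: PersonHistory, cond: ConditionDefinition, sources: SourceSet
) -> Optional[str]:
    if not cond.exclusions.unconditional:
        return None
    excl = _compiled(cond.exclusions.unconditional)
    for rec in history.encounters:
        if rec.source not in sources.included:
            continue
        for dx in rec.diagnoses:
            if excl.matches(dx.code):
                return f"exclusion code {dx.code.text} on record {rec.record_id}"
    return None


def ascertain(
    history: PersonHistory,
    cond: ConditionDefinition,
    sources: SourceSet = SourceSet(),
    convention: WindowConvention = WindowConvention.CALENDAR,
) -> AscertainmentResult:
    """Decide presence and index date of one condition for one person.

    Deterministic and independent of record input order (histories are
    date-sorted with stable record-id tie-breaks).  An unconditional
    exclusion code anywhere in the history (within the active sources)
    vetoes the condition outright.
    """
    excluded_by = _person_level_exclusion(history, cond, sources)
    if excluded_by is not None:
        return AscertainmentResult(
            person_id=history.person_id, condition_id=cond.id, present=False,
            excluded_by=excluded_by,
        )

    include = _compiled(cond.codes)
    best: Optional[tuple[dt.date, str, tuple[str, ...]]] = None
    for rule in cond.rules:
        if rule.source not in sources.included:
            continue
        candidates = [
            r for r in history.encounters if _record_qualifies(r, rule, cond, include)
        ]
        evidence = evaluate_rule(candidates, rule, convention)
        if evidence is None:
            continue
        first = evidence[0].date
        if best is None or first < best[0]:
            best = (first, rule.id, tuple(r.record_id for r in evidence))

    lab_present, lab_index = (False, None)
    if cond.uses_lab_criteria and sources.use_labs:
        lab_present, lab_index = lab_ckd(history.labs, convention)

    if best is None and not lab_present:
        return AscertainmentResult(person_id=history.person_id, condition_id=cond.id, present=False)

    if best is not None and (not lab_present or best[0] <= lab_index):
        return AscertainmentResult(
            person_id=history.person_id, condition_id=cond.id, present=True,
            index_date=best[0], satisfied_rule=best[1], supporting_record_ids=best[2],
            lab_based=False,
        )
    return AscertainmentResult(
        person_id=history.person_id, condition_id=cond.id, present=True,
        index_date=lab_index, satisfied_rule="lab", lab_based=True,
    )


def ascertain_all(
    history: PersonHistory,
    registry: ConditionRegistry,
    sources: SourceSet = SourceSet(),
    convention: WindowConvention = WindowConvention.CALENDAR,
) -> list[AscertainmentResult]:
    """One result per registry condition, in registry order."""
    return [ascertain(history, c, sources, convention) for c in registry.conditions]


def relevant_code_dates(
    history: PersonHistory, cond: ConditionDefinition, sources: SourceSet
) -> list[dt.date]:
    """Dates of every encounter (in the active sources) carrying a condition
    code, regardless of role/specialty/setting restrictions.

    Used for remission bookkeeping: any matching code refreshes activity,
    whether or not it belonged to the qualifying evidence set.
    """
    include = _compiled(cond.codes)
    out = []
    for rec in history.encounters:
        if rec.source not in sources.included:
            continue
        if any(include.matches(dx.code) for dx in rec.diagnoses):
            out.append(rec.date)
    return out


def active_at(
    result: AscertainmentResult,
    cond: ConditionDefinition,
    relevant_dates: Sequence[dt.date],
    t: dt.date,
) -> bool:
    """Is an ascertained condition active on date ``t``?

    Permanent conditions are present continuously from the index date.
    Remitting conditions stay active while the most recent relevant code on
    or before ``t`` is within ``remission_years`` of ``t`` (closed interval:
    still active exactly at last code + remission_years).
    """
    if not result.present:
        raise ValueError("active_at requires an ascertained (present) result")
    assert result.index_date is not None
    if t < result.index_date:
        return False
    if cond.permanence is Permanence.PERMANENT:
        return True
    assert cond.remission_years is not None
    prior = [d for d in relevant_dates if d <= t]
    if result.index_date <= t:
        prior.append(result.index_date)  # the index itself is a relevant code
    if not prior:
        return False
    last = max(prior)
    return t <= last + relativedelta(years=cond.remission_years)


def evaluate_aux(
    history: PersonHistory, cond: ConditionDefinition, sources: SourceSet = SourceSet()
) -> dict[str, bool]:
    """Evaluate auxiliary severity code sets (e.g. hepatic decompensation
    alongside cirrhosis): flag true iff any encounter in the active sources
    carries an aux code that is not carved out by the set's exceptions."""
    out: dict[str, bool] = {}
    for aux in cond.aux:
        include = _compiled(aux.codes)
        exceptions = _compiled(aux.exceptions) if aux.exceptions else None
        flag = False
        for rec in history.encounters:
            if rec.source not in sources.included:
                continue
            for dx in rec.diagnoses:
                if include.matches(dx.code) and not (exceptions and exceptions.matches(dx.code)):
                    flag = True
                    break
            if flag:
                break
        out[aux.name] = flag
    return out
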