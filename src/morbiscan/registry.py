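"""Machine-readable registry of chronic-condition case definitions.

Each condition is defined by (i) a diagnosis-code set, (ii) one or more
*evidence rules* — disjuncts of the form "N records from source S within
window W", optionally restricted by diagnosis role, provider specialty,
emergency-department setting, or absence of surgery — and (iii) optional
exclusions.  Conditions are graded by the validity of their source
validation study (high: PPV and sensitivity >= 70%; moderate: PPV >= 70%
with lower sensitivity) and marked permanent or remitting.

The registry ships as a single JSON document (``data/registry_tonelli30.json``)
with per-condition provenance: the algorithm phrase and the printed code
tokens it was transcribed from.  ``load_registry`` / ``serialize_registry``
round-trip it losslessly.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import re
from importlib import resources
from pathlib import Path
from typing import Optional

from dateutil.relativedelta import relativedelta
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .codes import CodePattern, CodeSystem, patterns_overlap

__all__ = [
    "Source",
    "DxRole",
    "Validity",
    "Permanence",
    "WindowUnit",
    "WindowConvention",
    "Window",
    "EvidenceRule",
    "ConditionalExclusion",
    "ExclusionSpec",
    "AuxCodeSet",
    "ConditionDefinition",
    "ConditionRegistry",
    "ValidationReport",
    "OverlapHit",
    "RegistryError",
    "expand_code_spec",
    "load_registry",
    "loads_registry",
    "default_registry_path",
    "load_default_registry",
    "serialize_registry",
    "save_registry",
    "validate_registry",
    "with_surgery_procedures",
]


class Source(str, enum.Enum):
    """Administrative data stream an encounter record comes from."""

    HOSPITALIZATION = "HOSPITALIZATION"
    CLAIM = "CLAIM"
    AMBULATORY = "AMBULATORY"


class DxRole(str, enum.Enum):
    """Diagnosis-role restriction on the matching diagnosis of a record."""

    ANY = "ANY"
    MOST_RESPONSIBLE = "MOST_RESPONSIBLE"
    MOST_RESPONSIBLE_OR_POST_ADMIT = "MOST_RESPONSIBLE_OR_POST_ADMIT"


class Validity(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"


class Permanence(str, enum.Enum):
    PERMANENT = "PERMANENT"
    REMITTING = "REMITTING"


class WindowUnit(str, enum.Enum):
    DAYS = "days"
    MONTHS = "months"
    YEARS = "years"


class WindowConvention(str, enum.Enum):
    """How "within N years/months" is turned into a last admissible date.

    CALENDAR: calendar anniversary (leap-year stable; the default).
    DAYS: fixed day counts (365 per year, 30 per month).
    """

    CALENDAR = "calendar"
    DAYS = "days"


class RegistryError(ValueError):
    """Raised when a registry file cannot be parsed or violates the schema."""


class _Model(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class Window(_Model):
    """Maximum span of a multi-record evidence chain, inclusive."""

    value: int = Field(ge=1)
    unit: WindowUnit

    def end(self, start: dt.date, convention: WindowConvention = WindowConvention.CALENDAR) -> dt.date:
        """Last date on which a further record still falls inside the window."""
        if self.unit is WindowUnit.DAYS:
            return start + dt.timedelta(days=self.value)
        if convention is WindowConvention.CALENDAR:
            if self.unit is WindowUnit.YEARS:
                return start + relativedelta(years=self.value)
            return start + relativedelta(months=self.value)
        days = 365 * self.value if self.unit is WindowUnit.YEARS else 30 * self.value
        return start + dt.timedelta(days=days)


class EvidenceRule(_Model):
    """One disjunct of a case definition: N records from one source stream.

    Evidence is never pooled across streams; each rule draws only on its own
    source.  ``min_count >= 2`` rules additionally require the records to fall
    on distinct service dates within ``window``.
    """

    id: str
    source: Source
    min_count: int = Field(ge=1)
    window: Optional[Window] = None
    dx_role: DxRole = DxRole.ANY
    specialties: Optional[tuple[str, ...]] = None
    ed_only: bool = False
    exclude_if_surgery: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EvidenceRule":
        if (self.window is None) != (self.min_count == 1):
            raise ValueError(
                f"rule {self.id!r}: window must be present exactly when min_count >= 2"
            )
        if self.specialties is not None and self.source is not Source.CLAIM:
            raise ValueError(f"rule {self.id!r}: specialty restriction only applies to claims")
        if self.ed_only and self.source is not Source.AMBULATORY:
            raise ValueError(f"rule {self.id!r}: ed_only only applies to ambulatory records")
        if (
            self.dx_role is DxRole.MOST_RESPONSIBLE_OR_POST_ADMIT
            and self.source is not Source.HOSPITALIZATION
        ):
            raise ValueError(f"rule {self.id!r}: post-admit roles exist only on hospitalizations")
        if self.specialties is not None:
            folded = tuple(s.casefold() for s in self.specialties)
            if folded != self.specialties:
                object.__setattr__(self, "specialties", folded)
        return self


class ConditionalExclusion(_Model):
    """A record-level carve-out: ``code`` does not count as evidence when any
    companion code appears on the same record."""

    code: CodePattern
    companions: tuple[CodePattern, ...]

    @model_validator(mode="after")
    def _check(self) -> "ConditionalExclusion":
        if not self.companions:
            raise ValueError("conditional exclusion needs at least one companion code")
        return self


class ExclusionSpec(_Model):
    """Exclusions attached to a condition.

    ``unconditional`` codes anywhere in the person's history (within the
    active source set) veto the condition; ``conditional`` carve-outs void
    only the co-occurring record; ``surgery_procedures`` mark hospitalizations
    that cannot serve as evidence for rules flagged ``exclude_if_surgery``.
    """

    unconditional: tuple[CodePattern, ...] = ()
    conditional: tuple[ConditionalExclusion, ...] = ()
    surgery_procedures: tuple[str, ...] = ()

    @property
    def empty(self) -> bool:
        return not (self.unconditional or self.conditional or self.surgery_procedures)


class AuxCodeSet(_Model):
    """An auxiliary code set (e.g. hepatic decompensation alongside cirrhosis).

    ``exceptions`` carve specific descendants out of the prefix patterns in
    ``codes`` (a published list may include 567.8 while explicitly excluding
    567.81 and 567.82).
    """

    name: str
    codes: tuple[CodePattern, ...]
    exceptions: tuple[CodePattern, ...] = ()
    provenance: dict = Field(default_factory=dict)


class ConditionDefinition(_Model):
    id: str
    name: str
    validity: Validity
    permanence: Permanence
    remission_years: Optional[int] = None
    codes: tuple[CodePattern, ...]
    rules: tuple[EvidenceRule, ...]
    exclusions: ExclusionSpec = Field(default_factory=ExclusionSpec)
    uses_lab_criteria: bool = False
    citation: str = ""
    provenance: dict = Field(default_factory=dict)
    aux: tuple[AuxCodeSet, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "ConditionDefinition":
        if not self.codes:
            raise ValueError(f"condition {self.id!r}: at least one code pattern required")
        if not self.rules and not self.uses_lab_criteria:
            raise ValueError(f"condition {self.id!r}: at least one evidence rule required")
        if self.permanence is Permanence.REMITTING:
            if self.remission_years not in (2, 5):
                raise ValueError(
                    f"condition {self.id!r}: remitting conditions use a 2- or 5-year "
                    f"remission window, got {self.remission_years!r}"
                )
        elif self.remission_years is not None:
            raise ValueError(f"condition {self.id!r}: permanent conditions take no remission window")
        seen = set()
        for rule in self.rules:
            if rule.id in seen:
                raise ValueError(f"condition {self.id!r}: duplicate rule id {rule.id!r}")
            seen.add(rule.id)
        return self


class PermittedOverlap(_Model):
    """A pair of conditions allowed to share specific diagnosis codes."""

    conditions: tuple[str, str]
    shared: tuple[CodePattern, ...]
    note: str = ""


class ConditionRegistry(_Model):
    schema_version: int = 1
    name: str = ""
    conditions: tuple[ConditionDefinition, ...]
    permitted_overlaps: tuple[PermittedOverlap, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "ConditionRegistry":
        ids = [c.id for c in self.conditions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate condition ids: {sorted(dupes)}")
        known = set(ids)
        for ov in self.permitted_overlaps:
            for cid in ov.conditions:
                if cid not in known:
                    raise ValueError(f"permitted overlap references unknown condition {cid!r}")
        return self

    def __getitem__(self, condition_id: str) -> ConditionDefinition:
        for c in self.conditions:
            if c.id == condition_id:
                return c
        raise KeyError(condition_id)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.conditions]


# ---------------------------------------------------------------------------
# Printed-token expansion


_RANGE_SEP = re.compile(r"\s*[–—-]\s*")


def expand_code_spec(token: str, system: CodeSystem | str, *, exact: bool = False) -> list[CodePattern]:
    """Expand one printed code token into normalized patterns.

    Accepted forms: a single (possibly dotted) code ("J45", "203.0"), an
    inclusive range with same-length endpoints ("200–202", "C81–C85",
    "425.4–425.9"), or a wildcard form where a lowercase "x" stands for any
    single character ("433.x1").  Ranges expand at the printed granularity;
    finer codes are reached through prefix matching at evaluation time.
    """
    system = CodeSystem(system)
    token = token.strip()
    if not token:
        raise RegistryError("empty code token")

    def _norm(t: str) -> str:
        out = t.strip().upper().replace(".", "").replace("X", "?") if "x" in t else t.strip().upper().replace(".", "")
        if not out:
            raise RegistryError(f"malformed code token {token!r}")
        return out

    parts = _RANGE_SEP.split(token)
    if len(parts) == 1:
        return [CodePattern(system=system, pattern=_norm(token), exact=exact)]
    if len(parts) != 2:
        raise RegistryError(f"malformed range {token!r}")
    a, b = (_norm(p) for p in parts)
    if "?" in a or "?" in b:
        raise RegistryError(f"wildcards not allowed in ranges: {token!r}")
    if len(a) != len(b):
        raise RegistryError(f"range endpoints differ in length: {token!r}")
    k = 0
    while k < len(a) and a[k] == b[k]:
        k += 1
    prefix, sa, sb = a[:k], a[k:], b[k:]
    if not (sa.isdigit() and sb.isdigit()):
        raise RegistryError(f"range endpoints must differ only in a numeric suffix: {token!r}")
    lo, hi = int(sa), int(sb)
    if lo > hi:
        raise RegistryError(f"reversed range {token!r}")
    width = len(sa)
    return [
        CodePattern(system=system, pattern=prefix + str(i).zfill(width), exact=exact)
        for i in range(lo, hi + 1)
    ]


# ---------------------------------------------------------------------------
# Serialization


def _pattern_to_json(p: CodePattern) -> dict:
    d = {"system": p.system.value, "pattern": p.pattern}
    if p.exact:
        d["exact"] = True
    return d


def _drop_defaults(d: dict, defaults: dict) -> dict:
    return {k: v for k, v in d.items() if k not in defaults or v != defaults[k]}


def serialize_registry(reg: ConditionRegistry) -> dict:
    """Registry → plain JSON-able dict (defaults omitted)."""
    out = {"schema_version": reg.schema_version, "name": reg.name, "conditions": []}
    for c in reg.conditions:
        cd: dict = {
            "id": c.id,
            "name": c.name,
            "validity": c.validity.value,
            "permanence": c.permanence.value,
        }
        if c.remission_years is not None:
            cd["remission_years"] = c.remission_years
        cd["codes"] = [_pattern_to_json(p) for p in c.codes]
        rules = []
        for r in c.rules:
            rd: dict = {"id": r.id, "source": r.source.value, "min_count": r.min_count}
            if r.window is not None:
                rd["window"] = {"value": r.window.value, "unit": r.window.unit.value}
            if r.dx_role is not DxRole.ANY:
                rd["dx_role"] = r.dx_role.value
            if r.specialties is not None:
                rd["specialties"] = list(r.specialties)
            if r.ed_only:
                rd["ed_only"] = True
            if r.exclude_if_surgery:
                rd["exclude_if_surgery"] = True
            rules.append(rd)
        cd["rules"] = rules
        if not c.exclusions.empty:
            ex: dict = {}
            if c.exclusions.unconditional:
                ex["unconditional"] = [_pattern_to_json(p) for p in c.exclusions.unconditional]
            if c.exclusions.conditional:
                ex["conditional"] = [
                    {
                        "code": _pattern_to_json(ce.code),
                        "companions": [_pattern_to_json(p) for p in ce.companions],
                    }
                    for ce in c.exclusions.conditional
                ]
            if c.exclusions.surgery_procedures:
                ex["surgery_procedures"] = list(c.exclusions.surgery_procedures)
            cd["exclusions"] = ex
        if c.uses_lab_criteria:
            cd["uses_lab_criteria"] = True
        if c.citation:
            cd["citation"] = c.citation
        if c.provenance:
            cd["provenance"] = c.provenance
        if c.aux:
            cd["aux"] = [
                _drop_defaults(
                    {
                        "name": a.name,
                        "codes": [_pattern_to_json(p) for p in a.codes],
                        "exceptions": [_pattern_to_json(p) for p in a.exceptions],
                        "provenance": a.provenance,
                    },
                    {"exceptions": [], "provenance": {}},
                )
                for a in c.aux
            ]
        out["conditions"].append(cd)
    if reg.permitted_overlaps:
        out["permitted_overlaps"] = [
            _drop_defaults(
                {
                    "conditions": list(ov.conditions),
                    "shared": [_pattern_to_json(p) for p in ov.shared],
                    "note": ov.note,
                },
                {"note": ""},
            )
            for ov in reg.permitted_overlaps
        ]
    return out


def save_registry(reg: ConditionRegistry, path: str | Path) -> None:
    """Write the registry as JSON, one compact line per condition."""
    doc = serialize_registry(reg)
    dump = lambda o: json.dumps(o, separators=(",", ":"))  # noqa: E731
    parts = [f'{{\n"schema_version": {doc["schema_version"]},\n"name": {dump(doc["name"])},']
    parts.append('"conditions": [')
    parts.append(",\n".join(dump(c) for c in doc["conditions"]))
    if doc.get("permitted_overlaps"):
        parts.append('],\n"permitted_overlaps": [')
        parts.append(",\n".join(dump(o) for o in doc["permitted_overlaps"]))
    parts.append("]\n}")
    Path(path).write_text("\n".join(parts) + "\n")


def loads_registry(doc: dict) -> ConditionRegistry:
    """Parse a registry JSON document, reporting the offending condition."""
    if not isinstance(doc, dict) or "conditions" not in doc:
        raise RegistryError("registry document must be an object with a 'conditions' list")
    conditions = []
    for i, cd in enumerate(doc.get("conditions", [])):
        try:
            conditions.append(ConditionDefinition.model_validate(cd))
        except (ValidationError, ValueError) as e:
            cid = cd.get("id", f"#{i}") if isinstance(cd, dict) else f"#{i}"
            raise RegistryError(f"condition {cid!r}: {e}") from e
    try:
        return ConditionRegistry.model_validate(
            {**{k: v for k, v in doc.items() if k != "conditions"}, "conditions": conditions}
        )
    except (ValidationError, ValueError) as e:
        raise RegistryError(str(e)) from e


def load_registry(path: str | Path) -> ConditionRegistry:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise RegistryError(f"{path}: not valid JSON: {e}") from e
    return loads_registry(doc)


def default_registry_path() -> Path:
    """Path of the registry file shipped with the package."""
    return Path(str(resources.files("morbiscan").joinpath("data/registry_tonelli30.json")))


def load_default_registry() -> ConditionRegistry:
    return load_registry(default_registry_path())


# ---------------------------------------------------------------------------
# Validation / audit


class OverlapHit(_Model):
    condition_a: str
    condition_b: str
    pattern_a: CodePattern
    pattern_b: CodePattern
    permitted: bool


class ValidationReport(_Model):
    overlaps: tuple[OverlapHit, ...]
    rule_issues: tuple[str, ...]

    @property
    def unpermitted_overlaps(self) -> list[OverlapHit]:
        return [h for h in self.overlaps if not h.permitted]

    @property
    def ok(self) -> bool:
        return not self.unpermitted_overlaps and not self.rule_issues

    def render(self) -> str:
        lines = []
        bad = self.unpermitted_overlaps
        lines.append(f"unpermitted code overlaps: {len(bad)}")
        for h in bad:
            lines.append(
                f"  {h.condition_a} <-> {h.condition_b}: "
                f"{h.pattern_a.pattern} / {h.pattern_b.pattern} ({h.pattern_a.system.value})"
            )
        lines.append(f"rule issues: {len(self.rule_issues)}")
        lines.extend(f"  {m}" for m in self.rule_issues)
        lines.append("status: " + ("OK" if self.ok else "PROBLEMS FOUND"))
        return "\n".join(lines)


def _overlap_permitted(reg: ConditionRegistry, a: str, b: str, pa: CodePattern, pb: CodePattern) -> bool:
    pair = frozenset((a, b))
    for ov in reg.permitted_overlaps:
        if frozenset(ov.conditions) != pair:
            continue
        shared = {(p.system, p.pattern) for p in ov.shared}
        if (pa.system, pa.pattern) in shared or (pb.system, pb.pattern) in shared:
            return True
    return False


def validate_registry(reg: ConditionRegistry) -> ValidationReport:
    """Audit a registry: cross-condition code overlaps and rule sanity.

    Two conditions overlap when any of their diagnosis code patterns could
    match a common concrete code; every such pair must be declared in
    ``permitted_overlaps``.  This is a report, never an exception.
    """
    overlaps: list[OverlapHit] = []
    for i, ca in enumerate(reg.conditions):
        for cb in reg.conditions[i + 1 :]:
            for pa in ca.codes:
                for pb in cb.codes:
                    if patterns_overlap(pa, pb):
                        overlaps.append(
                            OverlapHit(
                                condition_a=ca.id,
                                condition_b=cb.id,
                                pattern_a=pa,
                                pattern_b=pb,
                                permitted=_overlap_permitted(reg, ca.id, cb.id, pa, pb),
                            )
                        )
    issues: list[str] = []
    for c in reg.conditions:
        for r in c.rules:
            # Model validation already enforces this; re-checked here so the
            # audit also covers registries built programmatically.
            if (r.window is None) != (r.min_count == 1):
                issues.append(f"{c.id}/{r.id}: window present iff min_count >= 2 violated")
    return ValidationReport(overlaps=tuple(overlaps), rule_issues=tuple(issues))


def with_surgery_procedures(reg: ConditionRegistry, procedure_codes) -> ConditionRegistry:
    """Return a copy of ``reg`` where every condition having a rule with
    ``exclude_if_surgery`` carries the given surgery procedure-code patterns.

    The shipped registry leaves the surgery list empty (the source procedure
    classification list is site-specific); deployments supply their own.
    """
    procs = tuple(str(p).upper().replace(".", "") for p in procedure_codes)
    conditions = []
    for c in reg.conditions:
        if any(r.exclude_if_surgery for r in c.rules):
            c = c.model_copy(
                update={"exclusions": c.exclusions.model_copy(update={"surgery_procedures": procs})}
            )
        conditions.append(c)
    return reg.model_copy(update={"conditions": tuple(conditions)})
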