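"""Diagnosis / procedure code normalization and pattern matching.

Administrative records carry ICD-9-CM and ICD-10(-CA) diagnosis codes at
mixed granularity: a claim may bill a bare three-digit stem ("250") while a
discharge abstract carries five or more characters ("25001", ICD-10-CA adds
further digits).  Case-definition code lists are likewise printed at mixed
depth.  The only consistent matching semantics across both is therefore
*prefix* matching on dotless, upper-cased codes: pattern ``250`` matches any
descendant (``2500``, ``25001``, ...).  Patterns may carry one
single-character wildcard (``433?1``, from printed forms like "433.x1") and
may be flagged *exact* when a published list explicitly forbids
generalization to sub-codes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

__all__ = [
    "CodeSystem",
    "CodePattern",
    "NormalizedCode",
    "normalize",
    "matches",
    "any_match",
    "patterns_overlap",
]


class CodeSystem(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10 = "ICD10"


_WS = re.compile(r"\s+")
_ALNUM = re.compile(r"[A-Z0-9]")


@dataclass(frozen=True, slots=True)
class NormalizedCode:
    """An upper-cased, dotless diagnosis or procedure code."""

    system: CodeSystem
    text: str


@dataclass(frozen=True, slots=True)
class CodePattern:
    """A normalized code pattern with prefix semantics.

    ``pattern`` is dotless and upper-case; it may contain at most one ``?``
    wildcard that matches any single character.  When ``exact`` is true the
    candidate code must equal the pattern (no descendant matching).
    """

    system: CodeSystem
    pattern: str
    exact: bool = False

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty code pattern")
        if "." in self.pattern or self.pattern != self.pattern.upper():
            raise ValueError(f"pattern not normalized: {self.pattern!r}")
        if self.pattern.count("?") > 1:
            raise ValueError(f"at most one wildcard allowed: {self.pattern!r}")


def normalize(raw: str, system: CodeSystem | str) -> NormalizedCode:
    """Normalize a raw code string: strip whitespace, upper-case, drop dots.

    Idempotent.  Raises ``ValueError`` on input with no alphanumeric content.
    """
    system = CodeSystem(system)
    text = _WS.sub("", raw).upper().replace(".", "")
    if not text or not _ALNUM.search(text):
        raise ValueError(f"unparseable code: {raw!r}")
    return NormalizedCode(system=system, text=text)


def _chars_align(pattern: str, text: str) -> bool:
    return all(p == "?" or p == c for p, c in zip(pattern, text))


def matches(code: NormalizedCode, pattern: CodePattern) -> bool:
    """True iff ``code`` falls under ``pattern``.

    Prefix semantics: the code must be at least as long as the pattern and
    agree on every pattern position (``?`` matches any one character).
    Exact patterns require equal length.  A coding-system mismatch is simply
    a non-match, never an error.
    """
    if code.system is not pattern.system:
        return False
    if len(code.text) < len(pattern.pattern):
        return False
    if pattern.exact and len(code.text) != len(pattern.pattern):
        return False
    return _chars_align(pattern.pattern, code.text)


def any_match(codes, patterns) -> bool:
    """True iff some code in ``codes`` matches some pattern in ``patterns``."""
    return any(matches(c, p) for c in codes for p in patterns)


def patterns_overlap(a: CodePattern, b: CodePattern) -> bool:
    """True iff some concrete code could match both patterns.

    Two prefix patterns overlap when they agree on every shared position
    (wildcards agree with anything).  An exact pattern can only be matched
    by itself, so the other pattern must be a (wildcard-compatible) prefix
    of it.
    """
    if a.system is not b.system:
        return False
    # Position-wise compatibility over the shared prefix; zip stops at the
    # shorter pattern, which is exactly the prefix region that must agree.
    if any(x != y and x != "?" and y != "?" for x, y in zip(a.pattern, b.pattern)):
        return False
    if a.exact and len(b.pattern) > len(a.pattern):
        return False
    if b.exact and len(a.pattern) > len(b.pattern):
        return False
    return True
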