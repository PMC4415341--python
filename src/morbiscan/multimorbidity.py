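"""Multimorbidity aggregation: person x condition matrices, count
distributions, source-sensitivity comparisons, and age tabulations.

A condition counts toward a reference period (e.g. one fiscal year) when
its active interval overlaps the period by at least one day: permanent
conditions from their index date onward, remitting conditions while within
``remission_years`` of their most recent relevant code.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .engine import SourceSet, ascertain, relevant_code_dates
from .records import PersonDemographics, PersonHistory, age_at
from .registry import ConditionRegistry, Permanence, WindowConvention

__all__ = [
    "ConditionMatrix",
    "MultimorbidityReport",
    "condition_matrix",
    "multimorbidity_report",
    "source_sensitivity",
    "SourceSensitivity",
    "counts_by_age",
    "COUNT_BINS",
]

COUNT_BINS = ["0", "1", "2", "3", "4", "5+"]


@dataclass(frozen=True)
class ConditionMatrix:
    """Boolean person x condition activity flags over a reference period."""

    persons: tuple[str, ...]
    conditions: tuple[str, ...]
    flags: np.ndarray  # bool, shape (n_persons, n_conditions)
    period: tuple[dt.date, dt.date]
    sources: SourceSet

    def __post_init__(self) -> None:
        if self.flags.shape != (len(self.persons), len(self.conditions)):
            raise ValueError("flag matrix shape does not match person/condition ids")
        if self.period[0] > self.period[1]:
            raise ValueError("reference period start after end")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags, index=list(self.persons), columns=list(self.conditions))

    def counts(self) -> np.ndarray:
        return self.flags.sum(axis=1)


def _active_in_period(
    present: bool,
    index_date: Optional[dt.date],
    permanent: bool,
    remission_years: Optional[int],
    relevant_dates: Sequence[dt.date],
    period: tuple[dt.date, dt.date],
) -> bool:
    if not present or index_date is None or index_date > period[1]:
        return False
    if permanent:
        return True
    assert remission_years is not None
    # Remitting: active on some day t in the period iff there is a relevant
    # code c with c <= t <= c + remission_years and t >= index (closed ends).
    for c in list(relevant_dates) + [index_date]:
        horizon = c + relativedelta(years=remission_years)
        if horizon >= period[0] and horizon >= index_date and max(c, index_date) <= period[1]:
            return True
    return False


def condition_matrix(
    histories: dict[str, PersonHistory],
    registry: ConditionRegistry,
    sources: SourceSet = SourceSet(),
    period: tuple[dt.date, dt.date] = (dt.date(2008, 4, 1), dt.date(2009, 3, 31)),
    convention: WindowConvention = WindowConvention.CALENDAR,
) -> ConditionMatrix:
    """Ascertain every condition for every person and flag activity in the
    reference period (default: the 2008/2009 fiscal year)."""
    persons = tuple(sorted(histories))
    conditions = tuple(registry.ids)
    flags = np.zeros((len(persons), len(conditions)), dtype=bool)
    for i, pid in enumerate(persons):
        hist = histories[pid]
        for j, cond in enumerate(registry.conditions):
            res = ascertain(hist, cond, sources, convention)
            if not res.present:
                continue
            rel = (
                relevant_code_dates(hist, cond, sources)
                if cond.permanence is Permanence.REMITTING
                else ()
            )
            flags[i, j] = _active_in_period(
                res.present,
                res.index_date,
                cond.permanence is Permanence.PERMANENT,
                cond.remission_years,
                rel,
                period,
            )
    return ConditionMatrix(persons=persons, conditions=conditions, flags=flags,
                           period=period, sources=sources)


@dataclass(frozen=True)
class MultimorbidityReport:
    """Distribution of per-person condition counts plus prevalences.

    Percentages are reported to one decimal and always recomputed from the
    integer counts (single rounding step, no drift).
    """

    n_persons: int
    distribution_counts: dict[str, int]  # keys COUNT_BINS
    distribution_pct: dict[str, float]
    m2_plus: float
    m3_plus: float
    per_condition_prevalence: dict[str, float]
    sources_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [self.distribution_counts[b] for b in COUNT_BINS],
                "percent": [self.distribution_pct[b] for b in COUNT_BINS],
            },
            index=COUNT_BINS,
        )


def _pct(numer: int, denom: int) -> float:
    return round(100.0 * numer / denom, 1) if denom else 0.0


def multimorbidity_report(matrix: ConditionMatrix) -> MultimorbidityReport:
    counts = matrix.counts()
    n = len(matrix.persons)
    binned = {b: 0 for b in COUNT_BINS}
    for c in counts:
        binned[str(c) if c < 5 else "5+"] += 1
    m2 = int((counts >= 2).sum())
    m3 = int((counts >= 3).sum())
    prev = {
        cond: _pct(int(matrix.flags[:, j].sum()), n)
        for j, cond in enumerate(matrix.conditions)
    }
    return MultimorbidityReport(
        n_persons=n,
        distribution_counts=binned,
        distribution_pct={b: _pct(v, n) for b, v in binned.items()},
        m2_plus=_pct(m2, n),
        m3_plus=_pct(m3, n),
        per_condition_prevalence=prev,
        sources_label=matrix.sources.label(),
    )


@dataclass(frozen=True)
class SourceSensitivity:
    """Per-source-set multimorbidity reports and a prevalence comparison.

    ``prevalence`` has one row per condition and one column per source set;
    ``reduction_flags`` marks, relative to the fullest source set, conditions
    whose prevalence dropped 25-50% ("a") or more than 50% ("b")."""

    reports: dict[str, MultimorbidityReport]
    prevalence: pd.DataFrame
    reduction_flags: pd.DataFrame
    reference_label: str

    def render(self) -> str:
        cols = list(self.prevalence.columns)
        widths = {c: max(len(c), 6) for c in cols}
        name_w = max(len(i) for i in self.prevalence.index)
        lines = [
            "Prevalence (%) by source set"
            + (f" (reference: {self.reference_label})" if self.reference_label else ""),
            " " * name_w + "  " + "  ".join(c.rjust(widths[c]) for c in cols),
        ]
        for cond in self.prevalence.index:
            cells = []
            for c in cols:
                v = f"{self.prevalence.loc[cond, c]:.1f}"
                flag = self.reduction_flags.loc[cond, c]
                cells.append((v + (flag or "")).rjust(widths[c]))
            lines.append(cond.ljust(name_w) + "  " + "  ".join(cells))
        lines.append("")
        lines.append("flags: a = prevalence reduced 25-50% vs reference, b = reduced >50%")
        return "\n".join(lines)


def source_sensitivity(
    histories: dict[str, PersonHistory],
    registry: ConditionRegistry,
    source_sets: Sequence[SourceSet],
    period: tuple[dt.date, dt.date] = (dt.date(2008, 4, 1), dt.date(2009, 3, 31)),
    convention: WindowConvention = WindowConvention.CALENDAR,
) -> SourceSensitivity:
    """Recompute the multimorbidity report under each source restriction.

    The reference for reduction flags is the fullest set provided (most
    included streams; labs break ties)."""
    if not source_sets:
        raise ValueError("at least one source set required")
    labels = []
    reports: dict[str, MultimorbidityReport] = {}
    for ss in source_sets:
        label = ss.label()
        if label in reports:
            continue
        matrix = condition_matrix(histories, registry, ss, period, convention)
        reports[label] = multimorbidity_report(matrix)
        labels.append((label, ss))
    ref_label = max(labels, key=lambda t: (len(t[1].included), t[1].use_labs))[0]
    conds = list(registry.ids)
    prev = pd.DataFrame(
        {label: [reports[label].per_condition_prevalence[c] for c in conds]
         for label, _ in labels},
        index=conds,
    )
    flags = pd.DataFrame("", index=conds, columns=[l for l, _ in labels])
    for cond in conds:
        ref = prev.loc[cond, ref_label]
        if ref <= 0:
            continue
        for label, _ in labels:
            drop = (ref - prev.loc[cond, label]) / ref
            if drop > 0.5:
                flags.loc[cond, label] = "b"
            elif drop >= 0.25:
                flags.loc[cond, label] = "a"
    return SourceSensitivity(reports=reports, prevalence=prev,
                             reduction_flags=flags, reference_label=ref_label)


def counts_by_age(
    matrix: ConditionMatrix,
    demographics: dict[str, PersonDemographics],
    age_edges: Sequence[int] = (18, 30, 40, 50, 60, 70, 80),
) -> pd.DataFrame:
    """Tabulate the morbidity-count distribution within age bins.

    ``age_edges`` give left-closed bin edges; the last bin is open-ended
    (e.g. 18-29, ..., 80+).  Age is taken at the period start.  Persons with
    unknown birth dates land in an "unknown" row.  Each row holds the
    percentage share per count bin (summing to 100 for non-empty rows) and
    the bin size ``n``.
    """
    edges = list(age_edges)
    if edges != sorted(set(edges)):
        raise ValueError("age edges must be strictly increasing")
    labels = [f"{a}-{b - 1}" for a, b in zip(edges, edges[1:])] + [f"{edges[-1]}+"]
    at = matrix.period[0]
    rows = {lab: np.zeros(len(COUNT_BINS), dtype=int) for lab in labels}
    rows["unknown"] = np.zeros(len(COUNT_BINS), dtype=int)
    counts = matrix.counts()
    for i, pid in enumerate(matrix.persons):
        demo = demographics.get(pid)
        if demo is None or demo.birth_date is None:
            lab = "unknown"
        else:
            age = age_at(demo.birth_date, at)
            if age < edges[0]:
                lab = "unknown"
            else:
                idx = max(k for k, e in enumerate(edges) if age >= e)
                lab = labels[idx]
        b = counts[i] if counts[i] < 5 else 5
        rows[lab][b] += 1
    out = pd.DataFrame(index=list(rows), columns=COUNT_BINS, dtype=float)
    ns = []
    for lab, vec in rows.items():
        n = int(vec.sum())
        ns.append(n)
        out.loc[lab] = [(round(100.0 * v / n, 1) if n else 0.0) for v in vec]
    out["n"] = ns
    return out
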