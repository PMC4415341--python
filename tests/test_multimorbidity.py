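"""Multimorbidity matrices, count distributions, source sensitivity, age tables."""

import datetime as dt

import numpy as np
import pytest

from morbiscan.codes import CodeSystem
from morbiscan.engine import SourceSet, active_at, ascertain, relevant_code_dates
from morbiscan.multimorbidity import (
    COUNT_BINS,
    ConditionMatrix,
    condition_matrix,
    counts_by_age,
    multimorbidity_report,
    source_sensitivity,
)
from morbiscan.records import PersonDemographics, Sex, build_histories
from morbiscan.registry import Permanence, Source

from .conftest import history, make_encounter

FY2008 = (dt.date(2008, 4, 1), dt.date(2009, 3, 31))
ALL = SourceSet()


def _matrix(counts_per_person, n_conditions=30):
    """Matrix with the given number of active conditions per person."""
    persons = tuple(f"p{i}" for i in range(len(counts_per_person)))
    conds = tuple(f"c{j}" for j in range(n_conditions))
    flags = np.zeros((len(persons), n_conditions), dtype=bool)
    for i, k in enumerate(counts_per_person):
        flags[i, :k] = True
    return ConditionMatrix(persons=persons, conditions=conds, flags=flags,
                           period=FY2008, sources=ALL)


class TestReportArithmetic:
    def test_four_person_distribution(self):
        rep = multimorbidity_report(_matrix([0, 1, 2, 3]))
        assert rep.m2_plus == 50.0
        assert rep.m3_plus == 25.0
        assert rep.distribution_counts == {"0": 1, "1": 1, "2": 1, "3": 1, "4": 0, "5+": 0}
        assert sum(rep.distribution_counts.values()) == rep.n_persons

    def test_all_zero_matrix(self):
        rep = multimorbidity_report(_matrix([0, 0, 0]))
        assert rep.distribution_pct["0"] == 100.0
        assert rep.m2_plus == 0.0

    def test_seven_conditions_top_code_into_five_plus(self):
        rep = multimorbidity_report(_matrix([7]))
        assert rep.distribution_pct["5+"] == 100.0

    def test_percentages_recompute_exactly_from_counts(self):
        rep = multimorbidity_report(_matrix([0, 1, 1, 2, 2, 2, 5]))
        n = rep.n_persons
        for b in COUNT_BINS:
            assert rep.distribution_pct[b] == round(100.0 * rep.distribution_counts[b] / n, 1)
        m2_count = sum(rep.distribution_counts[b] for b in ("2", "3", "4", "5+"))
        assert rep.m2_plus == round(100.0 * m2_count / n, 1)


class TestConditionMatrix:
    def test_permanent_condition_flagged_years_after_index(self, registry):
        h = history(make_encounter("r1", "2000-01-01", codes="25001"))
        histories = {"p1": h}
        m = condition_matrix(histories, registry, ALL, FY2008)
        assert m.to_frame().loc["p1", "diabetes"]

    def test_remitted_depression_not_flagged(self, registry):
        h = history(
            make_encounter("r1", "2004-06-01", source=Source.CLAIM, codes="311"),
            make_encounter("r2", "2005-01-01", source=Source.CLAIM, codes="311"),
        )
        m = condition_matrix({"p1": h}, registry, ALL, FY2008)
        assert not m.to_frame().loc["p1", "depression"]

    def test_depression_active_when_remission_overlaps_period_start(self, registry):
        h = history(
            make_encounter("r1", "2006-02-01", source=Source.CLAIM, codes="311"),
            make_encounter("r2", "2006-06-01", source=Source.CLAIM, codes="311"),
        )
        # last code 2006-06-01 + 2y = 2008-06-01, inside FY2008
        m = condition_matrix({"p1": h}, registry, ALL, FY2008)
        assert m.to_frame().loc["p1", "depression"]

    def test_index_after_period_end_not_flagged(self, registry):
        h = history(make_encounter("r1", "2009-06-01", codes="25001"))
        m = condition_matrix({"p1": h}, registry, ALL, FY2008)
        assert not m.to_frame().loc["p1", "diabetes"]

    def test_empty_cohort_yields_empty_matrix(self, registry):
        m = condition_matrix({}, registry, ALL, FY2008)
        assert m.flags.shape == (0, 30)

    def test_period_flag_agrees_with_daily_active_at_sampling(self, registry):
        """The interval-overlap shortcut must agree with point-wise activity."""
        cond = registry["depression"]
        probes = [
            ["2005-06-01", "2006-03-15"],
            ["2006-04-02", "2007-03-30"],
            ["2003-01-01", "2004-01-01"],
            ["2008-06-01", "2008-07-01"],
        ]
        for dates in probes:
            h = history(*[
                make_encounter(f"r{i}", d, source=Source.CLAIM, codes="311")
                for i, d in enumerate(dates)
            ])
            m = condition_matrix({"p1": h}, registry, ALL, FY2008)
            flagged = bool(m.to_frame().loc["p1", "depression"])
            res = ascertain(h, cond, ALL)
            rel = relevant_code_dates(h, cond, ALL)
            day = FY2008[0]
            sampled = False
            while day <= FY2008[1]:
                if res.present and active_at(res, cond, rel, day):
                    sampled = True
                    break
                day += dt.timedelta(days=1)
            assert flagged == sampled, dates


class TestSourceSensitivity:
    def _histories(self, registry):
        # claims-only diabetes evidence; hospital-based hypertension
        h1 = history(
            make_encounter("r1", "2008-05-01", source=Source.CLAIM, codes="2500"),
            make_encounter("r2", "2008-09-01", source=Source.CLAIM, codes="2500"),
            person_id="p1",
        )
        h2 = history(make_encounter("r3", "2008-05-01", codes="401", person_id="p2"),
                     person_id="p2")
        return {"p1": h1, "p2": h2}

    def test_claims_only_condition_vanishes_under_hospitalizations_only(self, registry):
        sens = source_sensitivity(
            self._histories(registry), registry,
            [SourceSet.of("hosp"), SourceSet.of("hosp", "claim", "accs")],
            FY2008,
        )
        assert sens.prevalence.loc["diabetes", "hosp"] == 0.0
        assert sens.prevalence.loc["diabetes", "hosp+claim+accs"] == 50.0
        assert sens.reduction_flags.loc["diabetes", "hosp"] == "b"

    def test_prevalence_monotone_in_sources_for_exclusion_free_conditions(self, registry):
        sens = source_sensitivity(
            self._histories(registry), registry,
            [SourceSet.of("hosp"), SourceSet.of("hosp", "claim"),
             SourceSet.of("hosp", "claim", "accs")],
            FY2008,
        )
        free = [c.id for c in registry.conditions if c.exclusions.empty]
        for cond in free:
            row = sens.prevalence.loc[cond]
            assert row["hosp"] <= row["hosp+claim"] <= row["hosp+claim+accs"]

    def test_identical_source_sets_give_identical_reports(self, registry):
        sens = source_sensitivity(
            self._histories(registry), registry,
            [SourceSet.of("hosp", "claim", "accs"), SourceSet.of("hosp", "claim", "accs")],
            FY2008,
        )
        assert list(sens.reports) == ["hosp+claim+accs"]

    def test_render_mentions_reduction_flags(self, registry):
        sens = source_sensitivity(
            self._histories(registry), registry,
            [SourceSet.of("hosp"), SourceSet.of("hosp", "claim", "accs")], FY2008,
        )
        text = sens.render()
        assert "reduced >50%" in text and "diabetes" in text


class TestCountsByAge:
    def _demo(self, ages):
        return {
            f"p{i}": PersonDemographics(
                f"p{i}", FY2008[0] - dt.timedelta(days=int(a * 365.25) + 10), Sex.F)
            for i, a in enumerate(ages)
        }

    def test_rows_sum_to_hundred_for_nonempty_bins(self):
        matrix = _matrix([0, 1, 2, 3, 6])
        table = counts_by_age(matrix, self._demo([25, 35, 45, 62, 85]), (18, 30, 40, 50, 60, 70, 80))
        for lab, row in table.iterrows():
            if row["n"] > 0:
                assert abs(sum(row[b] for b in COUNT_BINS) - 100.0) < 0.3

    def test_empty_bin_is_all_zeros(self):
        matrix = _matrix([1])
        table = counts_by_age(matrix, self._demo([25]), (18, 30, 40))
        assert table.loc["30-39", COUNT_BINS].sum() == 0.0
        assert table.loc["30-39", "n"] == 0

    def test_person_just_under_edge_stays_in_lower_bin(self):
        matrix = _matrix([1])
        demo = {"p0": PersonDemographics(
            "p0", FY2008[0] - dt.timedelta(days=int(49.9 * 365.25)), Sex.M)}
        table = counts_by_age(matrix, demo, (18, 50, 80))
        assert table.loc["18-49", "n"] == 1

    def test_unknown_birth_date_lands_in_unknown_row(self):
        matrix = _matrix([2])
        demo = {"p0": PersonDemographics("p0", None, Sex.U)}
        table = counts_by_age(matrix, demo, (18, 50))
        assert table.loc["unknown", "n"] == 1

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            counts_by_age(_matrix([0]), {}, (50, 18))
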