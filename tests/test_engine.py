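"""Evidence-rule engine: windows, roles, exclusions, labs, remission."""

import datetime as dt
import itertools

import numpy as np
import pytest
from dateutil.relativedelta import relativedelta

from morbiscan.codes import CodeSystem
from morbiscan.engine import (
    AscertainmentResult,
    SourceSet,
    active_at,
    ascertain,
    ascertain_all,
    evaluate_aux,
    evaluate_rule,
    lab_ckd,
    relevant_code_dates,
)
from morbiscan.records import Analyte, DiagnosisRole, LabResult
from morbiscan.registry import (
    EvidenceRule,
    Source,
    WindowConvention,
    with_surgery_procedures,
)

from .conftest import history, make_encounter

ALL = SourceSet()
CAL = WindowConvention.CALENDAR
DAYS = WindowConvention.DAYS


def accs_rule(n=3, years=2):
    return EvidenceRule.model_validate(
        {"id": f"accs-{n}", "source": "AMBULATORY", "min_count": n,
         "window": {"value": years, "unit": "years"}}
    )


def ambulatory(rid, date, code="J451"):
    return make_encounter(rid, date, source=Source.AMBULATORY, codes=code,
                          system=CodeSystem.ICD10)


class TestEvaluateRule:
    def test_three_visits_within_two_years_qualify_from_first_date(self):
        recs = [ambulatory("r1", "2008-01-01"), ambulatory("r2", "2008-06-01"),
                ambulatory("r3", "2009-12-01")]
        evidence = evaluate_rule(recs, accs_rule())
        assert evidence is not None
        assert evidence[0].date == dt.date(2008, 1, 1)
        assert [r.record_id for r in evidence] == ["r1", "r2", "r3"]

    def test_no_triple_fits_the_window(self):
        recs = [ambulatory("r1", "2008-01-01"), ambulatory("r2", "2008-06-01"),
                ambulatory("r3", "2010-02-01")]
        assert evaluate_rule(recs, accs_rule()) is None

    def test_single_record_rule_takes_earliest(self):
        rule = EvidenceRule.model_validate(
            {"id": "hosp-1", "source": "HOSPITALIZATION", "min_count": 1})
        recs = [make_encounter("r1", "2008-03-01"), make_encounter("r2", "2009-01-01")]
        evidence = evaluate_rule(recs, rule)
        assert [r.record_id for r in evidence] == ["r1"]

    def test_same_day_duplicates_never_satisfy_a_multi_record_rule(self):
        rule = accs_rule(n=2)
        recs = [ambulatory("r1", "2008-01-01"), ambulatory("r2", "2008-01-01")]
        assert evaluate_rule(recs, rule) is None

    @pytest.mark.parametrize("convention,boundary_ok,one_past", [
        (CAL, dt.date(2010, 1, 1), dt.date(2010, 1, 2)),
        (DAYS, dt.date(2008, 1, 1) + dt.timedelta(days=730),
         dt.date(2008, 1, 1) + dt.timedelta(days=731)),
    ])
    def test_two_year_window_boundary(self, convention, boundary_ok, one_past):
        rule = accs_rule(n=2)
        ok = [ambulatory("r1", "2008-01-01"), ambulatory("r2", boundary_ok)]
        bad = [ambulatory("r1", "2008-01-01"), ambulatory("r2", one_past)]
        assert evaluate_rule(ok, rule, convention) is not None
        assert evaluate_rule(bad, rule, convention) is None


class TestBruteForceOracle:
    """evaluate_rule against exhaustive subset enumeration on small inputs."""

    @staticmethod
    def oracle(records, min_count, window_end):
        """Independent re-derivation: enumerate all record subsets of the
        required size with pairwise-distinct dates and admissible span;
        return the lexicographically earliest date tuple, or None."""
        best = None
        for combo in itertools.combinations(records, min_count):
            dates = sorted(r.date for r in combo)
            if len(set(dates)) != min_count:
                continue
            if window_end is not None and dates[-1] > window_end(dates[0]):
                continue
            if best is None or tuple(dates) < best:
                best = tuple(dates)
        return best

    @pytest.mark.parametrize("min_count,years", [(2, 2), (3, 2), (3, 1), (2, 3)])
    def test_qualification_and_index_agree(self, min_count, years):
        rng = np.random.default_rng(min_count * 100 + years)
        rule = accs_rule(n=min_count, years=years)
        base = dt.date(2007, 1, 1)
        for trial in range(400):
            n = int(rng.integers(0, 12))
            dates = sorted(base + dt.timedelta(days=int(d))
                           for d in rng.integers(0, 1500, size=n))
            recs = [ambulatory(f"r{i}", d) for i, d in enumerate(dates)]
            got = evaluate_rule(recs, rule)
            expected = self.oracle(recs, min_count, lambda s: s + relativedelta(years=years))
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert tuple(r.date for r in got) == expected
                assert got[0].date == expected[0]


class TestAscertain:
    def test_diabetes_single_hospitalization(self, registry):
        h = history(make_encounter("r1", "2008-03-01", codes="25001"))
        res = ascertain(h, registry["diabetes"], ALL)
        assert res.present and res.index_date == dt.date(2008, 3, 1)
        assert res.satisfied_rule == "hosp-1"
        assert res.supporting_record_ids == ("r1",)

    def test_two_claims_take_min_index_over_rules(self, registry):
        h = history(
            make_encounter("r1", "2008-01-10", source=Source.CLAIM, codes="25002"),
            make_encounter("r2", "2009-06-01", source=Source.CLAIM, codes="2500"),
            make_encounter("r3", "2009-08-01", codes="25001"),
        )
        res = ascertain(h, registry["diabetes"], ALL)
        # the claims pair starts earlier than the hospitalization
        assert res.index_date == dt.date(2008, 1, 10)
        assert res.satisfied_rule.startswith("claims")

    def test_ibs_vetoed_by_unconditional_exclusion_code(self, registry):
        h = history(
            make_encounter("r1", "2008-01-01", source=Source.CLAIM, codes="K580",
                           system=CodeSystem.ICD10),
            make_encounter("r2", "2008-06-01", source=Source.CLAIM, codes="K58",
                           system=CodeSystem.ICD10),
            make_encounter("r3", "2010-01-01", source=Source.CLAIM, codes="K50",
                           system=CodeSystem.ICD10),
        )
        res = ascertain(h, registry["irritable_bowel_syndrome"], ALL)
        assert not res.present
        assert "K50" in res.excluded_by

    def test_exclusion_outside_active_sources_does_not_veto(self, registry):
        h = history(
            make_encounter("r1", "2008-01-01", source=Source.CLAIM, codes="K58",
                           system=CodeSystem.ICD10),
            make_encounter("r2", "2008-06-01", source=Source.CLAIM, codes="K58",
                           system=CodeSystem.ICD10),
            make_encounter("r3", "2010-01-01", source=Source.AMBULATORY, codes="K50",
                           system=CodeSystem.ICD10),
        )
        only_claims = SourceSet.of("claim")
        assert ascertain(h, registry["irritable_bowel_syndrome"], only_claims).present

    def test_constipation_conditional_carveout_voids_the_record(self, registry):
        cond = registry["severe_constipation"]
        tainted = history(make_encounter("r1", "2008-01-01", codes=("5609", "78901")))
        clean = history(make_encounter("r1", "2008-01-01", codes=("5609", "78999")))
        assert not ascertain(tainted, cond, ALL).present
        assert ascertain(clean, cond, ALL).present

    def test_carveout_spares_other_qualifying_codes_on_same_record(self, registry):
        cond = registry["severe_constipation"]
        h = history(make_encounter("r1", "2008-01-01", codes=("5609", "78901", "5601")))
        res = ascertain(h, cond, ALL)
        assert res.present  # 560.1 is untouched by the 560.9 carve-out

    def test_surgical_hospitalization_cannot_serve_as_ibs_evidence(self, registry):
        reg = with_surgery_procedures(registry, ["CCP87"])
        cond = reg["irritable_bowel_syndrome"]
        surgical = history(
            make_encounter("r1", "2008-01-01", codes="5641", procedures=("CCP871",)))
        plain = history(make_encounter("r1", "2008-01-01", codes="5641"))
        assert not ascertain(surgical, cond, ALL).present
        assert ascertain(plain, cond, ALL).present

    def test_surgery_taints_the_record_not_the_person(self, registry):
        reg = with_surgery_procedures(registry, ["CCP87"])
        cond = reg["irritable_bowel_syndrome"]
        h = history(
            make_encounter("r1", "2008-01-01", codes="5641", procedures=("CCP871",)),
            make_encounter("r2", "2008-05-01", source=Source.CLAIM, codes="5641"),
            make_encounter("r3", "2009-02-01", source=Source.CLAIM, codes="5641"),
        )
        res = ascertain(h, cond, ALL)
        assert res.present and res.satisfied_rule.startswith("claims")

    def test_epilepsy_hospitalization_requires_most_responsible_role(self, registry):
        cond = registry["epilepsy"]
        other = history(make_encounter("r1", "2008-01-01", codes="345",
                                       role=DiagnosisRole.OTHER))
        mr = history(make_encounter("r1", "2008-01-01", codes="345",
                                    role=DiagnosisRole.MOST_RESPONSIBLE))
        assert not ascertain(other, cond, ALL).present
        assert ascertain(mr, cond, ALL).present

    def test_stroke_accepts_post_admit_hospitalization_diagnosis(self, registry):
        cond = registry["stroke_tia"]
        pa = history(make_encounter("r1", "2008-01-01", codes="430",
                                    role=DiagnosisRole.POST_ADMIT))
        assert ascertain(pa, cond, ALL).present

    def test_stroke_ambulatory_requires_ed_and_most_responsible(self, registry):
        cond = registry["stroke_tia"]

        def amb(ed, role):
            return history(make_encounter(
                "r1", "2008-01-01", source=Source.AMBULATORY, codes="I63",
                system=CodeSystem.ICD10, role=role, ed_flag=ed))

        assert ascertain(amb(True, DiagnosisRole.MOST_RESPONSIBLE), cond, ALL).present
        assert not ascertain(amb(False, DiagnosisRole.MOST_RESPONSIBLE), cond, ALL).present
        assert not ascertain(amb(True, DiagnosisRole.OTHER), cond, ALL).present

    def test_ibd_claims_need_gastro_or_gp_specialty(self, registry):
        cond = registry["inflammatory_bowel_disease"]

        def claims(spec):
            return history(
                make_encounter("r1", "2008-01-01", source=Source.CLAIM, codes="K50",
                               system=CodeSystem.ICD10, specialty=spec),
                make_encounter("r2", "2009-01-01", source=Source.CLAIM, codes="K50",
                               system=CodeSystem.ICD10, specialty=spec),
            )

        assert ascertain(claims("gastroenterology"), cond, ALL).present
        assert ascertain(claims("general practice"), cond, ALL).present
        assert not ascertain(claims("orthopedics"), cond, ALL).present

    def test_psoriasis_claim_restricted_to_dermatology(self, registry):
        cond = registry["psoriasis"]
        derm = history(make_encounter("r1", "2008-01-01", source=Source.CLAIM,
                                      codes="L400", system=CodeSystem.ICD10,
                                      specialty="dermatology"))
        gp = history(make_encounter("r1", "2008-01-01", source=Source.CLAIM,
                                    codes="L400", system=CodeSystem.ICD10,
                                    specialty="general practice"))
        assert ascertain(derm, cond, ALL).present
        assert not ascertain(gp, cond, ALL).present

    def test_rules_never_pool_evidence_across_sources(self, registry):
        # one claim + one hospitalization-coded claim-day must not combine
        cond = registry["diabetes"]
        h = history(
            make_encounter("r1", "2008-01-01", source=Source.CLAIM, codes="2500"),
            make_encounter("r2", "2008-06-01", source=Source.AMBULATORY, codes="2500"),
        )
        assert not ascertain(h, cond, ALL).present

    def test_empty_history_is_absent_for_all_thirty(self, registry):
        results = ascertain_all(history(), registry, ALL)
        assert len(results) == 30
        assert not any(r.present for r in results)

    def test_results_independent_of_record_input_order(self, registry):
        records = [
            make_encounter("r1", "2008-01-10", source=Source.CLAIM, codes="2500"),
            make_encounter("r2", "2008-06-01", source=Source.CLAIM, codes="25001"),
            make_encounter("r3", "2008-06-01", codes="401"),
        ]
        a = ascertain_all(history(*records), registry, ALL)
        b = ascertain_all(history(*reversed(records)), registry, ALL)
        assert a == b

    def test_adding_a_non_matching_record_changes_nothing(self, registry):
        base = [make_encounter("r1", "2008-01-01", codes="25001")]
        noise = make_encounter("zz", "2008-06-01", codes="Z000", system=CodeSystem.ICD10)
        a = ascertain_all(history(*base), registry, ALL)
        b = ascertain_all(history(*base, noise), registry, ALL)
        assert a == b

    def test_source_monotonicity_for_exclusion_free_conditions(self, registry):
        rng = np.random.default_rng(42)
        sets = [SourceSet.of("hosp"), SourceSet.of("hosp", "claim"),
                SourceSet.of("hosp", "claim", "accs")]
        free = [c for c in registry.conditions if c.exclusions.empty]
        pool = ["25001", "401", "345", "K50", "I21", "G20"]
        for _ in range(40):
            records = []
            for i in range(int(rng.integers(1, 8))):
                records.append(make_encounter(
                    f"r{i}", dt.date(2007, 1, 1) + dt.timedelta(days=int(rng.integers(0, 900))),
                    source=[Source.HOSPITALIZATION, Source.CLAIM, Source.AMBULATORY][int(rng.integers(3))],
                    codes=pool[int(rng.integers(len(pool)))],
                    system=CodeSystem.ICD9CM if rng.integers(2) else CodeSystem.ICD10,
                    role=[DiagnosisRole.MOST_RESPONSIBLE, DiagnosisRole.OTHER][int(rng.integers(2))],
                ))
            h = history(*records)
            for cond in free:
                prev = None
                for ss in sets:
                    res = ascertain(h, cond, ss)
                    if prev is not None and prev.present:
                        assert res.present, (cond.id, ss)
                        assert res.index_date <= prev.index_date
                    prev = res


class TestLabCkd:
    def test_two_low_egfr_within_a_year_qualify(self):
        labs = [LabResult("p", dt.date(2008, 1, 1), Analyte.EGFR, 55),
                LabResult("p", dt.date(2008, 8, 1), Analyte.EGFR, 58)]
        assert lab_ckd(labs) == (True, dt.date(2008, 1, 1))

    def test_mean_above_threshold_does_not_qualify(self):
        labs = [LabResult("p", dt.date(2008, 1, 1), Analyte.EGFR, 55),
                LabResult("p", dt.date(2008, 8, 1), Analyte.EGFR, 70)]
        assert lab_ckd(labs) == (False, None)

    def test_single_measurement_is_never_enough(self):
        labs = [LabResult("p", dt.date(2008, 1, 1), Analyte.EGFR, 40)]
        assert lab_ckd(labs) == (False, None)

    def test_acr_uses_strictly_greater_than_thirty(self):
        def pair(v1, v2):
            return [LabResult("p", dt.date(2008, 1, 1), Analyte.ACR, v1),
                    LabResult("p", dt.date(2008, 6, 1), Analyte.ACR, v2)]

        assert lab_ckd(pair(31, 31))[0] is True
        assert lab_ckd(pair(30, 30))[0] is False  # mean exactly 30 is not >30

    def test_measurements_beyond_twelve_months_do_not_pair(self):
        labs = [LabResult("p", dt.date(2008, 1, 1), Analyte.EGFR, 40),
                LabResult("p", dt.date(2009, 1, 2), Analyte.EGFR, 40)]
        assert lab_ckd(labs) == (False, None)

    def test_combined_ckd_indexes_at_the_earlier_pathway(self, registry):
        cond = registry["chronic_kidney_disease"]
        labs = [LabResult("p1", dt.date(2007, 1, 1), Analyte.EGFR, 50),
                LabResult("p1", dt.date(2007, 6, 1), Analyte.EGFR, 52)]
        admin = make_encounter("r1", "2008-05-01", codes="585")
        h = history(admin, labs=labs)
        res = ascertain(h, cond, ALL)
        assert res.present and res.index_date == dt.date(2007, 1, 1) and res.lab_based

        labs_late = [LabResult("p1", dt.date(2009, 1, 1), Analyte.EGFR, 50),
                     LabResult("p1", dt.date(2009, 6, 1), Analyte.EGFR, 52)]
        h2 = history(admin, labs=labs_late)
        res2 = ascertain(h2, cond, ALL)
        assert res2.present and res2.index_date == dt.date(2008, 5, 1) and not res2.lab_based

    def test_labs_ignored_when_source_set_excludes_them(self, registry):
        cond = registry["chronic_kidney_disease"]
        labs = [LabResult("p1", dt.date(2007, 1, 1), Analyte.EGFR, 50),
                LabResult("p1", dt.date(2007, 6, 1), Analyte.EGFR, 52)]
        h = history(labs=labs)
        no_labs = SourceSet(use_labs=False)
        assert not ascertain(h, cond, no_labs).present


class TestActiveAt:
    def _result(self, index):
        return AscertainmentResult("p", "x", True, index_date=index,
                                   satisfied_rule="hosp-1", supporting_record_ids=("r1",))

    def test_permanent_condition_persists_indefinitely(self, registry):
        cond = registry["diabetes"]
        res = self._result(dt.date(2008, 3, 1))
        assert active_at(res, cond, [], dt.date(2018, 3, 1))
        assert active_at(res, cond, [], dt.date(2048, 1, 1))
        assert not active_at(res, cond, [], dt.date(2008, 2, 28))

    def test_remitting_condition_deactivates_after_last_code_plus_window(self, registry):
        cond = registry["depression"]  # 2-year remission
        codes = [dt.date(2008, 1, 15), dt.date(2008, 3, 1)]
        res = self._result(codes[0])
        assert active_at(res, cond, codes, dt.date(2009, 12, 31))
        assert active_at(res, cond, codes, dt.date(2010, 3, 1))  # boundary: closed
        assert not active_at(res, cond, codes, dt.date(2010, 3, 2))

    def test_later_code_refreshes_the_remission_clock(self, registry):
        cond = registry["depression"]
        codes = [dt.date(2008, 1, 15), dt.date(2011, 1, 1)]
        res = self._result(codes[0])
        # inactive in the gap, reactivated by the 2011 code
        assert not active_at(res, cond, codes, dt.date(2010, 6, 1))
        assert active_at(res, cond, codes, dt.date(2012, 6, 1))

    def test_absent_result_is_a_contract_violation(self, registry):
        absent = AscertainmentResult("p", "depression", False)
        with pytest.raises(ValueError):
            active_at(absent, registry["depression"], [], dt.date(2010, 1, 1))


def test_relevant_dates_ignore_role_and_specialty_restrictions(registry):
    cond = registry["epilepsy"]
    h = history(make_encounter("r1", "2008-01-01", codes="345", role=DiagnosisRole.OTHER))
    assert relevant_code_dates(h, cond, ALL) == [dt.date(2008, 1, 1)]


def test_cirrhosis_decompensation_flag_honours_carveouts(registry):
    cond = registry["cirrhosis"]
    decomp = history(make_encounter("r1", "2008-01-01", codes=("5712", "5722")))
    carved = history(make_encounter("r1", "2008-01-01", codes=("5712", "56781")))
    assert evaluate_aux(decomp, cond, ALL)["hepatic_decompensation"] is True
    assert evaluate_aux(carved, cond, ALL)["hepatic_decompensation"] is False
    # 567.2 must not generalize: 56722 is not decompensation
    not_general = history(make_encounter("r1", "2008-01-01", codes=("5712", "56722")))
    assert evaluate_aux(not_general, cond, ALL)["hepatic_decompensation"] is False
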