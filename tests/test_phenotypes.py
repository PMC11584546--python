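"""Frailty phenotype scoring against an independent brute-force enumerator."""

import itertools

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from voxfrail.phenotypes import (INDETERMINATE, AssessmentRecord,
                                 derive_hybrids, score_ebf, score_record,
                                 score_sbf, score_table)


# --- independent enumerator: statuses straight from the quoted rules -------

def brute_force_statuses(weight_loss, exhaustion, chair, grip_low, walk_low,
                         activity_low):
    ebf_met = sum([weight_loss, exhaustion])
    ebf = {0: "robust", 1: "prefrail", 2: "frail"}[ebf_met]
    sbf_met = sum([chair, grip_low, walk_low, activity_low])
    sbf = "frail" if sbf_met >= 3 else ("prefrail" if sbf_met >= 1 else "robust")
    hbf_e = ebf == "frail" and sbf in ("prefrail", "frail")
    hbf_s = sbf == "frail" and ebf in ("prefrail", "frail")
    if ebf == "frail" and sbf == "frail":
        four = "both"
    elif ebf == "frail":
        four = "EBF-only"
    elif sbf == "frail":
        four = "SBF-only"
    else:
        four = "nonfrail"
    return ebf_met, ebf, sbf_met, sbf, hbf_e, hbf_s, four


def record_realizing(weight_loss, exhaustion, chair, grip_low, walk_low,
                     activity_low):
    return AssessmentRecord(
        subject_id="T", sex="male",
        weight_loss_kg=6.0 if weight_loss else 0.0,
        weight_loss_pct=8.0 if weight_loss else 0.0,
        exhaustion=exhaustion,
        chair_rise_unable=chair,
        grip_kg=25.0 if grip_low else 35.0,
        gait_speed_mps=0.8 if walk_low else 1.3,
        non_ambulatory=False,
        adl_deterioration=activity_low,
    )


class TestTruthTable:
    def test_all_64_criterion_combinations_match_enumerator(self):
        for combo in itertools.product([False, True], repeat=6):
            expected = brute_force_statuses(*combo)
            res = score_record(record_realizing(*combo))
            got = (res.ebf_criteria_met, res.ebf_status, res.sbf_criteria_met,
                   res.sbf_status, res.hbf_e, res.hbf_s, res.four_category)
            assert got == expected, f"mismatch for criteria {combo}"

    def test_both_hybrids_iff_both_category(self):
        for ebf in ("robust", "prefrail", "frail"):
            for sbf in ("robust", "prefrail", "frail"):
                hbf_e, hbf_s, four = derive_hybrids(ebf, sbf)
                assert (hbf_e and hbf_s) == (four == "both")

    @given(st.tuples(*[st.booleans()] * 6), st.integers(0, 5))
    def test_meeting_an_extra_criterion_never_moves_toward_robust(
            self, combo, flip):
        if combo[flip]:
            return  # only test turning a criterion on
        rank = {"robust": 0, "prefrail": 1, "frail": 2}
        before = score_record(record_realizing(*combo))
        harder = list(combo)
        harder[flip] = True
        after = score_record(record_realizing(*harder))
        assert rank[after.ebf_status] >= rank[before.ebf_status]
        assert rank[after.sbf_status] >= rank[before.sbf_status]


class TestBoundaries:
    def test_weight_loss_kg_bound_is_inclusive(self):
        # "at least 4.5 kg": 4.5 itself meets the criterion
        r = AssessmentRecord(weight_loss_kg=4.5, weight_loss_pct=4.0,
                             exhaustion=False)
        assert score_ebf(r) == (1, "prefrail")

    def test_weight_loss_pct_bound_is_strict(self):
        r = AssessmentRecord(weight_loss_kg=0.0, weight_loss_pct=5.0,
                             exhaustion=False)
        assert score_ebf(r) == (0, "robust")
        r2 = AssessmentRecord(weight_loss_kg=0.0, weight_loss_pct=5.01,
                              exhaustion=False)
        assert score_ebf(r2) == (1, "prefrail")

    def test_two_criteria_give_frail(self):
        r = AssessmentRecord(weight_loss_kg=5.0, exhaustion=True)
        assert score_ebf(r) == (2, "frail")

    @pytest.mark.parametrize("sex, grip, low", [
        ("male", 28.0, False), ("male", 27.99, True),
        ("female", 18.0, False), ("female", 17.99, True),
    ])
    def test_grip_cutoffs_are_strict(self, sex, grip, low):
        r = AssessmentRecord(sex=sex, grip_kg=grip, gait_speed_mps=1.3,
                             chair_rise_unable=False, non_ambulatory=False,
                             adl_deterioration=False)
        assert score_sbf(r) == ((1, "prefrail") if low else (0, "robust"))

    def test_gait_cutoff_is_strict(self):
        kw = dict(sex="female", grip_kg=20.0, chair_rise_unable=False,
                  non_ambulatory=False, adl_deterioration=False)
        assert score_sbf(AssessmentRecord(gait_speed_mps=1.0, **kw)) == (0, "robust")
        assert score_sbf(AssessmentRecord(gait_speed_mps=0.99, **kw)) == (1, "prefrail")

    def test_three_of_four_gives_frail(self):
        r = AssessmentRecord(sex="male", grip_kg=27.0, gait_speed_mps=0.9,
                             chair_rise_unable=True, non_ambulatory=False,
                             adl_deterioration=False)
        assert score_sbf(r) == (3, "frail")

    def test_wheelchair_user_counts_as_low_mobility(self):
        # no gait measurement, but non-ambulatory: criterion met, not missing
        r = AssessmentRecord(sex="male", grip_kg=35.0, gait_speed_mps=None,
                             chair_rise_unable=False, non_ambulatory=True,
                             adl_deterioration=False)
        assert score_sbf(r) == (1, "prefrail")


class TestMissingness:
    def test_missing_exhaustion_is_indeterminate(self):
        r = AssessmentRecord(weight_loss_kg=5.0)
        assert score_ebf(r) == (None, INDETERMINATE)

    def test_missing_gait_without_nonambulatory_is_indeterminate(self):
        r = AssessmentRecord(sex="male", grip_kg=35.0, gait_speed_mps=None,
                             chair_rise_unable=False, non_ambulatory=False,
                             adl_deterioration=False)
        assert score_sbf(r) == (None, INDETERMINATE)

    def test_precomputed_weight_loss_flag_is_accepted(self):
        r = AssessmentRecord(weight_loss_flag=True, exhaustion=True)
        assert score_ebf(r) == (2, "frail")

    def test_indeterminate_propagates_to_hybrids(self):
        assert derive_hybrids(INDETERMINATE, "frail") == (None, None,
                                                          INDETERMINATE)


class TestHybridExamples:
    def test_ebf_frail_sbf_prefrail(self):
        assert derive_hybrids("frail", "prefrail") == (True, False, "EBF-only")

    def test_double_robust(self):
        assert derive_hybrids("robust", "robust") == (False, False, "nonfrail")

    def test_double_frail(self):
        assert derive_hybrids("frail", "frail") == (True, True, "both")


class TestTableScoring:
    def test_score_table_handles_missing_and_is_pure(self):
        df = pd.DataFrame([
            dict(subject_id="a", sex="male", weight_loss_kg=5.0,
                 weight_loss_pct=6.0, exhaustion=True, chair_rise_unable=True,
                 grip_kg=25.0, gait_speed_mps=0.8, non_ambulatory=False,
                 adl_deterioration=True),
            dict(subject_id="b", sex="female", weight_loss_kg=0.0,
                 weight_loss_pct=0.0, exhaustion=None, chair_rise_unable=False,
                 grip_kg=25.0, gait_speed_mps=1.2, non_ambulatory=False,
                 adl_deterioration=False),
        ])
        before = df.copy()
        out = score_table(df)
        pd.testing.assert_frame_equal(df, before)  # no mutation
        assert out.loc[0, "four_category"] == "both"
        assert out.loc[1, "ebf_status"] == INDETERMINATE
        assert out.loc[1, "sbf_status"] == "robust"
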