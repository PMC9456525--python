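"""New-user identification, exclusions, and follow-up construction."""

import numpy as np
import pandas as pd
import pytest

from dpp4_safety import cohort, oracles, simulate
from dpp4_safety.cohort import CohortSpec

from conftest import tiny_claims

SPEC = CohortSpec()


class TestIdentifyNewUsers:
    def test_first_fill_in_window_is_index(self):
        ds = tiny_claims([("p1", "2017-05-01", "metformin")])
        cand = cohort.identify_new_users(ds, SPEC)
        assert len(cand) == 1
        row = cand.iloc[0]
        assert row["group"] == "comparator"
        assert row["index_date"] == pd.Timestamp("2017-05-01")

    def test_washout_violation_excludes(self):
        ds = tiny_claims([
            ("p1", "2017-05-01", "dpp4_inhibitor"),
            ("p1", "2017-03-15", "metformin"),
        ])
        assert cohort.identify_new_users(ds, SPEC).empty

    def test_old_fill_outside_washout_is_fine(self):
        ds = tiny_claims([
            ("p1", "2017-05-01", "dpp4_inhibitor"),
            ("p1", "2016-05-01", "metformin"),
        ])
        cand = cohort.identify_new_users(ds, SPEC)
        assert list(cand["group"]) == ["treatment"]

    def test_both_classes_same_day_excluded(self):
        ds = tiny_claims([
            ("p1", "2017-05-01", "dpp4_inhibitor"),
            ("p1", "2017-05-01", "metformin"),
        ])
        assert cohort.identify_new_users(ds, SPEC).empty

    def test_non_study_drug_ignored_unless_strict(self):
        ds = tiny_claims([
            ("p1", "2017-05-01", "dpp4_inhibitor"),
            ("p1", "2017-04-20", "statin"),
        ])
        assert len(cohort.identify_new_users(ds, SPEC)) == 1
        strict = CohortSpec(strict_all_drug_washout=True)
        assert cohort.identify_new_users(ds, strict).empty

    def test_matches_bruteforce_on_planted_population(self, planted_claims):
        _, ds = planted_claims
        cand = cohort.identify_new_users(ds, SPEC)
        got = sorted(
            map(tuple, cand[["patient_id", "group", "index_date"]].to_numpy())
        )
        assert got == oracles.brute_new_users(ds, SPEC)


class TestApplyExclusions:
    def test_recent_stroke_attributed_to_prior_event_rule(self):
        ds = tiny_claims(
            [("p1", "2017-05-01", "metformin")],
            rows_diag=[("p1", "2017-04-01", "I639", True)],
        )
        cand = cohort.identify_new_users(ds, SPEC)
        coh, att = cohort.apply_exclusions(cand, ds, SPEC)
        assert coh.empty and att["prior_event"] == 1

    def test_nonprimary_prior_diagnosis_does_not_exclude(self):
        ds = tiny_claims(
            [("p1", "2017-05-01", "metformin")],
            rows_diag=[("p1", "2017-04-01", "I639", False)],
        )
        cand = cohort.identify_new_users(ds, SPEC)
        coh, _ = cohort.apply_exclusions(cand, ds, SPEC)
        assert len(coh) == 1

    def test_controlled_drug_within_12_months_excludes(self):
        ds = tiny_claims([
            ("p1", "2017-05-01", "metformin"),
            ("p1", "2016-09-01", "controlled_drug"),
        ])
        cand = cohort.identify_new_users(ds, SPEC)
        coh, att = cohort.apply_exclusions(cand, ds, SPEC)
        assert coh.empty and att["controlled_drug"] == 1

    def test_clean_candidates_pass_unchanged(self):
        ds = tiny_claims([
            ("p1", "2017-05-01", "metformin"),
            ("p2", "2017-06-01", "dpp4_inhibitor"),
        ])
        cand = cohort.identify_new_users(ds, SPEC)
        coh, att = cohort.apply_exclusions(cand, ds, SPEC)
        assert len(coh) == len(cand) == 2
        assert att["candidates"] - sum(
            att[k] for k in ("prior_event", "controlled_drug", "age", "enrollment")
        ) == att["cohort"]

    def test_attrition_stages_sum_on_planted_population(self, planted_claims):
        _, ds = planted_claims
        cand = cohort.identify_new_users(ds, SPEC)
        coh, att = cohort.apply_exclusions(cand, ds, SPEC)
        removed = sum(
            att[k] for k in ("prior_event", "controlled_drug", "age", "enrollment")
        )
        assert att["candidates"] - removed == att["cohort"] == len(coh)
        assert att["prior_event"] > 0 and att["controlled_drug"] > 0


class TestBuildFollowup:
    def base_ds(self, rows_diag=None, rows_enroll=None):
        return tiny_claims(
            [("p1", "2017-05-01", "metformin")],
            rows_diag=rows_diag,
            rows_enroll=rows_enroll,
        )

    def build(self, ds):
        cand = cohort.identify_new_users(ds, SPEC)
        coh, _ = cohort.apply_exclusions(cand, ds, SPEC)
        return cohort.build_followup(coh, ds, "mace", SPEC)

    def test_event_ten_months_post_index(self):
        fu = self.build(self.base_ds(rows_diag=[("p1", "2018-03-01", "I210", True)]))
        rec = fu.iloc[0]
        assert rec["event"] and rec["censor_reason"] == "outcome"
        assert rec["time_months"] == pytest.approx(10.0, abs=0.2)

    def test_disenrollment_censors(self):
        fu = self.build(
            self.base_ds(
                rows_enroll=[("p1", "2015-01-01", "2018-11-01", "disenrollment")]
            )
        )
        rec = fu.iloc[0]
        assert not rec["event"] and rec["censor_reason"] == "disenrollment"
        assert rec["time_months"] == pytest.approx(18.0, abs=0.2)

    def test_study_end_censors_and_event_after_it_ignored(self):
        fu = self.build(self.base_ds(rows_diag=[("p1", "2020-08-01", "I210", True)]))
        rec = fu.iloc[0]
        assert not rec["event"] and rec["censor_reason"] == "study_end"
        assert rec["time_months"] == pytest.approx(37.9, abs=0.2)

    def test_index_day_event_counts_at_half_day(self):
        fu = self.build(self.base_ds(rows_diag=[("p1", "2017-05-01", "I210", True)]))
        rec = fu.iloc[0]
        assert rec["event"]
        assert rec["time_months"] == pytest.approx(0.5 / 30.4375)

    def test_age75_censoring(self):
        ds = self.base_ds()
        ds.patients["birth_date"] = pd.Timestamp("1943-06-01")  # 75 in mid-2018
        fu = self.build(ds)
        rec = fu.iloc[0]
        assert rec["censor_reason"] == "age75"

    def test_unknown_outcome_rejected(self):
        ds = self.base_ds()
        cand = cohort.identify_new_users(ds, SPEC)
        coh, _ = cohort.apply_exclusions(cand, ds, SPEC)
        with pytest.raises(ValueError, match="unknown outcome"):
            cohort.build_followup(coh, ds, "sprained_ankle", SPEC)

    def test_matches_bruteforce_scan(self, planted_claims):
        _, ds = planted_claims
        cand = cohort.identify_new_users(ds, SPEC)
        coh, _ = cohort.apply_exclusions(cand, ds, SPEC)
        sub = coh.head(120)
        fu = cohort.build_followup(sub, ds, "mace", SPEC)
        brute = oracles.brute_followup(
            sub, ds, SPEC.outcome_definitions["mace"], SPEC
        )
        for _, rec in fu.iterrows():
            months, event = brute[rec["patient_id"]]
            assert rec["event"] == event
            assert rec["time_months"] == pytest.approx(months)


class TestCohortInvariants:
    def test_groups_disjoint_and_indexes_in_window(self, planted_claims):
        _, ds = planted_claims
        cand = cohort.identify_new_users(ds, SPEC)
        assert cand["patient_id"].is_unique
        start, end = map(pd.Timestamp, SPEC.enrollment_window)
        assert cand["index_date"].between(start, end).all()

    def test_followup_times_strictly_positive(self, planted_claims):
        _, ds = planted_claims
        cand = cohort.identify_new_users(ds, SPEC)
        coh, _ = cohort.apply_exclusions(cand, ds, SPEC)
        for name in ("mace", "heart_failure", "all_cardiovascular"):
            fu = cohort.build_followup(coh, ds, name, SPEC)
            assert (fu["time_months"] > 0).all()
            assert (fu.loc[fu["event"], "censor_reason"] == "outcome").all()
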