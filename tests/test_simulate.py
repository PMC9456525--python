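"""Ground-truth calibration of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from dpp4_safety import cohort, simulate, survival
from dpp4_safety.spontaneous import DrugClass, EventDefinition, build_contingency


def target_table(cfg):
    reports = simulate.generate_spontaneous_reports(cfg)
    drug = DrugClass("t", frozenset(cfg.target_drug_members))
    event = EventDefinition("t", frozenset(cfg.target_event_terms))
    return build_contingency(reports, drug, event)


class TestReportGenerator:
    def test_invalid_joint_probability_names_field(self):
        with pytest.raises(ValueError, match="reporting_ratio"):
            simulate.ReportSimConfig(
                target_drug_share=0.01, target_event_share=0.5, reporting_ratio=80.0
            )

    def test_single_case_is_well_formed(self):
        (r,) = simulate.generate_spontaneous_reports(
            simulate.ReportSimConfig(n_cases=1, seed=0)
        )
        assert r.drugs and r.events

    def test_deterministic_given_seed(self):
        cfg = simulate.ReportSimConfig(n_cases=500, seed=3)
        assert simulate.generate_spontaneous_reports(
            cfg
        ) == simulate.generate_spontaneous_reports(cfg)

    def test_independence_joint_cell_within_3sd(self):
        cfg = simulate.ReportSimConfig(
            n_cases=100_000, reporting_ratio=1.0, seed=17,
            n_background_drugs=5, n_background_events=5,
        )
        t = target_table(cfg)
        expect = cfg.n_cases * 0.01 * 0.01
        assert abs(t.n11 - expect) <= 3 * np.sqrt(expect)

    def test_reporting_ratio_recovered_over_20_seeds(self):
        ratios = []
        for seed in range(20):
            cfg = simulate.ReportSimConfig(
                n_cases=100_000, reporting_ratio=4.0, seed=seed,
                n_background_drugs=3, n_background_events=3,
            )
            t = target_table(cfg)
            expected_ind = t.n1dot * t.ndot1 / t.ndotdot
            ratios.append(t.n11 / expected_ind)
        assert 3.0 <= np.mean(ratios) <= 5.0

    def test_marginal_shares_calibrated(self):
        cfg = simulate.ReportSimConfig(
            n_cases=50_000, target_drug_share=0.03, target_event_share=0.02,
            reporting_ratio=1.0, seed=8,
            n_background_drugs=5, n_background_events=5,
        )
        t = target_table(cfg)
        assert t.n1dot / t.ndotdot == pytest.approx(0.03, abs=0.003)
        assert t.ndot1 / t.ndotdot == pytest.approx(0.02, abs=0.003)


class TestClaimsGenerator:
    def test_nonpositive_hazard_rejected(self):
        with pytest.raises(ValueError, match="baseline_hazard"):
            simulate.ClaimsSimConfig(baseline_hazard={"stroke": 0.0})
        with pytest.raises(ValueError, match="true_hr"):
            simulate.ClaimsSimConfig(true_hr={"stroke": -1.0})

    def test_coefficient_length_enforced(self):
        with pytest.raises(ValueError, match="covariate_treatment_coefs"):
            simulate.ClaimsSimConfig(covariate_treatment_coefs=(0.1,))

    def test_deterministic_given_seed(self):
        cfg = simulate.ClaimsSimConfig(n_patients=300, seed=5)
        a = simulate.generate_claims_population(cfg)
        b = simulate.generate_claims_population(cfg)
        for name in ("patients", "dispensings", "diagnoses", "enrollment", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_population_structure(self):
        cfg = simulate.ClaimsSimConfig(n_patients=400, seed=6)
        ds = simulate.generate_claims_population(cfg)
        start = pd.Timestamp(cfg.enrollment_start)
        end = pd.Timestamp(cfg.enrollment_end)
        age = (start - ds.patients["birth_date"]).dt.days / 365.25
        assert (age < 75).all()
        study = ds.dispensings[
            ds.dispensings["drug_class"].isin(
                [simulate.TREATMENT_CLASS, simulate.COMPARATOR_CLASS]
            )
        ]
        per_patient = study.groupby("patient_id").size()
        assert (per_patient == 1).all()  # exactly one initiation, no plants
        assert study["date"].between(start, end).all()
        enr = ds.enrollment
        assert (enr["start"] < start).all()

    def test_file_roundtrip(self, tmp_path):
        ds = simulate.generate_claims_population(
            simulate.ClaimsSimConfig(n_patients=50, seed=1)
        )
        ds.write(tmp_path)
        back = simulate.ClaimsDataset.read(tmp_path)
        assert back.covariate_names == ds.covariate_names
        for name in ("patients", "dispensings", "diagnoses", "enrollment"):
            pd.testing.assert_frame_equal(
                getattr(back, name), getattr(ds, name), check_dtype=False
            )


def crude_mace_fit(cfg):
    ds = simulate.generate_claims_population(cfg)
    spec = cohort.CohortSpec()
    cand = cohort.identify_new_users(ds, spec)
    coh, _ = cohort.apply_exclusions(cand, ds, spec)
    fu = cohort.build_followup(coh, ds, "mace", spec)
    return survival.fit_cox(fu, "mace")


class TestGroundTruthRecovery:
    def test_exchangeable_arms_show_no_systematic_difference(self):
        zs = []
        for seed in range(10):
            est = crude_mace_fit(
                simulate.ClaimsSimConfig(n_patients=2000, seed=seed)
            )
            zs.append(np.log(est.hr) / est.log_hr_se)
        zs = np.array(zs)
        assert abs(zs.mean()) < 1.0  # se of the mean is ~0.32
        assert (zs > 0).any() and (zs < 0).any()

    def test_true_hr_2_recovered_without_confounding(self):
        hr2 = {k: 2.0 for k in simulate.DEFAULT_BASELINE_HAZARD}
        est = crude_mace_fit(
            simulate.ClaimsSimConfig(n_patients=10_000, true_hr=hr2, seed=11)
        )
        assert 1.8 <= est.hr <= 2.2

    def test_confounding_biases_the_crude_estimate(self):
        biased = 0
        for seed in range(5):
            est = crude_mace_fit(
                simulate.ClaimsSimConfig.confounded(seed=seed, n_patients=4000)
            )
            biased += abs(np.log(est.hr)) > 2 * est.log_hr_se
        assert biased >= 4
        # bias direction follows the sign of the confounding product
        assert est.hr > 1.0


class TestFollowupArms:
    def test_deterministic_and_balanced(self):
        a = simulate.simulate_followup_arms(500, seed=2)
        b = simulate.simulate_followup_arms(500, seed=2)
        pd.testing.assert_frame_equal(a, b)
        assert (a.groupby("group").size() == 500).all()
        assert (a["time_months"] > 0).all()

    def test_event_risk_near_design_target(self):
        fu = simulate.simulate_followup_arms(20_000, seed=3)
        risk = fu["event"].mean()
        assert 0.08 < risk < 0.14  # ~10% cumulative risk by design
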