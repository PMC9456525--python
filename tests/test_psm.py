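"""Propensity model, caliper matching, and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from dpp4_safety import cohort, psm, simulate


def cohort_frame(ids, groups, **covs):
    return pd.DataFrame({"patient_id": ids, "group": groups, **covs})


def simulated_cohort(config):
    ds = simulate.generate_claims_population(config)
    spec = cohort.CohortSpec()
    cand = cohort.identify_new_users(ds, spec)
    coh, _ = cohort.apply_exclusions(cand, ds, spec)
    return ds, coh


class TestEstimatePropensity:
    def test_pure_noise_slope_within_3se(self):
        rng = np.random.default_rng(0)
        n = 10_000
        coh = cohort_frame(
            np.arange(n),
            np.where(rng.random(n) < 0.5, "treatment", "comparator"),
            z=rng.standard_normal(n),
        )
        model = psm.estimate_propensity(coh, ["z"])
        assert abs(model.coefficients["z"]) < 3 * model.standard_errors["z"]
        assert model.converged

    def test_generator_coefficients_recovered(self):
        config = simulate.ClaimsSimConfig.confounded(seed=1, n_patients=10_000)
        ds, coh = simulated_cohort(config)
        model = psm.estimate_propensity(coh, ds.covariate_names)
        for name, truth in zip(
            config.covariate_names, config.covariate_treatment_coefs
        ):
            assert abs(model.coefficients[name] - truth) < 3 * model.standard_errors[
                name
            ], name

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        coh = cohort_frame(
            np.arange(200),
            np.where(rng.random(200) < 0.5, "treatment", "comparator"),
            z=rng.standard_normal(200),
            flat=np.ones(200),
        )
        with pytest.warns(UserWarning, match="flat"):
            model = psm.estimate_propensity(coh, ["z", "flat"])
        assert model.covariate_names == ["z"]

    def test_perfect_separation_names_covariate(self):
        groups = ["treatment"] * 50 + ["comparator"] * 50
        coh = cohort_frame(
            np.arange(100), groups, sep=np.r_[np.ones(50), np.zeros(50)]
        )
        with pytest.raises(psm.SeparationError, match="sep"):
            psm.estimate_propensity(coh, ["sep"])

    def test_single_group_rejected(self):
        coh = cohort_frame([1, 2], ["treatment", "treatment"], z=[0.0, 1.0])
        with pytest.raises(ValueError):
            psm.estimate_propensity(coh, ["z"])


def toy_model(t_logits, c_logits, t_ids=None, c_ids=None):
    nt, nc = len(t_logits), len(c_logits)
    logits = np.concatenate([t_logits, c_logits])
    ids = np.concatenate([
        t_ids if t_ids is not None else [f"t{i}" for i in range(nt)],
        c_ids if c_ids is not None else [f"c{i}" for i in range(nc)],
    ])
    return psm.PropensityModel(
        coefficients=pd.Series(dtype=float),
        standard_errors=pd.Series(dtype=float),
        covariate_names=[],
        subject_ids=ids,
        treated=np.r_[np.ones(nt, bool), np.zeros(nc, bool)],
        scores=1 / (1 + np.exp(-logits)),
        logits=logits,
        converged=True,
    )


class TestMatching:
    def test_identical_groups_pair_up_exactly(self):
        vals = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        m = psm.match_nearest_neighbor(toy_model(vals, vals), seed=0)
        assert len(m.pairs) == 5
        assert (m.pairs["distance"] == 0).all()
        got = {t: c for t, c in zip(m.pairs["treated_id"], m.pairs["comparator_id"])}
        assert got == {f"t{i}": f"c{i}" for i in range(5)}

    def test_treated_beyond_caliper_unmatched(self):
        m = psm.match_nearest_neighbor(
            toy_model([5.0], [0.0, 0.05, 0.1, -0.05, -0.1]), seed=0
        )
        assert m.pairs.empty
        assert m.n_unmatched_treated == 1

    def test_distance_ties_go_to_lower_comparator_id(self):
        m = psm.match_nearest_neighbor(
            toy_model([0.0], [-0.1, 0.1], c_ids=["c_b", "c_a"]),
            caliper_multiplier=3.0,
            seed=0,
        )
        assert list(m.pairs["comparator_id"]) == ["c_a"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_without_replacement_and_caliper_respected(self, seed):
        rng = np.random.default_rng(seed)
        m = psm.match_nearest_neighbor(
            toy_model(rng.normal(0.3, 1, 150), rng.normal(0, 1, 120)), seed=seed
        )
        ids = m.matched_ids
        assert len(ids) == len(set(ids))
        if len(m.pairs):
            assert m.pairs["distance"].max() <= m.caliper_value

    def test_greedy_total_distance_near_optimal(self):
        # when each treated subject has a clearly nearest comparator, greedy
        # must come within 5% of the optimal bipartite assignment (on dense
        # overlapping clouds greedy is legitimately 1.5-1.8x optimal, so this
        # asserts sane behaviour, not global optimality)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            centers = np.linspace(0.0, 10.0, 100)
            t = centers + rng.normal(0.0, 0.005, 100)
            c = centers + rng.normal(0.0, 0.005, 100)
            model = toy_model(t, c)
            m = psm.match_nearest_neighbor(model, caliper_multiplier=50.0, seed=seed)
            assert len(m.pairs) == 100
            cost = np.abs(t[:, None] - c[None, :])
            ri, ci = linear_sum_assignment(cost)
            optimal = cost[ri, ci].sum()
            assert m.pairs["distance"].sum() <= 1.05 * optimal


class TestBalance:
    def test_identical_groups_have_zero_smd(self):
        vals = np.array([-1.0, 0.0, 1.0])
        coh = cohort_frame(
            [f"t{i}" for i in range(3)] + [f"c{i}" for i in range(3)],
            ["treatment"] * 3 + ["comparator"] * 3,
            z=np.r_[vals, vals],
        )
        m = psm.match_nearest_neighbor(toy_model(vals, vals), seed=0)
        bal = psm.balance_diagnostics(m, coh, ["z"])
        assert bal["smd_before"].abs().max() == 0
        assert bal["smd_after"].abs().max() == 0

    def test_zero_pooled_sd_flagged(self):
        coh = cohort_frame(
            ["t0", "c0", "t1", "c1"],
            ["treatment", "comparator"] * 2,
            z=[1.0, 1.0, 1.0, 1.0],
        )
        m = psm.match_nearest_neighbor(
            toy_model([0.0, 0.1], [0.0, 0.1], t_ids=["t0", "t1"], c_ids=["c0", "c1"]),
            seed=0,
        )
        bal = psm.balance_diagnostics(m, coh, ["z"])
        assert bal["zero_sd"].all()
        assert (bal["smd_after"] == 0).all()

    def test_matching_improves_balance_on_confounded_data(self):
        config = simulate.ClaimsSimConfig.confounded(seed=2, n_patients=6000)
        ds, coh = simulated_cohort(config)
        model = psm.estimate_propensity(coh, ds.covariate_names)
        m = psm.match_nearest_neighbor(model, seed=2)
        bal = psm.balance_diagnostics(m, coh, ds.covariate_names)
        assert bal["smd_after"].abs().max() < bal["smd_before"].abs().max()
        assert bal["smd_after"].abs().max() < 0.1

    def test_empty_matching_rejected(self):
        coh = cohort_frame(["t0", "c0"], ["treatment", "comparator"], z=[0.0, 1.0])
        m = psm.match_nearest_neighbor(toy_model([10.0], [0.0]), seed=0)
        with pytest.raises(ValueError):
            psm.balance_diagnostics(m, coh, ["z"])
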