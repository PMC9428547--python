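"""Binomial GLMM fitting, inverse dose, ΔDHW and the tail reduction."""

import numpy as np
import pandas as pd
import pytest

import coralrht as crt
from coralrht.dose_response import GlmmFit

from conftest import simulate_glmm_obs


def toy_fit(beta, cov_scale=1e-6, dhw_range=(0.0, 20.0)):
    return GlmmFit(
        beta=np.asarray(beta, float),
        cov=np.eye(4) * cov_scale,
        sigma_u=0.5,
        loglik=0.0,
        converged=True,
        n_colonies={"RHHT": 10, "RLHT": 10},
        dhw_range=dhw_range,
    )


class TestBuildObservations:
    def test_bmi_to_count_encoding(self, bmi_profiles, classified):
        obs = crt.build_observations(bmi_profiles, classified["classification"])
        assert ((obs["k"] >= 0) & (obs["k"] <= obs["m"])).all()
        assert set(obs["group"]) == {"RHHT", "RLHT"}

    @pytest.mark.parametrize("bmi, k", [(0.0, 0), (1.0, 20), (0.05, 1), (0.123, 2)])
    def test_attainable_grid(self, bmi, k):
        prof = pd.DataFrame({0.0: [bmi], 1.0: [bmi], 2.0: [bmi]}, index=["A"])
        cls = pd.DataFrame({"colony_id": ["A"], "category": ["RHHT"]})
        obs = crt.build_observations(prof, cls, thin=0.0)
        assert (obs["k"] == k).all()

    def test_out_of_range_bmi_rejected(self):
        prof = pd.DataFrame({0.0: [1.2]}, index=["A"])
        cls = pd.DataFrame({"colony_id": ["A"], "category": ["RHHT"]})
        with pytest.raises(ValueError, match="outside"):
            crt.build_observations(prof, cls, thin=0.0)


class TestGlmmFit:
    def test_parameter_recovery_from_own_model(self):
        obs = simulate_glmm_obs(beta=(-8.0, 1.2, -3.0, 0.0), sigma_u=0.5, seed=10)
        fit = crt.fit_bmi_glmm(obs)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(1.2, rel=0.10)
        assert fit.sigma_u == pytest.approx(0.5, rel=0.5)

    def test_zero_variance_data_hits_boundary(self):
        obs = simulate_glmm_obs(sigma_u=0.0, n_colonies=60, seed=3)
        fit = crt.fit_bmi_glmm(obs)
        assert fit.sigma_u < 0.15

    def test_single_group_rank_deficiency_rejected(self):
        obs = simulate_glmm_obs(n_colonies=20, seed=1)
        only = obs[obs["group"] == "RHHT"]
        with pytest.raises(ValueError, match="colonies"):
            crt.fit_bmi_glmm(only)

    def test_too_few_dhw_values_rejected(self):
        obs = simulate_glmm_obs(dhw_grid=np.array([0.0, 5.0]), n_colonies=10, seed=1)
        with pytest.raises(ValueError, match="DHW"):
            crt.fit_bmi_glmm(obs)

    def test_covariance_symmetric_psd(self):
        obs = simulate_glmm_obs(n_colonies=40, seed=5)
        fit = crt.fit_bmi_glmm(obs)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)


class TestInverseDose:
    @pytest.mark.parametrize(
        "beta, level, expected",
        [
            ((-6.0, 1.0, 0.0, 0.0), 0.5, 6.0),
            ((-6.0, 2.0, 0.0, 0.0), 0.5, 3.0),
            ((-6.0, 1.0, 0.0, 0.0), 0.25, 6.0 + np.log(1 / 3)),
        ],
    )
    def test_closed_form_inversion(self, beta, level, expected):
        point, lo, hi = crt.inverse_dose(toy_fit(beta), "RHHT", level, seed=1)
        assert point == pytest.approx(expected, abs=1e-6)
        assert lo <= point <= hi

    def test_bootstrap_ci_contains_point_across_seeds(self):
        fit = toy_fit((-6.0, 1.0, -2.0, 0.0), cov_scale=0.01)
        inside = 0
        for seed in range(50):
            point, lo, hi = crt.inverse_dose(fit, "RLHT", 0.5, seed=seed)
            inside += lo <= point <= hi
        assert inside >= 49

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1])
    def test_degenerate_level_rejected(self, level):
        with pytest.raises(ValueError, match="bmi_level"):
            crt.inverse_dose(toy_fit((-6, 1, 0, 0)), "RHHT", level)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            crt.inverse_dose(toy_fit((-6.0, -1.0, 0.0, 0.0)), "RHHT", 0.5)

    def test_non_converged_fit_refused(self):
        fit = toy_fit((-6.0, 1.0, 0.0, 0.0))
        fit.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            crt.inverse_dose(fit, "RHHT", 0.5)


class TestComparisonLevel:
    def test_caps_at_half_when_everything_identified(self):
        fit = toy_fit((-6.0, 1.0, 2.0, 0.0), dhw_range=(0.0, 20.0))
        level, admissible = crt.select_comparison_level(fit, seed=0)
        assert level == pytest.approx(0.5)
        assert admissible

    def test_drops_below_half_when_range_truncated(self):
        # RHHT dose at BMI 0.5 is 6.0; observed range ends at 5.0
        fit = toy_fit((-6.0, 1.0, 2.0, 0.0), cov_scale=1e-4, dhw_range=(0.0, 5.0))
        level, admissible = crt.select_comparison_level(fit, seed=0)
        assert admissible
        assert level < 0.5
        # highest level whose dose stays below 5.0: logit(b) < -1
        assert level == pytest.approx(0.25, abs=0.051)

    def test_widening_range_never_lowers_level(self):
        fit_narrow = toy_fit((-6.0, 1.0, 2.0, 0.0), cov_scale=1e-4, dhw_range=(0.0, 5.0))
        fit_wide = toy_fit((-6.0, 1.0, 2.0, 0.0), cov_scale=1e-4, dhw_range=(0.0, 8.0))
        lvl_narrow, _ = crt.select_comparison_level(fit_narrow, seed=0)
        lvl_wide, _ = crt.select_comparison_level(fit_wide, seed=0)
        assert lvl_wide >= lvl_narrow

    def test_strict_raises_when_nothing_admissible(self):
        fit = toy_fit((-20.0, 1.0, 10.0, 0.0), cov_scale=1e-4, dhw_range=(0.0, 5.0))
        with pytest.raises(ValueError, match="no BMI level"):
            crt.select_comparison_level(fit, seed=0, strict=True)
        level, admissible = crt.select_comparison_level(fit, seed=0, strict=False)
        assert not admissible
        assert level == pytest.approx(0.05)


class TestDeltaDhw:
    def test_identical_groups_give_null_delta(self):
        fit = toy_fit((-6.0, 1.0, 0.0, 0.0), cov_scale=1e-4)
        est = crt.delta_dhw(fit, 0.5, seed=0)
        assert est.delta_dhw[0] == pytest.approx(0.0, abs=1e-6)
        assert est.delta_dhw[1] <= 0.0 <= est.delta_dhw[2]

    @pytest.mark.parametrize("level", [0.1, 0.3, 0.5, 0.7])
    def test_shared_slope_delta_is_offset_over_slope(self, level):
        # eta_L = eta_H + 2.4 -> RLHT reaches any level 2.4/1.2 earlier
        fit = toy_fit((-6.0, 1.2, 2.4, 0.0))
        est = crt.delta_dhw(fit, level, seed=0)
        assert est.delta_dhw[0] == pytest.approx(2.0, abs=1e-6)

    def test_delta_equals_difference_of_doses(self):
        fit = toy_fit((-6.0, 1.0, 3.0, 0.1), cov_scale=1e-4)
        est = crt.delta_dhw(fit, 0.4, seed=2)
        assert est.delta_dhw[0] == pytest.approx(est.dhw_high[0] - est.dhw_low[0])

    def test_group_label_swap_negates_delta(self):
        obs = simulate_glmm_obs(beta=(-6.0, 1.2, 3.0, 0.0), n_colonies=40, seed=6)
        swapped = obs.assign(
            group=obs["group"].map({"RHHT": "RLHT", "RLHT": "RHHT"})
        )
        est = crt.delta_dhw(crt.fit_bmi_glmm(obs), 0.4, seed=0)
        est_swapped = crt.delta_dhw(crt.fit_bmi_glmm(swapped), 0.4, seed=0)
        assert est.delta_dhw[0] == pytest.approx(-est_swapped.delta_dhw[0], abs=5e-3)


class TestStepwiseReduction:
    def stepwise_inputs(self, n_per_group=13, seed=0):
        obs = simulate_glmm_obs(
            beta=(-8.0, 1.5, 4.0, 0.0), n_colonies=2 * n_per_group, seed=seed
        )
        colonies = sorted(obs["colony_id"].unique())
        rng = np.random.default_rng(seed)
        mean_bmi = pd.Series(rng.uniform(0, 1, len(colonies)), index=colonies)
        return obs, mean_bmi

    def test_sequence_length_and_sizes(self):
        obs, mean_bmi = self.stepwise_inputs(n_per_group=12)
        seq = crt.stepwise_tail_reduction(
            obs, mean_bmi, float(mean_bmi.mean()), target_n=10, n_boot=200, seed=0
        )
        assert list(seq["n_rhht"]) == [12, 11, 10]
        assert list(seq["n_rlht"]) == [12, 11, 10]

    def test_removal_deterministic(self):
        obs, mean_bmi = self.stepwise_inputs()
        kwargs = dict(target_n=11, n_boot=200, seed=4)
        a = crt.stepwise_tail_reduction(obs, mean_bmi, float(mean_bmi.mean()), **kwargs)
        b = crt.stepwise_tail_reduction(obs, mean_bmi, float(mean_bmi.mean()), **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_group_not_exceeding_target_rejected(self):
        obs, mean_bmi = self.stepwise_inputs(n_per_group=10)
        with pytest.raises(ValueError, match="target_n"):
            crt.stepwise_tail_reduction(
                obs, mean_bmi, float(mean_bmi.mean()), target_n=10
            )

    def test_tail_members_are_most_extreme_by_mean_bmi(self):
        obs, mean_bmi = self.stepwise_inputs(n_per_group=12, seed=2)
        pop_mean = float(mean_bmi.mean())
        removed_first = []
        for g in ("RHHT", "RLHT"):
            members = sorted(obs.loc[obs["group"] == g, "colony_id"].unique())
            removed_first.append(min((abs(mean_bmi[c] - pop_mean), c) for c in members)[1])
        seq = crt.stepwise_tail_reduction(
            obs, mean_bmi, pop_mean, target_n=11, n_boot=200, seed=0
        )
        assert len(seq) == 2  # 12 -> 11
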