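"""Synthetic-study generator: determinism, structure, and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coralrht as crt
from coralrht import synthetic
from coralrht.synthetic import PopulationConfig, ProjectionConfig


class TestPopulation:
    def test_degenerate_variance_collapses_to_mean(self):
        cfg = PopulationConfig(sigma_theta=0.0, sigma_frag=0.0, seed=3)
        colonies, fragments = crt.generate_population(cfg)
        assert np.allclose(colonies["theta"], cfg.mu_theta)
        assert np.allclose(fragments["theta_frag"], cfg.mu_theta)

    def test_mean_threshold_matches_population_mean(self):
        cfg = PopulationConfig(n_colonies=10_000, seed=5)
        colonies, _ = crt.generate_population(cfg)
        se = cfg.sigma_theta / np.sqrt(cfg.n_colonies)
        assert abs(colonies["theta"].mean() - cfg.mu_theta) < 3 * se

    def test_same_seed_identical_tables(self):
        a = crt.generate_population(PopulationConfig(seed=9))
        b = crt.generate_population(PopulationConfig(seed=9))
        assert a[0].to_csv() == b[0].to_csv()
        assert a[1].to_csv() == b[1].to_csv()

    def test_one_fragment_per_colony_per_tank(self):
        cfg = PopulationConfig(seed=1)
        _, fragments = crt.generate_population(cfg)
        counts = fragments.groupby(["colony_id", "tank_id"]).size()
        assert (counts == 1).all()
        assert fragments["tank_id"].nunique() == cfg.n_stress_tanks + 1

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_colonies": 10}, "n_colonies"),
            ({"bleach_offset": 0.0}, "bleach_offset"),
            ({"logistic_scale": -1.0}, "logistic_scale"),
            ({"p_handling_death": 1.5}, "p_handling_death"),
            ({"direct_death_prob": -0.1}, "direct_death_prob"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            PopulationConfig(**kwargs)


class TestExperiment:
    def test_status_non_decreasing_per_fragment(self, experiment):
        for _, grp in experiment["status"].groupby("fragment_id"):
            s = grp.sort_values("day")["status"].to_numpy()
            assert (np.diff(s) >= 0).all()

    def test_tank_records_stop_at_half_mortality(self, experiment):
        status = experiment["status"]
        for tank, grp in status[status["tank_id"] != synthetic.CONTROL_TANK].groupby("tank_id"):
            frac_dead = grp.groupby("day").apply(
                lambda g: (g["status"] == 4).mean(), include_groups=False
            )
            days = frac_dead.index.to_numpy()
            # only the final assessment may be at or past 50% mortality
            assert (frac_dead.iloc[:-1] < 0.5).all(), tank
            assert frac_dead.iloc[-1] >= 0.5, tank
            assert days.max() == grp["day"].max()

    def test_tolerant_fragment_never_responds(self, experiment, tank_dhw_by_day):
        # the relevant ceiling is the stress reached before tank termination
        status = experiment["status"]
        last = status[status["tank_id"] != synthetic.CONTROL_TANK].groupby("tank_id")["day"].max()
        term = tank_dhw_by_day.merge(
            last.rename("last_day"), left_on="entity_id", right_index=True
        )
        max_dhw = term.loc[term["day"] == term["last_day"], "dhw_cweeks"].max()
        hardy = experiment["fragments"].query("theta_frag > @max_dhw + 2")
        ids = set(hardy["fragment_id"]) & set(experiment["status"]["fragment_id"])
        recs = experiment["status"][experiment["status"]["fragment_id"].isin(ids)]
        stress_recs = recs[recs["tank_id"] != synthetic.CONTROL_TANK]
        assert len(stress_recs) > 0
        assert (stress_recs["status"] == 0).all()

    def test_direct_death_skips_visible_bleaching(self, default_cfg):
        dhw_grid = np.linspace(0, 12, 200)
        states = [
            synthetic._status_from_dhw(d, theta=6.0, direct=True, config=default_cfg)
            for d in dhw_grid
        ]
        assert set(states) == {0, 4}

    def test_gradual_fragment_passes_through_bleached_phase(self, default_cfg):
        dhw_grid = np.linspace(0, 12, 500)
        states = [
            synthetic._status_from_dhw(d, theta=6.0, direct=False, config=default_cfg)
            for d in dhw_grid
        ]
        assert set(states) == {0, 1, 2, 3, 4}
        assert (np.diff(states) >= 0).all()

    def test_control_tank_unstressed(self, experiment):
        temps = experiment["temps"]
        ctrl = temps[temps["entity_id"] == synthetic.CONTROL_TANK]["sst_c"]
        assert ctrl.nunique() == 1

    def test_ramp_must_cover_span(self, default_cfg):
        population = crt.generate_population(default_cfg)
        bad = pd.DataFrame({"day": [0, 2, 3], "temp_c": [29.0, 30.0, 31.0]})
        with pytest.raises(ValueError, match="ramp"):
            crt.generate_experiment(population, default_cfg, ramp=bad)

    def test_same_seed_identical_experiment(self, default_cfg):
        population = crt.generate_population(default_cfg)
        s1, r1, t1 = crt.generate_experiment(population, default_cfg)
        s2, r2, t2 = crt.generate_experiment(population, default_cfg)
        assert s1.to_csv() == s2.to_csv()
        assert r1.to_csv() == r2.to_csv()
        assert t1.to_csv() == t2.to_csv()

    def test_rgb_whitens_with_bleaching(self, experiment):
        merged = experiment["status"].merge(experiment["rgb"], on=["fragment_id", "day"])
        mean_r = merged.groupby("status")["r"].mean()
        assert mean_r.loc[0] < mean_r.loc[1] < mean_r.loc[2]

    def test_endpoint_mortality_near_half_across_seeds(self):
        rates = []
        for seed in range(20):
            cfg = PopulationConfig(seed=seed)
            population = crt.generate_population(cfg)
            status, _, _ = crt.generate_experiment(population, cfg)
            fates = crt.endpoint_fates(status, synthetic.CONTROL_TANK)
            rates.append(fates["dead"].mean())
        assert 0.40 <= np.mean(rates) <= 0.60


class TestIts2:
    def test_rows_sum_to_one(self, experiment, default_cfg):
        its2 = crt.generate_its2_table(
            (experiment["colonies"], experiment["fragments"]), default_cfg
        )
        sums = its2.groupby("colony_id")["rel_abundance"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_full_dominance_single_profile(self, experiment, default_cfg):
        its2 = crt.generate_its2_table(
            (experiment["colonies"], experiment["fragments"]), default_cfg, p_dominant=1.0
        )
        major = (
            its2.sort_values("rel_abundance", ascending=False)
            .groupby("colony_id")
            .first()["profile"]
        )
        assert (major == synthetic.ITS2_DOMINANT).all()

    def test_profile_independent_of_tolerance(self):
        """Chi-square p-values between dominant profile and RHT category
        behave like a null across seeds (independence by construction)."""
        pvals = []
        for seed in range(25):
            cfg = PopulationConfig(seed=seed)
            population = crt.generate_population(cfg)
            status, _, _ = crt.generate_experiment(population, cfg)
            fates = crt.endpoint_fates(status, synthetic.CONTROL_TANK)
            cls = crt.classify_endpoint(fates, p_hat=0.5)
            its2 = crt.generate_its2_table(population, cfg)
            dominant = (
                its2.sort_values("rel_abundance", ascending=False)
                .groupby("colony_id")
                .first()["profile"]
            )
            df = cls.merge(dominant, left_on="colony_id", right_index=True)
            tab = pd.crosstab(df["profile"] == synthetic.ITS2_DOMINANT, df["category"])
            if tab.shape[0] < 2:
                continue
            pvals.append(stats.chi2_contingency(tab).pvalue)
        assert len(pvals) >= 15
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.2

    def test_classified_tail_calibration(self):
        """RHHT tail lands in the high-20s/low-30s percent band; the RLHT
        tail is at least as large (termination records fates just past the
        50% crossing, which favours the all-dead fate)."""
        rhht, rlht = [], []
        for seed in range(10):
            cfg = PopulationConfig(seed=seed)
            population = crt.generate_population(cfg)
            status, _, _ = crt.generate_experiment(population, cfg)
            exc = crt.exclude_handling_deaths(status, synthetic.CONTROL_TANK)
            fates = crt.endpoint_fates(status, synthetic.CONTROL_TANK)
            cls = crt.classify_endpoint(fates, p_hat=0.5, exclude=exc)
            n = (cls["category"] != "excluded").sum()
            rhht.append((cls["category"] == "RHHT").sum() / n)
            rlht.append((cls["category"] == "RLHT").sum() / n)
        assert 0.23 <= np.mean(rhht) <= 0.37
        assert np.mean(rlht) >= np.mean(rhht)


class TestProjectionEnsemble:
    def test_zero_trend_zero_noise_all_zero(self):
        cfg = ProjectionConfig(trend=(0.0, 0.0), noise_sd=0.0, model_offset_sd=0.0, baseline=0.0, seed=2)
        ens = crt.generate_projection_ensemble(cfg)
        assert (ens["dhw"] == 0.0).all()

    def test_linear_trend_first_exceedance_year(self):
        cfg = ProjectionConfig(
            scenarios=("SSP5-8.5",),
            n_models_per_scenario=(3,),
            trend=(0.4,),
            noise_sd=0.0,
            model_offset_sd=0.0,
            baseline=0.0,
            seed=2,
        )
        ens = crt.generate_projection_ensemble(cfg)
        annual = ens.groupby(["gcm", "year"])["dhw"].max().reset_index()
        first = annual[annual["dhw"] >= 8.0].groupby("gcm")["year"].min()
        assert (first == cfg.start_year + 20).all()

    def test_same_seed_identical(self):
        a = crt.generate_projection_ensemble(ProjectionConfig(seed=4))
        b = crt.generate_projection_ensemble(ProjectionConfig(seed=4))
        assert a.to_csv() == b.to_csv()

    def test_misaligned_scenarios_rejected(self):
        with pytest.raises(ValueError, match="align"):
            ProjectionConfig(scenarios=("SSP2-4.5",), n_models_per_scenario=(3, 4))
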