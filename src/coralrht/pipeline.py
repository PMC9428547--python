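"""End-to-end study driver: simulate/load -> classify -> ΔDHW -> projection.

``run_pipeline`` executes the stages in analysis order, persists the
intermediate CSV artifacts under the configured output directory, and
returns a :class:`StudyReport`.  Every random quantity derives from the
master seed; rerunning with the same seed reproduces the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, dose_response, indices, io, projection, synthetic, thermal

log = logging.getLogger("coralrht")


def setup_logging(out_dir: str | Path | None = None, level: int = logging.INFO) -> None:
    """Console logging, plus a run log file when ``out_dir`` is given."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class StudyReport:
    """Artifacts of one end-to-end run."""

    classification: pd.DataFrame
    ranksum: tuple[float, float]
    symbiont_table: pd.DataFrame
    cluster_labels: pd.Series
    delta_sequence: pd.DataFrame
    onset_table: pd.DataFrame
    onset_contrasts: pd.DataFrame
    info: dict = field(default_factory=dict)


def _simulate_inputs(cfg: io.StudyConfig):
    pop_cfg = synthetic.PopulationConfig(seed=cfg.seed)
    population = synthetic.generate_population(pop_cfg)
    status, rgb, temps = synthetic.generate_experiment(population, pop_cfg)
    its2 = synthetic.generate_its2_table(population, pop_cfg)
    proj = synthetic.generate_projection_ensemble(synthetic.ProjectionConfig(seed=cfg.seed))
    return status, rgb, temps, its2, proj


def run_pipeline(cfg: io.StudyConfig) -> StudyReport:
    """Run the full analysis; see the module docstring.

    Raises with the failing stage named if any stage cannot complete.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if cfg.status_path is None:
            log.info("simulating synthetic study (seed=%d)", cfg.seed)
            status, rgb, temps, its2, proj = _simulate_inputs(cfg)
        else:
            status = io.read_table(cfg.status_path, "status")
            rgb = io.read_table(cfg.rgb_path, "rgb")
            temps = io.read_table(cfg.temperature_path, "temperature")
            its2 = io.read_table(cfg.its2_path, "its2")
            proj = io.read_table(cfg.projections_path, "projections")

        stage = "thermal_dose"
        dhw = thermal.tank_dhw(temps, adjusted_threshold=synthetic.TANK_STRESS_THRESHOLD_C)
        start = pd.to_datetime(dhw["date"]).min()
        dhw["day"] = (pd.to_datetime(dhw["date"]) - start).dt.days
        io.write_table(dhw, out / "dhw.csv", "dhw")

        stage = "exclusions"
        excluded = classify.exclude_handling_deaths(status, cfg.control_tank)
        log.info("handling-death exclusions: %d colonies", len(excluded))
        stress = status[
            (status["tank_id"] != cfg.control_tank)
            & ~status["colony_id"].isin(excluded)
        ]

        stage = "classification"
        fates = classify.endpoint_fates(status, cfg.control_tank)
        realized = classify.realized_mortality(fates, excluded)
        p_hat = realized if cfg.p_hat == "realized" else float(cfg.p_hat)
        log.info("endpoint mortality: realized %.3f, test rate %.3f", realized, p_hat)
        cls = classify.classify_endpoint(fates, p_hat=p_hat, alpha=cfg.alpha, exclude=excluded)
        mean_bmi = indices.colony_mean_bmi(stress)
        cls = cls.merge(mean_bmi, left_on="colony_id", right_index=True, how="left")
        io.write_table(cls, out / "classification.csv", "classification")
        hi = cls.loc[cls["category"] == "RHHT", "mean_bmi"].dropna()
        lo = cls.loc[cls["category"] == "RLHT", "mean_bmi"].dropna()
        ranksum = classify.compare_group_bmi(hi, lo) if len(hi) and len(lo) else (np.nan, np.nan)

        stage = "symbionts"
        table1 = classify.tabulate_symbionts(its2, cls)
        table1.to_csv(out / "table1.csv", index=False)

        stage = "profiles"
        bmi_obs = stress[["colony_id", "tank_id", "day", "status"]].copy()
        bmi_obs["value"] = bmi_obs["status"] / 4.0
        tank_dhw_days = dhw[dhw["entity_id"] != cfg.control_tank].rename(
            columns={"entity_id": "tank_id"}
        )
        bmi_prof = thermal.interpolate_profiles(
            bmi_obs, tank_dhw_days, grid_step=cfg.grid_step, agg="mean"
        )
        io.write_table(io.profiles_to_long(bmi_prof), out / "profiles_bmi.csv", "profiles")
        cmi_obs = indices.cmi_profile_inputs(stress, rgb, exclude=excluded)
        cmi_prof = thermal.interpolate_profiles(
            cmi_obs, tank_dhw_days, grid_step=cfg.grid_step, agg="median"
        )
        io.write_table(io.profiles_to_long(cmi_prof), out / "profiles_cmi.csv", "profiles")

        stage = "clustering"
        z = indices.zscore_matrix(cmi_prof)
        _, labels = indices.cluster_profiles(z, n_clusters=3)
        labels.rename("cluster").to_csv(out / "clusters.csv")

        stage = "dose_response"
        obs = dose_response.build_observations(bmi_prof, cls, m=cfg.m_trials)
        seq = dose_response.stepwise_tail_reduction(
            obs,
            mean_bmi=mean_bmi,
            population_mean_bmi=float(mean_bmi.mean()),
            target_n=cfg.target_n,
            n_boot=cfg.n_boot,
            seed=cfg.seed,
        )
        io.write_table(seq, out / "delta_dhw.csv", "delta_dhw")
        log.info(
            "delta-DHW: full %.2f C-weeks, decile %.2f C-weeks",
            seq["delta_dhw"].iloc[0],
            seq["delta_dhw"].iloc[-1],
        )

        stage = "climate_projection"
        onsets = projection.onset_table(proj, thresholds=cfg.thresholds)
        io.write_table(onsets, out / "abm_onset.csv", "abm_onset")
        lmm = projection.fit_onset_lmm(onsets)
        lmm["contrasts"].to_csv(out / "onset_contrasts.csv", index=False)
        log.info("censored onsets excluded from LMM: %d", lmm["n_censored"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return StudyReport(
        classification=cls,
        ranksum=ranksum,
        symbiont_table=table1,
        cluster_labels=labels,
        delta_sequence=seq,
        onset_table=onsets,
        onset_contrasts=lmm["contrasts"],
        info={
            "seed": cfg.seed,
            "excluded": sorted(excluded),
            "realized_mortality": realized,
            "p_hat": p_hat,
            "n_censored": lmm["n_censored"],
            "re_var": lmm["re_var"],
        },
    )


def replicate_study(
    seeds,
    target_n: int = 10,
    n_boot: int = 1000,
    p_hat: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classification and ΔDHW summary across replicate synthetic studies.

    For each seed: generate the default synthetic study, classify
    colonies, fit the GLMM, run the stepwise tail reduction, and record
    the headline quantities.  Used by the acceptance checks and useful
    for calibration experiments.

    Returns one row per seed: ``pct_rhht, pct_rlht, delta_full,
    delta_decile, bmi_level_full, bmi_level_decile, realized_mortality``.
    """
    rows = []
    for seed in seeds:
        pop_cfg = synthetic.PopulationConfig(seed=int(seed))
        population = synthetic.generate_population(pop_cfg)
        status, _rgb, temps = synthetic.generate_experiment(population, pop_cfg)
        dhw = thermal.tank_dhw(temps, adjusted_threshold=synthetic.TANK_STRESS_THRESHOLD_C)
        start = pd.to_datetime(dhw["date"]).min()
        dhw["day"] = (pd.to_datetime(dhw["date"]) - start).dt.days

        excluded = classify.exclude_handling_deaths(status, synthetic.CONTROL_TANK)
        fates = classify.endpoint_fates(status, synthetic.CONTROL_TANK)
        cls = classify.classify_endpoint(fates, p_hat=p_hat, alpha=alpha, exclude=excluded)
        n_scored = (cls["category"] != "excluded").sum()

        stress = status[
            (status["tank_id"] != synthetic.CONTROL_TANK)
            & ~status["colony_id"].isin(excluded)
        ]
        bmi_obs = stress[["colony_id", "tank_id", "day", "status"]].copy()
        bmi_obs["value"] = bmi_obs["status"] / 4.0
        tank_dhw_days = dhw[dhw["entity_id"] != synthetic.CONTROL_TANK].rename(
            columns={"entity_id": "tank_id"}
        )
        prof = thermal.interpolate_profiles(bmi_obs, tank_dhw_days, agg="mean")
        mean_bmi = indices.colony_mean_bmi(stress)
        obs = dose_response.build_observations(prof, cls)
        seq = dose_response.stepwise_tail_reduction(
            obs,
            mean_bmi=mean_bmi,
            population_mean_bmi=float(mean_bmi.mean()),
            target_n=target_n,
            n_boot=n_boot,
            seed=int(seed),
        )
        rows.append(
            {
                "seed": int(seed),
                "pct_rhht": 100.0 * (cls["category"] == "RHHT").sum() / n_scored,
                "pct_rlht": 100.0 * (cls["category"] == "RLHT").sum() / n_scored,
                "delta_full": seq["delta_dhw"].iloc[0],
                "delta_decile": seq["delta_dhw"].iloc[-1],
                "bmi_level_full": seq["bmi_level"].iloc[0],
                "bmi_level_decile": seq["bmi_level"].iloc[-1],
                "realized_mortality": classify.realized_mortality(fates, excluded),
            }
        )
    return pd.DataFrame(rows)
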