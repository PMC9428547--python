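"""Synthetic heatwave-assay and climate-projection data.

Generates data with the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without access to the
original tank experiment:

* a wild population of coral colonies with latent heat-tolerance
  thresholds (°C-weeks of DHW a colony withstands before dying), normally
  distributed between colonies with additional fragment-level scatter;
* a ramped tank heatwave (+1 °C on days 1, 4 and 8, +0.5 °C on day 21)
  with one fragment per colony in each of five stress tanks and one
  procedural control tank, ordinal status scoring at the real assessment
  cadence, per-tank termination once half its fragments have died, and a
  handling-death rule for the control tank;
* RGB colour measurements whose whiteness tracks bleaching state;
* an ITS2 symbiont type-profile table independent of tolerance;
* a GCM ensemble of quarterly DHW projections with scenario-specific
  warming trends.

Fragment fates are threshold-driven: a fragment dies exactly when its
tank's accumulated DHW reaches its own threshold, and passes through the
visible bleaching states over the preceding ``bleach_offset`` °C-weeks
(transitions spaced ``logistic_scale`` apart).  This makes the group-level
dose-response a pure horizontal shift, which is the property the GLMM
stage is designed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermal import tank_dhw

CONTROL_TANK = "control"
#: experiment day-0 ambient temperature, °C
AMBIENT_C = 29.0
#: tank stress threshold: DHW accumulates once tank temperature reaches this, °C
TANK_STRESS_THRESHOLD_C = 30.0
#: temperature step schedule: (day, increment °C)
RAMP_STEPS = ((1, 1.0), (4, 1.0), (8, 1.0), (21, 0.5))
#: experiment length, days (day 0 .. day 30)
EXPERIMENT_DAYS = 31

# fixed child-stream offsets from the master seed (one stream per purpose)
_STREAM = {"population": 0, "experiment": 1, "rgb": 2, "its2": 3, "projection": 4}

#: status-dependent mean whiteness fraction for RGB emission
_WHITENESS = {0: 0.45, 1: 0.70, 2: 0.95, 3: 0.95}
_RGB_NOISE_SD = 10.0

#: dominant ITS2 type profile and its population frequency (plus rare variants)
ITS2_DOMINANT = "C40-C3-C115-C40h"
ITS2_RARE = ("C40-C3-C40j", "C40-C40i-C3", "C40-C3-C40i-C40j", "C40-C15h-C3-C115-C40h")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


def _probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PopulationConfig:
    """Population and assay parameters of the synthetic experiment.

    Defaults mirror the study conditions: 102 colonies, five stress tanks
    with one fragment per colony each, colony death thresholds normal with
    mean 6.8 and sd 1.38 °C-weeks, fragment-level sd 0.4 °C-weeks, visible
    bleaching starting 1.5 °C-weeks before death with ordinal transitions
    spaced 0.6 °C-weeks apart, and 13% of fragments skipping the visible
    bleached phase entirely.
    """

    n_colonies: int = 102
    n_stress_tanks: int = 5
    fragments_per_tank_per_colony: int = 1
    mu_theta: float = 6.8
    sigma_theta: float = 1.38
    sigma_frag: float = 0.4
    bleach_offset: float = 1.5
    logistic_scale: float = 0.6
    p_handling_death: float = 0.02
    direct_death_prob: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 20:
            raise ValueError(
                f"n_colonies must be at least 20 (decile subsampling needs 10 per "
                f"tail), got {self.n_colonies}"
            )
        if self.n_stress_tanks < 1:
            raise ValueError(f"n_stress_tanks must be >= 1, got {self.n_stress_tanks}")
        if self.fragments_per_tank_per_colony != 1:
            raise ValueError("fragments_per_tank_per_colony must be 1 (one fragment per colony per tank)")
        if self.sigma_theta < 0 or self.sigma_frag < 0:
            raise ValueError("sigma_theta and sigma_frag must be non-negative")
        _positive("bleach_offset", self.bleach_offset)
        _positive("logistic_scale", self.logistic_scale)
        _probability("p_handling_death", self.p_handling_death)
        _probability("direct_death_prob", self.direct_death_prob)


@dataclass(frozen=True)
class ProjectionConfig:
    """GCM-ensemble DHW projection parameters.

    Default trends put annual severe-bleaching stress (8 °C-weeks) near
    the early 2030s and make each extra 4 °C-weeks of tolerance worth
    roughly a decade under the fast-warming scenario and substantially
    more under the moderate one.
    """

    scenarios: tuple[str, ...] = ("SSP2-4.5", "SSP5-8.5")
    n_models_per_scenario: tuple[int, ...] = (24, 28)
    start_year: int = 2015
    end_year: int = 2100
    trend: tuple[float, ...] = (0.235, 0.40)  # °C-weeks per year
    baseline: float = 1.0
    noise_sd: float = 1.0
    model_offset_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must be after start_year")
        if len(self.scenarios) != len(self.n_models_per_scenario) or len(self.scenarios) != len(self.trend):
            raise ValueError("scenarios, n_models_per_scenario and trend must align")
        if any(t < 0 for t in self.trend):
            raise ValueError("trends must be >= 0")
        if self.noise_sd < 0 or self.model_offset_sd < 0:
            raise ValueError("noise_sd and model_offset_sd must be >= 0")


def stress_tank_ids(config: PopulationConfig) -> list[str]:
    return [f"S{k + 1}" for k in range(config.n_stress_tanks)]


def generate_population(config: PopulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw latent colony and fragment heat-tolerance thresholds.

    Returns
    -------
    colonies
        ``colony_id``, ``theta`` (colony death threshold, °C-weeks).
    fragments
        ``fragment_id``, ``colony_id``, ``tank_id``, ``theta_frag``; one
        fragment per colony in each stress tank and in the control tank.
    """
    rng = _rng(config.seed, "population")
    theta = rng.normal(config.mu_theta, config.sigma_theta, config.n_colonies)
    colony_ids = [f"C{i + 1:03d}" for i in range(config.n_colonies)]
    colonies = pd.DataFrame({"colony_id": colony_ids, "theta": theta})

    tanks = stress_tank_ids(config) + [CONTROL_TANK]
    rows = []
    for i, cid in enumerate(colony_ids):
        for tank in tanks:
            rows.append(
                {
                    "fragment_id": f"{cid}-{tank}",
                    "colony_id": cid,
                    "tank_id": tank,
                    "theta_frag": theta[i] + rng.normal(0.0, config.sigma_frag),
                }
            )
    return colonies, pd.DataFrame(rows)


def default_ramp_schedule(
    days: int = EXPERIMENT_DAYS,
    ambient: float = AMBIENT_C,
    steps: tuple[tuple[int, float], ...] = RAMP_STEPS,
) -> pd.DataFrame:
    """Stress-tank setpoint schedule: columns ``day``, ``temp_c``."""
    temp = np.full(days, ambient, dtype=float)
    for day, inc in steps:
        if day >= days:
            raise ValueError(f"ramp step at day {day} outside the {days}-day span")
        temp[day:] += inc
    return pd.DataFrame({"day": np.arange(days), "temp_c": temp})


def assessment_days(days: int = EXPERIMENT_DAYS, coarse_until: int = 10, coarse_step: int = 3) -> np.ndarray:
    """Assessment cadence: every ``coarse_step`` days early on, then daily."""
    early = list(range(0, coarse_until, coarse_step))
    return np.array(sorted(set(early) | set(range(coarse_until, days))))


def _status_from_dhw(dhw: float, theta: float, direct: bool, config: PopulationConfig) -> int:
    """Ordinal status implied by accumulated DHW for one fragment.

    Visible trajectory enters partial bleaching at ``theta - bleach_offset``
    and advances one ordinal step every ``logistic_scale`` °C-weeks; death
    occurs exactly at ``theta``.  Direct-death fragments show nothing
    before dying.
    """
    if dhw >= theta:
        return 4
    if direct:
        return 0
    onset = theta - config.bleach_offset
    if dhw < onset:
        return 0
    step = int((dhw - onset) // config.logistic_scale)
    return min(step + 1, 3)


def generate_experiment(
    population: tuple[pd.DataFrame, pd.DataFrame],
    config: PopulationConfig,
    ramp: pd.DataFrame | None = None,
    stress_threshold_c: float = TANK_STRESS_THRESHOLD_C,
    start_date: str = "2019-04-19",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the synthetic tank heatwave over a generated population.

    Returns ``(status, rgb, temperatures)``:

    * ``status``: ``fragment_id, colony_id, tank_id, day, status`` at each
      assessment; a stress tank's records stop at the first assessment at
      which at least half of its fragments are dead.
    * ``rgb``: ``fragment_id, day, r, g, b`` for fragments with living
      tissue (status 0-3), whiteness increasing with bleaching state.
    * ``temperatures``: daily ``entity_id, date, sst_c`` per tank.
    """
    colonies, fragments = population
    if ramp is None:
        ramp = default_ramp_schedule()
    ramp_days = ramp["day"].to_numpy(int)
    if len(ramp) < 2 or not np.array_equal(ramp_days, np.arange(len(ramp))):
        raise ValueError(
            "ramp schedule must cover the experiment span with contiguous days from 0"
        )
    days = assessment_days(len(ramp))

    dates = pd.to_datetime(start_date) + pd.to_timedelta(ramp["day"].to_numpy(int), unit="D")
    temp_frames = []
    for tank in stress_tank_ids(config):
        temp_frames.append(
            pd.DataFrame({"entity_id": tank, "date": dates, "sst_c": ramp["temp_c"].to_numpy(float)})
        )
    temp_frames.append(
        pd.DataFrame({"entity_id": CONTROL_TANK, "date": dates, "sst_c": float(ramp["temp_c"].iloc[0])})
    )
    temps = pd.concat(temp_frames, ignore_index=True)

    dhw = tank_dhw(temps, adjusted_threshold=stress_threshold_c)
    dhw["day"] = (pd.to_datetime(dhw["date"]) - pd.to_datetime(start_date)).dt.days
    dhw_by_day = {
        t: dict(zip(g["day"], g["dhw_cweeks"])) for t, g in dhw.groupby("entity_id")
    }

    rng = _rng(config.seed, "experiment")
    direct = dict(
        zip(
            fragments["fragment_id"],
            rng.random(len(fragments)) < config.direct_death_prob,
        )
    )
    # control-tank handling deaths: per colony, the control fragment dies at a
    # uniformly drawn assessment (handling damage, unrelated to heat)
    handling = {}
    for cid in colonies["colony_id"]:
        if rng.random() < config.p_handling_death:
            handling[cid] = int(rng.choice(days[1:]))

    status_rows = []
    for tank, tgrp in fragments.groupby("tank_id", sort=False):
        is_control = tank == CONTROL_TANK
        frag_ids = tgrp["fragment_id"].to_numpy()
        col_ids = tgrp["colony_id"].to_numpy()
        thetas = tgrp["theta_frag"].to_numpy(float)
        for day in days:
            d = dhw_by_day[tank][int(day)]
            statuses = []
            for fid, cid, th in zip(frag_ids, col_ids, thetas):
                if is_control:
                    s = 4 if cid in handling and day >= handling[cid] else 0
                else:
                    s = _status_from_dhw(d, th, direct[fid], config)
                statuses.append(s)
                status_rows.append(
                    {"fragment_id": fid, "colony_id": cid, "tank_id": tank, "day": int(day), "status": s}
                )
            if not is_control and np.mean(np.asarray(statuses) == 4) >= 0.5:
                break  # tank terminated at 50% mortality

    status = pd.DataFrame(status_rows)

    rgb_rng = _rng(config.seed, "rgb")
    live = status[status["status"] <= 3]
    w = live["status"].map(_WHITENESS).to_numpy(float) * 255.0
    chans = np.clip(
        w[:, None] + rgb_rng.normal(0.0, _RGB_NOISE_SD, (len(live), 3)), 0.0, 255.0
    )
    rgb = pd.DataFrame(
        {
            "fragment_id": live["fragment_id"].to_numpy(),
            "day": live["day"].to_numpy(),
            "r": chans[:, 0],
            "g": chans[:, 1],
            "b": chans[:, 2],
        }
    )
    return status, rgb, temps


def generate_its2_table(
    population: tuple[pd.DataFrame, pd.DataFrame],
    config: PopulationConfig,
    p_dominant: float = 0.77,
) -> pd.DataFrame:
    """Symbiont ITS2 type-profile relative abundances per colony.

    One type profile dominates most colonies; the rest carry one of a few
    rare variants.  Assignment is independent of the colony's tolerance
    threshold by construction, emulating a population whose symbiont
    community does not explain tolerance.  Rows sum to one.
    """
    _probability("p_dominant", p_dominant)
    colonies, _ = population
    rng = _rng(config.seed, "its2")
    rows = []
    for cid in colonies["colony_id"]:
        if rng.random() < p_dominant:
            major = ITS2_DOMINANT
        else:
            major = str(rng.choice(ITS2_RARE))
        abund = {p: 0.0 for p in (ITS2_DOMINANT,) + ITS2_RARE}
        major_frac = rng.uniform(0.85, 1.0)
        abund[major] = major_frac
        minor = str(rng.choice([p for p in abund if p != major]))
        abund[minor] += 1.0 - major_frac
        for profile, ra in abund.items():
            rows.append({"colony_id": cid, "profile": profile, "rel_abundance": ra})
    return pd.DataFrame(rows)


def generate_projection_ensemble(config: ProjectionConfig) -> pd.DataFrame:
    """Quarterly DHW projections for a synthetic GCM ensemble.

    Per model-year-quarter: ``max(0, baseline + model offset +
    trend * (year - start_year) + noise)``; deterministic given the seed.

    Returns columns ``gcm, scenario, year, quarter, dhw``.
    """
    rng = _rng(config.seed, "projection")
    years = np.arange(config.start_year, config.end_year + 1)
    rows = []
    for scenario, n_models, trend in zip(
        config.scenarios, config.n_models_per_scenario, config.trend
    ):
        for m in range(n_models):
            gcm = f"{scenario}-GCM{m + 1:02d}"
            offset = rng.normal(0.0, config.model_offset_sd)
            noise = rng.normal(0.0, config.noise_sd, (len(years), 4))
            vals = np.maximum(
                0.0,
                config.baseline + offset + trend * (years[:, None] - config.start_year) + noise,
            )
            for yi, year in enumerate(years):
                for q in range(4):
                    rows.append(
                        {
                            "gcm": gcm,
                            "scenario": scenario,
                            "year": int(year),
                            "quarter": q + 1,
                            "dhw": vals[yi, q],
                        }
                    )
    return pd.DataFrame(rows)
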