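import numpy as np
import pandas as pd
import pytest

import coralrht as crt
from coralrht import synthetic


@pytest.fixture(scope="session")
def default_cfg():
    return synthetic.PopulationConfig(seed=7)


@pytest.fixture(scope="session")
def experiment(default_cfg):
    """One default synthetic study, shared across tests."""
    population = crt.generate_population(default_cfg)
    status, rgb, temps = crt.generate_experiment(population, default_cfg)
    return {
        "config": default_cfg,
        "colonies": population[0],
        "fragments": population[1],
        "status": status,
        "rgb": rgb,
        "temps": temps,
    }


@pytest.fixture(scope="session")
def tank_dhw_by_day(experiment):
    dhw = crt.tank_dhw(experiment["temps"], adjusted_threshold=synthetic.TANK_STRESS_THRESHOLD_C)
    start = pd.to_datetime(dhw["date"]).min()
    dhw["day"] = (pd.to_datetime(dhw["date"]) - start).dt.days
    return dhw


@pytest.fixture(scope="session")
def classified(experiment):
    excluded = crt.exclude_handling_deaths(experiment["status"], synthetic.CONTROL_TANK)
    fates = crt.endpoint_fates(experiment["status"], synthetic.CONTROL_TANK)
    cls = crt.classify_endpoint(fates, p_hat=0.5, exclude=excluded)
    return {"excluded": excluded, "fates": fates, "classification": cls}


@pytest.fixture(scope="session")
def bmi_profiles(experiment, tank_dhw_by_day, classified):
    stress = experiment["status"]
    stress = stress[
        (stress["tank_id"] != synthetic.CONTROL_TANK)
        & ~stress["colony_id"].isin(classified["excluded"])
    ]
    obs = stress[["colony_id", "tank_id", "day", "status"]].copy()
    obs["value"] = obs["status"] / 4.0
    tanks = tank_dhw_by_day[tank_dhw_by_day["entity_id"] != synthetic.CONTROL_TANK]
    return crt.interpolate_profiles(
        obs, tanks.rename(columns={"entity_id": "tank_id"}), agg="mean"
    )


def simulate_glmm_obs(
    beta=(-8.0, 1.2, -3.0, 0.0),
    sigma_u=0.5,
    n_colonies=100,
    dhw_grid=None,
    m=20,
    seed=0,
):
    """Binomial observations drawn exactly from the GLMM's own model."""
    rng = np.random.default_rng(seed)
    if dhw_grid is None:
        dhw_grid = np.arange(0.0, 10.5, 0.5)
    b0, b1, b2, b3 = beta
    rows = []
    for i in range(n_colonies):
        group = "RLHT" if i % 2 else "RHHT"
        g = 1.0 if group == "RLHT" else 0.0
        u = rng.normal(0.0, sigma_u)
        for d in dhw_grid:
            eta = b0 + b1 * d + b2 * g + b3 * d * g + u
            p = 1.0 / (1.0 + np.exp(-eta))
            rows.append((f"C{i:03d}", group, float(d), int(rng.binomial(m, p)), m))
    return pd.DataFrame(rows, columns=["colony_id", "group", "dhw", "k", "m"])
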