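"""Degree heating weeks (DHW) and heat-stress alignment.

DHW is the standard accumulated heat-stress metric for coral bleaching:
daily sea-surface temperature anomalies relative to the maximum of the
monthly-mean climatology (MMM) are summed over a trailing 12-week (84-day)
window — counting only anomalies of at least 1 °C — and divided by seven
to express the result in °C-weeks.

This module computes the MMM baseline, daily DHW for satellite-style or
tank temperature series, and the projection of colony health indices from
experiment time onto a common DHW grid so that colonies exposed in tanks
with different realized stress histories become comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: length of the DHW accumulation window, days (12 weeks)
DHW_WINDOW_DAYS = 84
#: minimum anomaly (°C above MMM) that accumulates into DHW
DHW_MIN_ANOMALY = 1.0


@dataclass(frozen=True)
class ClimatologyBaseline:
    """Monthly SST climatology and its maximum (MMM), in °C."""

    monthly_mean_sst: tuple[float, ...]
    mmm: float = field(init=False)
    baseline_period: str = ""

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.monthly_mean_sst)
        if len(vals) != 12:
            raise ValueError(
                f"monthly_mean_sst needs exactly 12 monthly means, got {len(vals)}"
            )
        if not all(np.isfinite(vals)):
            raise ValueError("monthly_mean_sst contains non-finite values")
        object.__setattr__(self, "monthly_mean_sst", vals)
        object.__setattr__(self, "mmm", max(vals))


def compute_mmm(climatology: pd.DataFrame, baseline_period: str = "") -> ClimatologyBaseline:
    """Build the MMM baseline from a 12-row monthly climatology table.

    Parameters
    ----------
    climatology
        Table with columns ``month`` (1..12) and ``mean_sst_c``.
    """
    months = set(climatology["month"].astype(int))
    if months != set(range(1, 13)):
        missing = sorted(set(range(1, 13)) - months)
        raise ValueError(f"climatology missing months: {missing}")
    ordered = climatology.sort_values("month")["mean_sst_c"].to_numpy(float)
    return ClimatologyBaseline(tuple(ordered), baseline_period=baseline_period)


def _rolling_dhw(sst: np.ndarray, stress_base: float, include_equal: bool) -> np.ndarray:
    """Trailing-window DHW for one daily series.

    ``stress_base`` is the reference temperature (MMM); anomalies of at
    least :data:`DHW_MIN_ANOMALY` above it accumulate.  The first 83 days
    use the available partial history (the experiment starts from zero
    accumulated stress, so a shorter window is the correct behaviour
    rather than a missing value).
    """
    if not np.all(np.isfinite(sst)):
        raise ValueError("temperature series contains non-finite values")
    anom = sst - stress_base
    if include_equal:
        hot = anom >= DHW_MIN_ANOMALY
    else:
        hot = anom > DHW_MIN_ANOMALY
    contrib = np.where(hot, anom, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(contrib)])
    lo = np.maximum(np.arange(len(sst)) - (DHW_WINDOW_DAYS - 1), 0)
    return (csum[1:] - csum[lo]) / 7.0


def compute_dhw(
    temps: pd.DataFrame,
    baseline: ClimatologyBaseline,
    include_equal: bool = True,
) -> pd.DataFrame:
    """Daily DHW per entity from a daily temperature table.

    Parameters
    ----------
    temps
        Columns ``entity_id``, ``date``, ``sst_c``; one row per entity-day,
        dates strictly increasing and gap-free within each entity.
    baseline
        MMM climatology baseline.
    include_equal
        If True (operational convention) anomalies exactly equal to 1 °C
        accumulate; if False only strictly greater anomalies do.

    Returns
    -------
    DataFrame with columns ``entity_id``, ``date``, ``dhw_cweeks``.
    """
    out = []
    for entity, grp in temps.groupby("entity_id", sort=False):
        grp = grp.sort_values("date")
        dates = pd.to_datetime(grp["date"])
        gaps = dates.diff().dropna()
        if (gaps <= pd.Timedelta(0)).any():
            raise ValueError(f"entity {entity}: dates not strictly increasing")
        if (gaps != pd.Timedelta(days=1)).any():
            raise ValueError(f"entity {entity}: temperature series has gaps")
        dhw = _rolling_dhw(grp["sst_c"].to_numpy(float), baseline.mmm, include_equal)
        out.append(pd.DataFrame({"entity_id": entity, "date": dates.values, "dhw_cweeks": dhw}))
    return pd.concat(out, ignore_index=True)


def tank_dhw(
    temps: pd.DataFrame,
    adjusted_threshold: float,
    include_equal: bool = True,
) -> pd.DataFrame:
    """DHW for tank series against an adjusted stress threshold.

    The satellite MMM is not directly applicable inside mesocosm tanks, so
    accumulation starts at ``adjusted_threshold`` (°C): the algorithm is
    identical to :func:`compute_dhw` with the MMM replaced by
    ``adjusted_threshold - 1``.
    """
    if float(temps["sst_c"].max()) < adjusted_threshold:
        warnings.warn(
            f"adjusted_threshold {adjusted_threshold} never reached by any tank; "
            "all DHW will be zero",
            stacklevel=2,
        )
    fake = ClimatologyBaseline((adjusted_threshold - DHW_MIN_ANOMALY,) * 12)
    return compute_dhw(temps, fake, include_equal=include_equal)


def interpolate_profiles(
    observations: pd.DataFrame,
    dhw_by_tank: pd.DataFrame,
    grid_step: float = 0.1,
    agg: str = "mean",
) -> pd.DataFrame:
    """Project per-tank colony index observations onto a common DHW grid.

    Each stress tank maps assessment day -> accumulated DHW through its own
    temperature history.  Index values observed in a tank are linearly
    interpolated onto a shared DHW grid (0 to the largest DHW any tank
    reached before termination, fixed step) and then averaged across tanks.
    Grid points beyond a tank's termination DHW are missing for that tank;
    a grid point beyond every contributing tank's termination is NaN.

    Parameters
    ----------
    observations
        Columns ``colony_id``, ``tank_id``, ``day``, ``value``.
    dhw_by_tank
        Columns ``tank_id``, ``day``, ``dhw_cweeks`` covering every
        observation day of each tank.
    grid_step
        DHW grid spacing, °C-weeks.
    agg
        How a colony's per-tank curves combine at each grid point:
        ``"mean"`` (the BMI convention — the across-tank mean of status/4
        equals the fragment-proportion BMI) or ``"median"`` (the CMI
        convention).

    Returns
    -------
    DataFrame indexed by ``colony_id`` with one column per grid DHW value.
    """
    day2dhw = {
        t: dict(zip(g["day"].to_numpy(int), g["dhw_cweeks"].to_numpy(float)))
        for t, g in dhw_by_tank.groupby("tank_id")
    }
    obs = observations.copy()
    missing_tanks = set(obs["tank_id"]) - set(day2dhw)
    if missing_tanks:
        raise ValueError(f"no DHW series for tanks: {sorted(missing_tanks)}")

    def to_dhw(row):
        m = day2dhw[row["tank_id"]]
        d = int(row["day"])
        if d not in m:
            raise ValueError(f"tank {row['tank_id']}: no DHW for observation day {d}")
        return m[d]

    obs["dhw"] = obs.apply(to_dhw, axis=1)
    max_dhw = obs.groupby("tank_id")["dhw"].max().max()
    grid = np.round(np.arange(0.0, max_dhw + grid_step / 2, grid_step), 10)

    rows = {}
    for colony, cgrp in obs.groupby("colony_id", sort=True):
        tank_curves = []
        for _, tgrp in cgrp.groupby("tank_id"):
            tgrp = tgrp.sort_values("dhw")
            x = tgrp["dhw"].to_numpy(float)
            y = tgrp["value"].to_numpy(float)
            vals = np.interp(grid, x, y, left=y[0], right=np.nan)
            vals[grid > x[-1]] = np.nan  # no extrapolation past termination
            tank_curves.append(vals)
        if not tank_curves:
            raise ValueError(f"colony {colony}: no observations to interpolate")
        stacked = np.vstack(tank_curves)
        if agg not in ("mean", "median"):
            raise ValueError(f"unknown aggregation {agg!r}")
        reducer = np.nanmean if agg == "mean" else np.nanmedian
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid tails
            rows[colony] = reducer(stacked, axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=grid).rename_axis("colony_id")
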