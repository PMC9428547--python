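"""Annual bleaching-mortality (ABM) onset under projected warming.

Quarterly DHW projections from a GCM ensemble are reduced to one annual
heat-stress value per model-year (the within-year maximum by default —
DHW is already an accumulation, so the annual peak is the year's stress).
The ABM onset for a tolerance threshold is the first year from which the
entire coming decade meets or exceeds the threshold annually; models
whose horizon ends before any full decade qualifies are censored.
Differences in onset between thresholds (4/8/12 °C-weeks, the bleaching
alert ladder) and emissions scenarios are tested with a linear mixed
model with a random intercept per GCM, followed by Tukey-adjusted
pairwise contrasts of the threshold-by-scenario cell means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLDS = (4.0, 8.0, 12.0)
#: consecutive years of exceedance defining "annual" conditions
ABM_RUN_YEARS = 10


def annual_dhw(quarterly, mode: str = "max") -> float:
    """Annualize one year's four quarterly DHW values.

    ``mode="max"`` (default) takes the year's peak accumulated stress;
    ``mode="sum"`` is provided for sensitivity analysis.
    """
    vals = np.asarray(quarterly, dtype=float)
    if vals.shape[-1] != 4 or np.isnan(vals).any():
        raise ValueError("need exactly 4 non-missing quarterly values")
    if mode == "max":
        return float(vals.max(axis=-1)) if vals.ndim == 1 else vals.max(axis=-1)
    if mode == "sum":
        return float(vals.sum(axis=-1)) if vals.ndim == 1 else vals.sum(axis=-1)
    raise ValueError(f"unknown annualization mode {mode!r}")


@dataclass(frozen=True)
class AbmOnset:
    """Onset of annual bleaching-mortality conditions for one model run."""

    gcm: str
    scenario: str
    threshold: float
    onset_year: int | None

    @property
    def censored(self) -> bool:
        return self.onset_year is None


def abm_onset(years, annual, threshold: float) -> int | None:
    """First year from which a full decade exceeds ``threshold`` annually.

    ``years`` must be contiguous and cover at least one decade.  Returns
    the onset year, or None (censored) when no qualifying decade fits in
    the horizon.  Exceedance is inclusive (>= threshold).
    """
    years = np.asarray(years, dtype=int)
    vals = np.asarray(annual, dtype=float)
    if len(years) < ABM_RUN_YEARS:
        raise ValueError(f"series must cover >= {ABM_RUN_YEARS} years")
    if not np.array_equal(np.diff(years), np.ones(len(years) - 1, dtype=int)):
        raise ValueError("years must be contiguous")
    hot = vals >= threshold
    window = np.convolve(hot.astype(int), np.ones(ABM_RUN_YEARS, dtype=int), "valid")
    idx = np.nonzero(window == ABM_RUN_YEARS)[0]
    return int(years[idx[0]]) if idx.size else None


def onset_table(
    ensemble: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    scenarios=None,
    mode: str = "max",
) -> pd.DataFrame:
    """ABM onset for every GCM x scenario x threshold combination.

    ``ensemble`` has columns ``gcm, scenario, year, quarter, dhw``.
    Returns ``gcm, scenario, threshold, onset_year, censored`` (one row
    per combination; ``onset_year`` NaN when censored).
    """
    if ensemble.empty:
        raise ValueError("empty projection ensemble")
    if scenarios is not None:
        missing = set(scenarios) - set(ensemble["scenario"])
        if missing:
            raise ValueError(f"ensemble lacks scenarios: {sorted(missing)}")
        ensemble = ensemble[ensemble["scenario"].isin(scenarios)]
    rows = []
    for (gcm, scenario), grp in ensemble.groupby(["gcm", "scenario"], sort=True):
        wide = grp.pivot_table(index="year", columns="quarter", values="dhw")
        years = wide.index.to_numpy(int)
        annual = annual_dhw(wide.to_numpy(float), mode=mode)
        for thr in thresholds:
            onset = abm_onset(years, annual, float(thr))
            rows.append(
                {
                    "gcm": gcm,
                    "scenario": scenario,
                    "threshold": float(thr),
                    "onset_year": np.nan if onset is None else onset,
                    "censored": onset is None,
                }
            )
    return pd.DataFrame(rows)


def fit_onset_lmm(onsets: pd.DataFrame) -> dict:
    """LMM of onset year on threshold x scenario with Tukey contrasts.

    Censored rows are excluded (their count is reported, not imputed).
    The model is ``onset_year ~ C(threshold) * C(scenario)`` with a
    random intercept per GCM; pairwise contrasts of the six cell means
    are adjusted family-wise with the studentized range (Tukey) using a
    containment degrees-of-freedom approximation.

    Returns a dict with ``model`` (fitted MixedLM results), ``cells``
    (cell-mean table), ``contrasts`` (pairwise table), ``n_censored``
    and ``re_var`` (between-GCM variance).
    """
    import statsmodels.formula.api as smf

    data = onsets.copy()
    n_censored = int(data["censored"].sum())
    data = data[~data["censored"]].copy()
    if data["gcm"].nunique() < 2:
        raise ValueError("need >= 2 models")
    cells = (
        data.groupby(["threshold", "scenario"])
        .size()
        .rename("n")
        .reset_index()
    )
    if (cells["n"] == 0).any() or len(cells) < 2:
        raise ValueError("a threshold x scenario cell has no uncensored onsets")

    data["thr"] = data["threshold"].astype(float).astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance warnings on clean data
        model = smf.mixedlm(
            "onset_year ~ C(thr) * C(scenario)", data, groups=data["gcm"]
        ).fit(reml=True)

    # cell means as linear combinations of the fixed effects
    fe = model.fe_params
    cov = model.cov_params().loc[fe.index, fe.index].to_numpy()
    exog_names = list(fe.index)
    thr_levels = sorted(data["thr"].unique(), key=float)
    scen_levels = sorted(data["scenario"].unique())

    def cell_vector(thr: str, scen: str) -> np.ndarray:
        v = np.zeros(len(exog_names))
        for i, name in enumerate(exog_names):
            if name == "Intercept":
                v[i] = 1.0
            elif name == f"C(thr)[T.{thr}]":
                v[i] = 1.0
            elif name == f"C(scenario)[T.{scen}]":
                v[i] = 1.0
            elif name == f"C(thr)[T.{thr}]:C(scenario)[T.{scen}]":
                v[i] = 1.0
        return v

    labels, vectors = [], []
    for t in thr_levels:
        for s in scen_levels:
            labels.append(f"thr{float(t):g}|{s}")
            vectors.append(cell_vector(t, s))
    V = np.vstack(vectors)
    means = V @ fe.to_numpy()
    cell_table = pd.DataFrame({"cell": labels, "mean_onset": means})

    n_cells = len(labels)
    n_gcm = data["gcm"].nunique()
    # containment df: observations minus cell means minus (GCM - 1) intercepts
    df_resid = max(len(data) - n_cells - (n_gcm - 1), 1)
    rows = []
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            c = V[i] - V[j]
            est = float(c @ fe.to_numpy())
            se = float(np.sqrt(c @ cov @ c))
            q = abs(est) / se * np.sqrt(2.0) if se > 0 else np.inf
            p_adj = float(stats.studentized_range.sf(q, n_cells, df_resid))
            rows.append(
                {
                    "contrast": f"{labels[i]} - {labels[j]}",
                    "estimate": est,
                    "se": se,
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                }
            )
    contrasts = pd.DataFrame(rows)
    return {
        "model": model,
        "cells": cell_table,
        "contrasts": contrasts,
        "n_censored": n_censored,
        "re_var": float(model.cov_re.iloc[0, 0]),
        "df_resid": df_resid,
    }
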