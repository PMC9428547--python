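"""Relative heat tolerance (RHT) classification by endpoint mortality.

A colony with all replicate stressed fragments alive at its tanks' final
assessments is relatively high heat tolerant (RHHT); one with all
fragments dead is relatively low heat tolerant (RLHT).  Binomial theory
gives the chance probability of an all-same fate under the endpoint
mortality rate p: p^n for all dead, (1-p)^n for all alive, one-tailed in
the direction observed.  A category is assigned only when that chance
probability is below alpha; colonies with mixed fates stay unclassified,
and colonies whose procedural-control fragment died are excluded outright
as handling casualties.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("RHHT", "RLHT", "unclassified", "excluded")


def exclude_handling_deaths(status: pd.DataFrame, control_tank: str) -> frozenset:
    """Colonies whose control fragment reached status 4 (handling deaths).

    Every colony must have a control-tank fragment; its death at any
    assessment marks the colony excluded from all downstream analysis.
    """
    ctrl = status[status["tank_id"] == control_tank]
    covered = set(ctrl["colony_id"])
    missing = sorted(set(status["colony_id"]) - covered)
    if missing:
        raise ValueError(f"colonies missing a control fragment: {missing}")
    died = ctrl.loc[ctrl["status"] == 4, "colony_id"]
    return frozenset(died)


def endpoint_fates(status: pd.DataFrame, control_tank: str) -> pd.DataFrame:
    """Per-fragment endpoint fate at its own tank's final assessment.

    Tanks terminate at different times, so "endpoint" is tank-specific:
    the fragment's status at the last assessment recorded for its tank.

    Returns ``fragment_id, colony_id, tank_id, dead`` for stressed
    fragments only.
    """
    stress = status[status["tank_id"] != control_tank]
    last_day = stress.groupby("tank_id")["day"].transform("max")
    final = stress[stress["day"] == last_day]
    out = final[["fragment_id", "colony_id", "tank_id"]].copy()
    out["dead"] = (final["status"] == 4).to_numpy()
    return out.reset_index(drop=True)


def classify_endpoint(
    fates: pd.DataFrame,
    p_hat: float = 0.5,
    alpha: float = 0.05,
    exclude: frozenset = frozenset(),
) -> pd.DataFrame:
    """Classify colonies into RHT categories from endpoint fates.

    Parameters
    ----------
    fates
        Output of :func:`endpoint_fates`.
    p_hat
        Endpoint mortality rate used in the binomial chance test.  The
        tank-termination rule pins the realized rate to (just above) 50%,
        so the design rate 0.5 is the default; pass the realized pooled
        rate for a data-driven variant.
    alpha
        Significance level for assigning a category.
    exclude
        Handling-death colonies, marked ``excluded`` in the output.

    Returns
    -------
    DataFrame: ``colony_id, category, n_fragments, n_dead, binomial_p``.
    """
    if not 0.0 < p_hat < 1.0:
        raise ValueError(f"p_hat must be strictly inside (0, 1), got {p_hat}")
    rows = []
    for colony, grp in fates.groupby("colony_id", sort=True):
        n = len(grp)
        if n == 0:
            raise ValueError(f"colony {colony}: no stressed fragments")
        n_dead = int(grp["dead"].sum())
        if colony in exclude:
            rows.append((colony, "excluded", n, n_dead, np.nan))
            continue
        if n_dead == n:
            p = p_hat**n
            cat = "RLHT" if p < alpha else "unclassified"
        elif n_dead == 0:
            p = (1.0 - p_hat) ** n
            cat = "RHHT" if p < alpha else "unclassified"
        else:
            p = np.nan
            cat = "unclassified"
        rows.append((colony, cat, n, n_dead, p))
    return pd.DataFrame(
        rows, columns=["colony_id", "category", "n_fragments", "n_dead", "binomial_p"]
    )


def realized_mortality(fates: pd.DataFrame, exclude: frozenset = frozenset()) -> float:
    """Pooled endpoint mortality over non-excluded stressed fragments."""
    kept = fates[~fates["colony_id"].isin(exclude)]
    if kept.empty:
        raise ValueError("no non-excluded fragments")
    return float(kept["dead"].mean())


def compare_group_bmi(bmi_rhht, bmi_rlht) -> tuple[float, float]:
    """Rank-based comparison of mean BMI between the tolerance groups.

    Returns ``(W, p)`` with W the Mann-Whitney U statistic of the RHHT
    group (the rank sum of the first group minus its minimum possible
    value) and a two-sided p — exact for small samples without ties,
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(bmi_rhht, float)
    y = np.asarray(bmi_rlht, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both tolerance groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def tabulate_symbionts(its2: pd.DataFrame, classification: pd.DataFrame) -> pd.DataFrame:
    """Dominant ITS2 profile x RHT category contingency table (% colonies).

    The dominant profile of a colony is the argmax of its relative
    abundances.  Percentages are over all classified and unclassified
    (non-excluded) colonies; each row's total is the profile's overall
    share of the population.
    """
    kept = classification[classification["category"] != "excluded"]
    missing = sorted(set(kept["colony_id"]) - set(its2["colony_id"]))
    if missing:
        raise ValueError(f"colonies missing from the ITS2 table: {missing}")
    dominant = (
        its2.sort_values("rel_abundance", ascending=False)
        .groupby("colony_id", sort=False)
        .first()["profile"]
        .rename("dominant_profile")
    )
    df = kept.merge(dominant, left_on="colony_id", right_index=True)
    n = len(df)
    table = (
        df.groupby(["dominant_profile", "category"]).size().unstack(fill_value=0)
        / n
        * 100.0
    )
    for cat in ("RHHT", "RLHT", "unclassified"):
        if cat not in table:
            table[cat] = 0.0
    table = table[["RHHT", "RLHT", "unclassified"]]
    table.columns = ["high_rhht_pct", "low_rlht_pct", "unclassified_pct"]
    table["total_pct"] = table.sum(axis=1)
    return table.sort_values("total_pct", ascending=False).reset_index()
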