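"""Bleaching-and-mortality (BMI) and colour-and-mortality (CMI) indices.

BMI summarizes a colony's ordinal fragment statuses (0 healthy, 1
partially bleached, 2 bleached, 3 partial mortality, 4 dead) as a weighted
mean scaled to [0, 1]:

    BMI = (0*c1 + 1*c2 + 2*c3 + 3*c4 + 4*c5) / 4

with c1..c5 the proportions of fragments in each category.  CMI replaces
the subjective live-state scores with a normalized RGB colour intensity
(fraction of the brightest pixel observed in the experiment), giving a
continuous index in [0, 2] that resolves colour change before bleaching
is visible to the eye.

The module also z-scores colony-by-DHW profile matrices column-wise and
clusters response trajectories hierarchically (Euclidean distance, Ward
linkage in its classic unsquared-distance form).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

VALID_STATUSES = frozenset(range(5))


def _check_statuses(statuses: np.ndarray) -> np.ndarray:
    statuses = np.asarray(statuses)
    if statuses.size == 0:
        raise ValueError("empty fragment status set")
    if not set(np.unique(statuses)) <= VALID_STATUSES:
        bad = sorted(set(np.unique(statuses)) - VALID_STATUSES)
        raise ValueError(f"invalid ordinal statuses: {bad}")
    return statuses.astype(int)


def compute_bmi(statuses) -> float:
    """BMI of one colony at one assessment from its stressed fragments.

    Equals the mean ordinal status divided by 4 (the category-proportion
    weighted sum and the mean are identical); range [0, 1].
    """
    return float(_check_statuses(statuses).mean() / 4.0)


def bmi_series(status: pd.DataFrame, exclude: set | frozenset = frozenset()) -> pd.DataFrame:
    """Per-colony BMI at each assessment day from a fragment status table.

    Only fragments under observation on a given day contribute (terminated
    tanks stop contributing after their final assessment).

    Parameters
    ----------
    status
        Stress-tank records: ``colony_id, day, status``.
    exclude
        Colony ids removed from the analysis (handling deaths).
    """
    df = status[~status["colony_id"].isin(exclude)]
    out = (
        df.groupby(["colony_id", "day"])["status"]
        .apply(lambda s: compute_bmi(s.to_numpy()))
        .rename("bmi")
        .reset_index()
    )
    return out


def mean_bmi(daily_bmi) -> float:
    """Colony mean BMI: plain average of the daily BMI values."""
    vals = np.asarray(daily_bmi, dtype=float)
    if vals.size == 0:
        raise ValueError("no assessments to average")
    return float(vals.mean())


def colony_mean_bmi(status: pd.DataFrame, exclude: set | frozenset = frozenset()) -> pd.Series:
    """Mean BMI per colony over assessment days, indexed by colony_id."""
    daily = bmi_series(status, exclude)
    return daily.groupby("colony_id")["bmi"].mean().rename("mean_bmi")


def colour_intensity(r, g, b, max_intensity: float):
    """Colour intensity: Euclidean RGB norm as a fraction of the maximum.

    ``max_intensity`` is the largest norm measured in the experiment, so
    values self-normalize into [0, 1] (clipped against numerical spill).
    """
    if max_intensity <= 0:
        raise ValueError(f"max_intensity must be > 0, got {max_intensity}")
    norm = np.sqrt(np.square(np.asarray(r, float)) + np.square(np.asarray(g, float)) + np.square(np.asarray(b, float)))
    out = np.clip(norm / max_intensity, 0.0, 1.0)
    return float(out) if np.isscalar(r) else out


def recalc_cmi_score(status: int, intensity: float | None) -> float:
    """Fragment CMI score in [0, 2] from ordinal status and colour intensity.

    Live visual states (0/1/2) are replaced by the colour-intensity
    fraction; partial mortality adds 1 to it; dead fragments score the
    maximum of 2 regardless of colour.
    """
    if status not in VALID_STATUSES:
        raise ValueError(f"invalid status {status}")
    if status == 4:
        return 2.0
    if intensity is None or not np.isfinite(intensity):
        raise ValueError(f"missing colour intensity for live fragment (status {status})")
    if not 0.0 <= intensity <= 1.0:
        raise ValueError(f"intensity must be in [0, 1], got {intensity}")
    if status == 3:
        return float(intensity) + 1.0
    return float(intensity)


def colony_cmi(fragment_scores, method: str = "median") -> float:
    """Colony CMI at one DHW point: median (default) across its fragments.

    A mean-aggregation switch is provided for sensitivity checks.  The
    even-count median is the midpoint of the central pair.
    """
    vals = np.asarray(fragment_scores, dtype=float)
    if vals.size == 0:
        raise ValueError("no fragment scores")
    if method == "median":
        return float(np.median(vals))
    if method == "mean":
        return float(vals.mean())
    raise ValueError(f"unknown aggregation method {method!r}")


def zscore_matrix(profiles: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Z-score each DHW column of a colony-by-DHW profile matrix.

    Population (n) standard deviation by default (``ddof=1`` switches to
    the sample convention).  Zero-variance columns map to all zeros; NaN
    cells (beyond a colony's last observed DHW) stay NaN and are ignored
    in the column moments.
    """
    M = profiles.to_numpy(float)
    mean = np.nanmean(M, axis=0)
    sd = np.nanstd(M, axis=0, ddof=ddof)
    Z = np.where(sd > 0, (M - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    Z[np.isnan(M)] = np.nan
    return pd.DataFrame(Z, index=profiles.index, columns=profiles.columns)


def _pairwise_complete_euclidean(M: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances using shared non-missing columns.

    Distances over the shared columns are rescaled by sqrt(p / p_shared)
    (the convention R's ``dist`` uses for missing cells), so rows observed
    over shorter DHW ranges remain comparable.
    """
    n, p = M.shape
    ok = ~np.isnan(M)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ok[i] & ok[j]
            k = int(shared.sum())
            if k == 0:
                raise ValueError(f"rows {i} and {j} share no observed grid points")
            d2 = float(np.sum((M[i, shared] - M[j, shared]) ** 2)) * (p / k)
            D[i, j] = D[j, i] = np.sqrt(d2)
    return squareform(D, checks=False)


def cluster_profiles(
    profiles: pd.DataFrame, n_clusters: int | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """Hierarchical clustering of (z-scored) response profiles.

    Euclidean distances (pairwise-complete over missing cells) with the
    classic Ward update applied to unsquared distances — the ``ward.D``
    agglomeration of R's ``hclust``.  SciPy's Ward routine applies the
    Lance-Williams recursion to squared inputs, so the same merge sequence
    is obtained by feeding it the square roots of the distances; the
    returned heights are squared back onto the ``ward.D`` scale.

    Returns ``(linkage_matrix, labels)``; ``labels`` is None unless
    ``n_clusters`` is given.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    d = _pairwise_complete_euclidean(profiles.to_numpy(float))
    if np.allclose(d, 0.0):
        import warnings

        warnings.warn("all profiles identical; degenerate dendrogram", stacklevel=2)
    Z = hierarchy.linkage(np.sqrt(d), method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2  # back to the unsquared-distance (ward.D) height scale
    labels = None
    if n_clusters is not None:
        lab = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        labels = pd.Series(lab, index=profiles.index, name="cluster")
    return Z, labels


def cmi_profile_inputs(
    status: pd.DataFrame,
    rgb: pd.DataFrame,
    exclude: set | frozenset = frozenset(),
    method: str = "median",
) -> pd.DataFrame:
    """Per-fragment CMI observations ready for DHW interpolation.

    Joins status and RGB tables, normalizes colour intensity by the
    experiment-wide maximum, applies the CMI recalculation per fragment
    and returns ``colony_id, tank_id, day, value`` rows (``value`` is the
    fragment CMI score; colony aggregation happens on the DHW grid).
    """
    df = status[~status["colony_id"].isin(exclude)].merge(
        rgb, on=["fragment_id", "day"], how="left"
    )
    norm = np.sqrt(df["r"] ** 2 + df["g"] ** 2 + df["b"] ** 2)
    max_int = float(norm.max())
    frac = norm / max_int
    scores = [
        recalc_cmi_score(int(s), None if pd.isna(f) else float(min(f, 1.0)))
        for s, f in zip(df["status"], frac)
    ]
    out = df[["colony_id", "tank_id", "day"]].copy()
    out["value"] = scores
    return out
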