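"""CSV schemas, validated readers/writers, and study configuration.

All tabular interchange is plain CSV with fixed headers.  Readers
validate every row and report failures with the file, 1-based data row
number and offending field; writers round-trip losslessly through the
corresponding reader.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A table failed schema validation."""


def _in_range(lo, hi):
    def check(v):
        return lo <= v <= hi

    return check


#: column -> (dtype, row validator or None)
SCHEMAS: dict[str, dict] = {
    "temperature": {
        "entity_id": (str, None),
        "date": ("date", None),
        "sst_c": (float, np.isfinite),
    },
    "climatology": {
        "month": (int, _in_range(1, 12)),
        "mean_sst_c": (float, np.isfinite),
    },
    "dhw": {
        "entity_id": (str, None),
        "date": ("date", None),
        "dhw_cweeks": (float, lambda v: np.isfinite(v) and v >= 0),
    },
    "status": {
        "fragment_id": (str, None),
        "colony_id": (str, None),
        "tank_id": (str, None),
        "day": (int, lambda v: v >= 0),
        "status": (int, _in_range(0, 4)),
    },
    "rgb": {
        "fragment_id": (str, None),
        "day": (int, lambda v: v >= 0),
        "r": (float, _in_range(0, 255)),
        "g": (float, _in_range(0, 255)),
        "b": (float, _in_range(0, 255)),
    },
    "its2": {
        "colony_id": (str, None),
        "profile": (str, None),
        "rel_abundance": (float, _in_range(0, 1)),
    },
    "projections": {
        "gcm": (str, None),
        "scenario": (str, None),
        "year": (int, None),
        "quarter": (int, _in_range(1, 4)),
        "dhw": (float, lambda v: np.isfinite(v) and v >= 0),
    },
    "classification": {
        "colony_id": (str, None),
        "category": (str, lambda v: v in ("RHHT", "RLHT", "unclassified", "excluded")),
        "n_fragments": (int, lambda v: v >= 1),
        "n_dead": (int, lambda v: v >= 0),
        "binomial_p": (float, None),
        "mean_bmi": (float, None),
    },
    "profiles": {
        "colony_id": (str, None),
        "dhw": (float, lambda v: v >= 0),
        "value": (float, None),
    },
    "delta_dhw": {
        "step": (int, None),
        "n_rhht": (int, None),
        "n_rlht": (int, None),
        "bmi_level": (float, _in_range(0, 1)),
        "dhw_high": (float, None),
        "dhw_low": (float, None),
        "delta_dhw": (float, None),
        "delta_lo": (float, None),
        "delta_hi": (float, None),
    },
    "abm_onset": {
        "gcm": (str, None),
        "scenario": (str, None),
        "threshold": (float, None),
        "onset_year": (float, None),
        "censored": (bool, None),
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` naming the row (1-based, excluding the
    header) and field of the first violation.
    """
    columns = SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = {}
    for col, (dtype, check) in columns.items():
        series = df[col]
        try:
            if dtype is str:
                conv = series.astype(str)
            elif dtype is int:
                conv = series.astype(float)
                if not np.all(conv == np.round(conv)):
                    bad = int(np.nonzero(conv != np.round(conv))[0][0]) + 1
                    raise SchemaError(f"{path}: row {bad}, field {col!r}: not an integer")
                conv = conv.astype(int)
            elif dtype is float:
                conv = series.astype(float)
            elif dtype is bool:
                conv = series.astype(bool)
            elif dtype == "date":
                conv = pd.to_datetime(series)
            else:  # pragma: no cover
                raise AssertionError(dtype)
        except SchemaError:
            raise
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: field {col!r}: {exc}") from exc
        if check is not None:
            vals = conv.to_numpy()
            ok = np.array([bool(check(v)) for v in vals])
            if not ok.all():
                bad = int(np.nonzero(~ok)[0][0])
                raise SchemaError(
                    f"{path}: row {bad + 1}, field {col!r}: invalid value {vals[bad]!r}"
                )
        out[col] = conv
    return pd.DataFrame(out)


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a table restricted to its schema columns."""
    cols = [c for c in SCHEMAS[schema] if c in df.columns]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, index=False)


def profiles_to_long(profiles: pd.DataFrame) -> pd.DataFrame:
    """Colony-by-DHW matrix -> long ``colony_id, dhw, value`` table."""
    long = profiles.rename_axis("colony_id").reset_index().melt(
        id_vars="colony_id", var_name="dhw", value_name="value"
    )
    long["dhw"] = long["dhw"].astype(float)
    return long.dropna(subset=["value"]).sort_values(["colony_id", "dhw"]).reset_index(drop=True)


def profiles_from_long(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`profiles_to_long`."""
    return long.pivot(index="colony_id", columns="dhw", values="value")


@dataclasses.dataclass
class StudyConfig:
    """End-to-end pipeline configuration.

    ``None`` paths mean "generate synthetically with ``seed``".
    """

    out_dir: str = "study_out"
    status_path: str | None = None
    rgb_path: str | None = None
    temperature_path: str | None = None
    its2_path: str | None = None
    projections_path: str | None = None
    control_tank: str = "control"
    alpha: float = 0.05
    p_hat: str | float = 0.5  # "realized" or a fixed rate
    grid_step: float = 0.1
    m_trials: int = 20
    n_boot: int = 1000
    target_n: int = 10
    thresholds: tuple[float, ...] = (4.0, 8.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.m_trials < 1 or self.n_boot < 1 or self.target_n < 1:
            raise ValueError("m_trials, n_boot and target_n must be >= 1")
        if isinstance(self.p_hat, str) and self.p_hat != "realized":
            raise ValueError("p_hat must be a rate in (0,1) or 'realized'")
        for p in (
            self.status_path,
            self.rgb_path,
            self.temperature_path,
            self.its2_path,
            self.projections_path,
        ):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input file does not exist: {p}")


def load_config(path: str | Path) -> StudyConfig:
    """Load a :class:`StudyConfig` from a YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    return StudyConfig(**raw)
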