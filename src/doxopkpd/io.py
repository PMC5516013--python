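"""Table schemas, configuration and run logs.

Two tidy CSV schemas are the package's interchange formats:

* drug timecourse tables — ``time_hr, condition_id, compartment, value,
  value_kind`` (extra columns such as ``replicate`` are allowed);
* longitudinal count tables — ``time_hr, concentration_nM, exposure_hr,
  replicate, count``.

Readers validate the schema and point at the offending row or column.
Every CLI invocation writes one JSON run log with the command, config,
seeds and per-stage diagnostics.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "TIMECOURSE_COLUMNS",
    "COUNT_COLUMNS",
    "read_timecourse_table",
    "write_timecourse_table",
    "read_count_table",
    "write_count_table",
    "write_trajectory_table",
    "replicate_means",
    "load_config",
    "write_run_log",
]

TIMECOURSE_COLUMNS = ("time_hr", "condition_id", "compartment", "value", "value_kind")
COUNT_COLUMNS = ("time_hr", "concentration_nM", "exposure_hr", "replicate", "count")

_COMPARTMENTS = {
    "extracellular",
    "intracellular_free",
    "intracellular_bound",
    "intracellular_total",
}
_VALUE_KINDS = {"concentration_nM", "intensity_au"}


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise SchemaError(f"empty input file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"no data rows in {path}")
    return df


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_timecourse_table(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    bad = df[~df["compartment"].isin(_COMPARTMENTS)]
    if not bad.empty:
        raise SchemaError(
            f"{path}: unknown compartment {bad['compartment'].iloc[0]!r} "
            f"at row {bad.index[0]}"
        )
    bad = df[~df["value_kind"].isin(_VALUE_KINDS)]
    if not bad.empty:
        raise SchemaError(
            f"{path}: unknown value_kind {bad['value_kind'].iloc[0]!r} "
            f"at row {bad.index[0]}"
        )
    if df["value"].isna().any() or (df["value"] < 0).any():
        row = df.index[df["value"].isna() | (df["value"] < 0)][0]
        raise SchemaError(f"{path}: negative or missing value at row {row}")
    group_cols = ["condition_id", "compartment"]
    if "replicate" in df.columns:
        group_cols.append("replicate")
    for key, g in df.groupby(group_cols, sort=False):
        if not g["time_hr"].is_monotonic_increasing:
            raise SchemaError(f"{path}: unsorted time_hr within group {key}")
    return df


def write_timecourse_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_count_table(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, COUNT_COLUMNS, path)
    if df["count"].isna().any() or (df["count"] < 0).any():
        row = df.index[df["count"].isna() | (df["count"] < 0)][0]
        raise SchemaError(f"{path}: negative or missing count at row {row}")
    for key, g in df.groupby(["concentration_nM", "exposure_hr", "replicate"], sort=False):
        if not g["time_hr"].is_monotonic_increasing:
            raise SchemaError(f"{path}: unsorted time_hr within condition {key}")
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, COUNT_COLUMNS, path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_trajectory_table(times, counts, condition_id: str, source: str, path) -> None:
    """Model or observed trajectory rows: time_hr, condition_id, count, source."""
    if source not in ("model", "observed"):
        raise ValidationError("source must be 'model' or 'observed'")
    df = pd.DataFrame(
        {
            "time_hr": np.asarray(times, dtype=float),
            "condition_id": condition_id,
            "count": np.asarray(counts, dtype=float),
            "source": source,
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def replicate_means(count_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates to their mean count per condition and timepoint."""
    return (
        count_df.groupby(["concentration_nM", "exposure_hr", "time_hr"], as_index=False)[
            "count"
        ]
        .mean()
        .sort_values(["exposure_hr", "concentration_nM", "time_hr"])
        .reset_index(drop=True)
    )


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such config file: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def write_run_log(path, command: str, config: dict, seeds: dict, diagnostics: dict) -> None:
    """One JSON log per CLI invocation: provenance plus stage diagnostics."""
    from . import __version__

    payload = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "command": command,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "seeds": seeds,
        "software_version": __version__,
        "diagnostics": diagnostics,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=str))
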