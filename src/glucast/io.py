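"""Stable on-disk formats: per-patient CSV series and YAML sidecars.

One CSV row per sample, ISO-8601 UTC timestamps, floats with 6 decimals:

    timestamp,bg_mgdl,carbs_g,insulin_fast_u,insulin_slow_u

The sampling period is inferred from the timestamps on read and must be
uniform. Patient parameters travel in a YAML sidecar next to the CSV.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulator import ChannelSeries, PatientParams

__all__ = ["write_series", "read_series", "write_params", "read_params"]

COLUMNS = ["timestamp", "bg_mgdl", "carbs_g", "insulin_fast_u", "insulin_slow_u"]


def write_series(series: ChannelSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(series.timestamps).strftime("%Y-%m-%dT%H:%M:%S"),
            "bg_mgdl": series.bg,
            "carbs_g": series.carbs,
            "insulin_fast_u": series.insulin_fast,
            "insulin_slow_u": series.insulin_slow,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_series(path: str | Path) -> ChannelSeries:
    df = pd.read_csv(path)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"]).to_numpy()
    if len(ts) < 2:
        raise ValueError(f"{path}: need at least two samples to infer the period")
    steps = np.diff(ts).astype("timedelta64[s]").astype(float)
    if not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: non-uniform sampling period")
    return ChannelSeries(
        start_time=ts[0].astype("datetime64[s]"),
        dt_min=float(steps[0]) / 60.0,
        bg=df["bg_mgdl"].to_numpy(float),
        carbs=df["carbs_g"].to_numpy(float),
        insulin_fast=df["insulin_fast_u"].to_numpy(float),
        insulin_slow=df["insulin_slow_u"].to_numpy(float),
    )


def write_params(params: PatientParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(params), sort_keys=False))


def read_params(path: str | Path) -> PatientParams:
    return PatientParams(**yaml.safe_load(Path(path).read_text()))
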