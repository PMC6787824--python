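"""File formats and configuration.

Logger files use a BAS-style CSV dialect:

* light (".lig"-like):      ``status,datetime_iso,seconds_since_epoch,light``
* immersion (".act"-like):  ``status,datetime_iso,seconds_since_epoch,wet_count``

Tables (metadata, biometrics, isotopes, positions, schedules) are plain CSV
with a header row.  The pipeline configuration is a YAML mapping validated
against a fixed schema before any stage runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# logger files


def write_light(light: pd.DataFrame, path: PathLike) -> None:
    ts = pd.DatetimeIndex(light["timestamp"])
    out = pd.DataFrame({
        "status": "ok",
        "datetime_iso": ts.strftime("%Y-%m-%dT%H:%M:%S"),
        "seconds_since_epoch": (ts.asi8 // 10**9),
        "light": light["light"].round(2),
    })
    out.to_csv(path, index=False)


def read_light(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({
        "timestamp": pd.to_datetime(df["seconds_since_epoch"], unit="s"),
        "light": df["light"].astype(float),
    })


def write_immersion(immersion: pd.DataFrame, path: PathLike) -> None:
    ts = pd.DatetimeIndex(immersion["timestamp"])
    out = pd.DataFrame({
        "status": "ok",
        "datetime_iso": ts.strftime("%Y-%m-%dT%H:%M:%S"),
        "seconds_since_epoch": (ts.asi8 // 10**9),
        "wet_count": immersion["wet"].astype(int),
    })
    out.to_csv(path, index=False)


def read_immersion(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame({
        "timestamp": pd.to_datetime(df["seconds_since_epoch"], unit="s"),
        "wet": df["wet_count"].astype(int),
    })


# ---------------------------------------------------------------------------
# tables


def write_positions(positions: pd.DataFrame, path: PathLike, bird_id: str = "") -> None:
    out = positions.copy()
    if bird_id:
        out.insert(0, "bird_id", bird_id)
    out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_positions(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("date", "timestamp"):
        if col in df:
            df[col] = pd.to_datetime(df[col])
    return df


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, date_format="%Y-%m-%d")


def write_geojson(obj: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh)


# ---------------------------------------------------------------------------
# pipeline configuration

_CONFIG_SCHEMA = {
    "output_dir": str,
    "seed": int,
    "position_source": str,         # "geolocation" | "truth+noise" | "truth"
    "position_noise_km": (int, float),
    "simulate": dict,               # SimulationConfig fields
    "light_threshold": (int, float),
    "equinox_halfwidth_days": int,
    "speed_limit_kmh": (int, float),
    "phenology_radius_km": (int, float),
    "phenology_speed_km_day": (int, float),
    "phenology_window_days": int,
    "resident_radius_km": (int, float),
    "kernel_bandwidth_km": (int, float),
    "kernel_cell_km": (int, float),
    "nfi_window_days": int,
    "seab_draws": int,
}

DEFAULT_CONFIG = {
    "output_dir": "seaseg_output",
    "seed": 0,
    "position_source": "truth+noise",
    "position_noise_km": 186.0,
    "simulate": {},
    "light_threshold": 20.0,
    "equinox_halfwidth_days": 20,
    "speed_limit_kmh": 35.0,
    "phenology_radius_km": 500.0,
    "phenology_speed_km_day": 200.0,
    "phenology_window_days": 10,
    "resident_radius_km": 1000.0,
    "kernel_bandwidth_km": 186.0,
    "kernel_cell_km": 25.0,
    "nfi_window_days": 28,
    "seab_draws": 4000,
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    from .synthetic_data import SimulationConfig

    merged = dict(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if key not in _CONFIG_SCHEMA:
            raise ConfigError(f"unknown configuration key: {key!r}")
        expected = _CONFIG_SCHEMA[key]
        if not isinstance(value, expected):
            raise ConfigError(f"config key {key!r} expects {expected}, got {type(value)}")
        merged[key] = value
    if merged["position_source"] not in ("geolocation", "truth+noise", "truth"):
        raise ConfigError(f"invalid position_source {merged['position_source']!r}")
    sim_fields = set(SimulationConfig.__dataclass_fields__)
    unknown = set(merged["simulate"]) - sim_fields
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    return merged


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)
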