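"""File dialects, configuration and provenance.

CSV dialect: comma-separated, '.' decimal, UTF-8, one header row. Config
files are YAML or JSON, autodetected by extension. All writes are atomic
(write to a temporary file in the target directory, then rename). Every
run artifact carries a provenance block (package version, seed, config
hash).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import TrialSeries, GRID_DT
from .simulator import ModelParams, SimResult

__all__ = [
    "read_trial", "write_trial", "write_sim_result",
    "read_breath_records", "read_power_trace",
    "read_config", "write_config", "atomic_write_text",
    "read_model_params", "write_model_params", "provenance",
]

_TRIAL_COLUMNS = ("t", "u1", "u2")


def atomic_write_text(path, text: str) -> None:
    """Write-then-rename so readers never see a partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trial(path, trial: TrialSeries) -> None:
    df = trial.to_dataframe()
    # %.17g keeps the decimal text exact for float64 round-trips
    atomic_write_text(path, df.to_csv(index=False, float_format="%.17g"))


def read_trial(path) -> TrialSeries:
    """Read a trial CSV, validating the header and grid uniformity."""
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {}
    for col in df.columns:
        if col != col.lower() and col.lower() in (*_TRIAL_COLUMNS, "y"):
            warnings.warn(f"header {col!r} matched case-insensitively",
                          stacklevel=2)
            rename[col] = col.lower()
    df = df.rename(columns=rename)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.flatnonzero(np.abs(dt - GRID_DT) > 1e-9)
    if bad.size:
        raise ValueError(
            f"{path}: non-uniform grid at data line {int(bad[0]) + 2} "
            f"(spacing {dt[bad[0]]:.3f} s, expected {GRID_DT} s)")
    return TrialSeries.from_dataframe(df)


def read_breath_records(path) -> pd.DataFrame:
    """Raw breath-by-breath file: columns t, VE_exp_BTPS, VE_exp_STPD,
    FeO2, FeCO2 (end-of-breath timestamps, irregular)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["t", "VE_exp_BTPS", "VE_exp_STPD", "FeO2", "FeCO2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if np.any(np.diff(df["t"].to_numpy()) <= 0):
        raise ValueError(f"{path}: breath timestamps must be increasing")
    return df


def read_power_trace(path) -> pd.DataFrame:
    """Raw ergometer power file: columns t, watts (1 Hz)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("t", "watts") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_sim_result(path, result: SimResult) -> None:
    atomic_write_text(path, result.to_dataframe().to_csv(
        index=False, float_format="%.17g"))


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(path, data: dict) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        atomic_write_text(path, json.dumps(data, indent=2, sort_keys=True))
    else:
        atomic_write_text(path, yaml.safe_dump(data, sort_keys=True))


def read_model_params(path) -> ModelParams:
    """Model parameters from a flat key/value config block."""
    return ModelParams.from_dict(read_config(path))


def write_model_params(path, params: ModelParams) -> None:
    write_config(path, params.to_dict())


def provenance(seed=None, config: dict | None = None) -> dict:
    from . import __version__

    block = {"package": "bioen", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        block["config_sha256"] = digest
    return block
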