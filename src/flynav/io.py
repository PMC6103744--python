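"""Readers and writers for trajectory tables and run manifests."""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRAJECTORY_COLUMNS = [
    "t_s",
    "x_mm",
    "y_mm",
    "orientation_deg",
    "fly_id",
    "trial_id",
    "stimulus_id",
]


def read_trajectory_table(path) -> pd.DataFrame:
    """Read a raw trajectory table (CSV or HDF5 by extension)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(path, key="trajectories")
    else:
        df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    return df


def write_trajectory_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="trajectories", mode="w")
    else:
        df.to_csv(path, index=False)


def iter_trials(df: pd.DataFrame):
    """Yield ((fly_id, trial_id), per-trial frame) in deterministic order."""
    for key, g in df.groupby(["fly_id", "trial_id"], sort=True):
        yield key, g.sort_values("t_s").reset_index(drop=True)


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_manifest(path, **entries) -> None:
    """Write a YAML run manifest (parameters, seeds, versions)."""
    import flynav

    payload = {"flynav_version": flynav.__version__}
    payload.update({k: _plain(v) for k, v in entries.items()})
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=False)


def read_manifest(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
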