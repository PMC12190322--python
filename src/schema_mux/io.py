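"""Reading and writing the delimited-text session files.

Sessions are stored as UTF-8 CSV: ``trials.csv`` (one row per trial, fixed
header) and ``spikes.csv`` (long format, ``unit_id,spike_time``).  Write-read
round trips are exact (floats serialized via repr).
"""

from __future__ import annotations

import warnings
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from schema_mux.data import (
    TRIAL_COLUMNS,
    SpikeTrainSet,
    TrialTableFormatError,
    validate_trials,
)

_BOOL_COLS = ("reward_by_nonmatch", "reward_by_cueid", "completed")


def read_trial_table(path: str | PathLike) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    The stored ``config`` column is cross-checked against the configuration
    recomputed from the odor sequence; a mismatch raises a consistency error
    naming the trial.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableFormatError(f"{path}: missing columns {missing}")
    for col in _BOOL_COLS:
        df[col] = df[col].astype(bool)
    df["trial_index"] = df["trial_index"].astype(int)
    df["odor_id"] = df["odor_id"].astype(int)
    for col in ("t_trial_start", "t_poke_in", "t_odor_on", "t_unpoke", "t_well"):
        df[col] = df[col].astype(float)
    return validate_trials(df)


def write_trial_table(trials: pd.DataFrame, path: str | PathLike) -> None:
    trials = trials[list(TRIAL_COLUMNS)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False, float_format="%.17g")


def read_spike_table(path: str | PathLike) -> SpikeTrainSet:
    """Read a long-format spike table (``unit_id,spike_time``).

    Rows may arrive in any order; times are sorted per unit.  An empty file
    yields an empty set with a warning; negative times raise ``ValueError``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["unit_id", "spike_time"])
    if df.empty:
        warnings.warn(f"{path}: empty spike table", stacklevel=2)
        return SpikeTrainSet(session_id=path.parent.name, units={})
    if not {"unit_id", "spike_time"} <= set(df.columns):
        raise TrialTableFormatError(f"{path}: expected columns unit_id,spike_time")
    if (df["spike_time"] < 0).any():
        raise ValueError(f"{path}: negative spike time")
    units = {
        str(uid): np.sort(g["spike_time"].to_numpy(dtype=float))
        for uid, g in df.groupby("unit_id", sort=True)
    }
    return SpikeTrainSet(session_id=path.parent.name, units=units)


def write_spike_table(spikes: SpikeTrainSet, path: str | PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame({"unit_id": uid, "spike_time": times})
        for uid, times in spikes.units.items()
    ]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["unit_id", "spike_time"])
    df.to_csv(path, index=False, float_format="%.17g")
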