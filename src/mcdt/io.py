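"""Trial and participant file dialects.

One CSV per (participant, exercise, cognitive load) trial, named
``<participant>_<exercise>_<CL>.csv``, with a mandatory header
``time_s,acc_x,acc_y,acc_z,gyro_x,gyro_y,gyro_z`` (m/s^2 and degrees/s)
and uniform, strictly increasing time stamps.  The participant table is a
single CSV with id, group, age, sex, education, fab, mmse columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signals import TrialRecording

TRIAL_COLUMNS = ("time_s", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")
PARTICIPANT_COLUMNS = ("id", "group", "age", "sex", "education", "fab", "mmse")


class TrialParseError(ValueError):
    """A trial file violates the dialect."""


def trial_filename(participant_id: str, exercise: str, cl: str) -> str:
    return f"{participant_id}_{exercise}_{cl}.csv"


def write_trial(r: TrialRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": r.t,
            "acc_x": r.acc[:, 0], "acc_y": r.acc[:, 1], "acc_z": r.acc[:, 2],
            "gyro_x": r.gyro[:, 0], "gyro_y": r.gyro[:, 1], "gyro_z": r.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_trial(path: str | Path) -> TrialRecording:
    """Parse and validate one trial CSV; fs is inferred from the stamps."""
    path = Path(path)
    try:
        pid, exercise, cl = path.stem.split("_")
    except ValueError as e:
        raise TrialParseError(
            f"{path.name}: filename must look like <participant>_<exercise>_<CL>.csv"
        ) from e
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path.name}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TrialParseError(f"{path.name}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0)) + 2  # +1 for header, +1 for 1-based
        raise TrialParseError(f"{path.name}: non-increasing time_s at line {i}")
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        i = int(np.argmax(np.abs(dt - dt[0]) > 1e-6)) + 2
        raise TrialParseError(f"{path.name}: non-uniform sampling at line {i}")
    fs = float(round(1.0 / dt[0], 6))
    return TrialRecording(
        participant_id=pid, exercise=exercise, cl=cl, fs=fs, t=t,
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
        gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float),
    )


def write_participants(participants: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    participants.to_csv(path, index=False)
    return path


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"{Path(path).name}: missing columns {missing}")
    return df
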