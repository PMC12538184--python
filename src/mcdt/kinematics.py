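"""Kinematic parameters per trial: 8 per tapping task, 13 for gait.

Angular rates segmented into cycles are integrated with the trapezoidal
rule at the native sample spacing to obtain movement amplitudes; a
per-cycle linear drift correction (zero-velocity-update principle: the
limb returns to its start angle at each cycle boundary) removes slow gyro
bias before the peak angle is read off.  Across the 4 tapping tasks
(8 features each) and the 13 gait parameters there are 45 features per
cognitive-load condition, i.e. 180 columns for a complete 4-condition
protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

from .signals import (
    CL_LEVELS,
    GAIT_CUTOFF_HZ,
    TAPPING_CUTOFF_HZ,
    TAPPING_EXERCISES,
    GaitCycle,
    TapCycle,
    TapDetectorSettings,
    TrialRecording,
    butterworth_lowpass,
    segment_gait,
    segment_taps,
    select_channel,
    trim_still_phase,
)

TAPPING_FEATURES = ("tap", "exc", "exc_sd", "wo", "wo_sd", "wc", "wc_sd", "iav")
GAIT_FEATURES = (
    "gt", "gstrd", "gvel", "gstrd_l", "gstrd_t", "gstrd_t_sd",
    "gswt", "gswt_sd", "gstt", "gstt_sd", "grs", "gexc", "gexc_sd",
)
N_FEATURES_PER_CL = len(TAPPING_FEATURES) * len(TAPPING_EXERCISES) + len(GAIT_FEATURES)


@dataclass(frozen=True)
class TappingFeatures:
    """Per-trial tapping summary; SD fields are NaN below 2 cycles."""

    tap: int
    exc: float
    exc_sd: float
    wo: float
    wo_sd: float
    wc: float
    wc_sd: float
    iav: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TAPPING_FEATURES}


@dataclass(frozen=True)
class GaitFeatures:
    gt: float
    gstrd: int
    gvel: float
    gstrd_l: float
    gstrd_t: float
    gstrd_t_sd: float
    gswt: float
    gswt_sd: float
    gstt: float
    gstt_sd: float
    grs: float
    gexc: float
    gexc_sd: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GAIT_FEATURES}


def angular_excursion(
    omega_seg: np.ndarray, fs: float, drift_correct: bool = False
) -> float:
    """Peak absolute angle (degrees) reached over a gyro segment.

    Trapezoidal integration at the native sample spacing.  With
    ``drift_correct`` the integrated angle is linearly detrended so the
    cycle-end angle returns to the cycle-start angle — appropriate for a
    full open-close cycle, where the zero-velocity-update assumption
    pins both boundaries; leave it off for a single phase.
    """
    omega_seg = np.asarray(omega_seg, dtype=float)
    if omega_seg.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    theta = cumulative_trapezoid(omega_seg, dx=1.0 / fs, initial=0.0)
    if drift_correct:
        theta = theta - np.linspace(0.0, theta[-1], theta.size)
    return float(np.max(np.abs(theta)))


def iav(acc: np.ndarray, fs: float, still_mean: np.ndarray | None = None) -> float:
    """Integral of the absolute acceleration magnitude (m/s) — an energy
    expenditure proxy.

    The still-phase mean acceleration vector (the gravity baseline) is
    subtracted channel-wise before taking the Euclidean magnitude.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.ndim == 1:  # pre-computed magnitude channel
        mag = np.abs(acc - (0.0 if still_mean is None else float(np.asarray(still_mean))))
    else:
        if acc.shape[0] == 3 and acc.shape[1] != 3:
            acc = acc.T
        if still_mean is not None:
            acc = acc - np.asarray(still_mean, dtype=float)
        mag = np.linalg.norm(acc, axis=1)
    if mag.size < 2:
        return 0.0
    return float(trapezoid(mag, dx=1.0 / fs))


def _idx(t: float, fs: float) -> int:
    return int(round(t * fs))


def _integration_supports(cycles: list[TapCycle], fs: float, n: int) -> list[tuple[int, int]]:
    """Per-cycle integration bounds anchored at the inter-tap dwells.

    The digit rests between taps (the zero-velocity anchor), so each
    cycle's angle is integrated from the midpoint of the preceding dwell
    to the midpoint of the following one, capturing lobe tails that fall
    below the detection threshold.
    """
    bounds = []
    for i, c in enumerate(cycles):
        half = (_idx(c.t_end, fs) - _idx(c.t_start, fs)) // 4
        lo = (
            (_idx(cycles[i - 1].t_end, fs) + _idx(c.t_start, fs)) // 2
            if i > 0
            else max(0, _idx(c.t_start, fs) - half)
        )
        hi = (
            (_idx(c.t_end, fs) + _idx(cycles[i + 1].t_start, fs)) // 2
            if i + 1 < len(cycles)
            else min(n - 1, _idx(c.t_end, fs) + half)
        )
        bounds.append((lo, hi))
    return bounds


def extract_tapping_features(
    cycles: list[TapCycle],
    omega_move: np.ndarray,
    acc_move: np.ndarray,
    fs: float,
    acc_still_mean: np.ndarray | None = None,
    omega_move_raw: np.ndarray | None = None,
    velocity_stat: str = "peak",
) -> TappingFeatures:
    """Summarise one tapping trial from its detected cycles.

    exc is the per-cycle drift-corrected peak angle, integrated on the
    raw channel when provided (integration smooths noise by itself, and
    skipping the low-pass keeps filter ringing out of the amplitude);
    wo/wc are per-cycle peak angular speeds of the opening and closing
    phases on the filtered channel; SDs are taken across cycles; iav
    integrates over the whole movement window.
    """
    energy = iav(acc_move, fs, acc_still_mean)
    if not cycles:
        nan = float("nan")
        return TappingFeatures(0, nan, nan, nan, nan, nan, nan, energy)
    if velocity_stat not in ("peak", "mean"):
        raise ValueError("velocity_stat must be 'peak' or 'mean'")
    stat = np.max if velocity_stat == "peak" else np.mean
    omega_int = omega_move if omega_move_raw is None else omega_move_raw
    excs, wos, wcs = [], [], []
    supports = _integration_supports(cycles, fs, omega_int.size)
    for c, (lo, hi) in zip(cycles, supports):
        i0, ip, i1 = _idx(c.t_start, fs), _idx(c.t_peak, fs), _idx(c.t_end, fs)
        i1 = min(i1, omega_move.size - 1)
        excs.append(angular_excursion(omega_int[lo : hi + 1], fs, drift_correct=True))
        wos.append(float(stat(np.abs(omega_move[i0 : ip + 1]))))
        wcs.append(float(stat(np.abs(omega_move[ip : i1 + 1]))))
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan")
    return TappingFeatures(
        tap=len(cycles),
        exc=float(np.mean(excs)),
        exc_sd=sd(excs),
        wo=float(np.mean(wos)),
        wo_sd=sd(wos),
        wc=float(np.mean(wcs)),
        wc_sd=sd(wcs),
        iav=energy,
    )


def extract_gait_features(
    cycles: list[GaitCycle],
    r: TrialRecording,
    distance_m: float = 10.0,
    cutoff_hz: float = GAIT_CUTOFF_HZ,
) -> GaitFeatures | None:
    """Summarise one walking trial from its detected strides.

    Gait time spans first movement onset to last foot-flat; velocity and
    stride length follow from the fixed walkway distance; stride time is
    the onset-to-onset interval, split into swing (toe-off to heel
    strike) and stance (the remainder); gexc integrates the sagittal
    angular rate over swing only.  Returns None (with a warning) below
    2 strides.
    """
    if len(cycles) < 2:
        warnings.warn("fewer than 2 gait cycles; gait features undefined")
        return None
    fs = r.fs
    omega = butterworth_lowpass(r.gyro_y, fs, cutoff_hz)
    gt = cycles[-1].t_flat - cycles[0].t_move
    stride_t = [b.t_move - a.t_move for a, b in zip(cycles, cycles[1:])]
    swing_t = [c.t_heel_strike - c.t_toe_off for c in cycles]
    stance_t = [st - sw for st, sw in zip(stride_t, swing_t[:-1])]
    grs = float(np.mean([s / st for s, st in zip(stance_t, stride_t)]))
    excs = [
        angular_excursion(omega[_idx(c.t_toe_off, fs) : _idx(c.t_heel_strike, fs) + 1], fs)
        for c in cycles
    ]
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan")
    return GaitFeatures(
        gt=float(gt),
        gstrd=len(cycles),
        gvel=float(distance_m / gt),
        gstrd_l=float(distance_m / len(cycles)),
        gstrd_t=float(np.mean(stride_t)),
        gstrd_t_sd=sd(stride_t),
        gswt=float(np.mean(swing_t)),
        gswt_sd=sd(swing_t),
        gstt=float(np.mean(stance_t)),
        gstt_sd=sd(stance_t),
        grs=grs,
        gexc=float(np.mean(excs)),
        gexc_sd=sd(excs),
    )


def extract_trial_features(
    r: TrialRecording,
    tap_settings: TapDetectorSettings = TapDetectorSettings(),
    tapping_cutoff_hz: float = TAPPING_CUTOFF_HZ,
) -> dict[str, float]:
    """Filter, segment and featurise one trial (either task family)."""
    if r.exercise in TAPPING_EXERCISES:
        omega_raw = select_channel(r)
        omega = butterworth_lowpass(omega_raw, r.fs, tapping_cutoff_hz)
        omega_move, omega_still = trim_still_phase(omega, r.fs)
        omega_move_raw, _ = trim_still_phase(omega_raw, r.fs)
        acc_move, acc_still = r.acc[omega_still.size :], r.acc[: omega_still.size]
        noise_sd = float(np.std(omega_still)) if omega_still.size else 0.0
        cycles = segment_taps(omega_move, r.fs, tap_settings, noise_sd=noise_sd)
        feats = extract_tapping_features(
            cycles, omega_move, acc_move, r.fs,
            acc_still_mean=acc_still.mean(axis=0) if acc_still.size else None,
            omega_move_raw=omega_move_raw,
        )
        return feats.as_dict()
    cycles = segment_gait(r)
    feats = extract_gait_features(cycles, r)
    if feats is None:
        return {name: float("nan") for name in GAIT_FEATURES}
    return feats.as_dict()


def build_feature_table(trials) -> pd.DataFrame:
    """Tidy feature table from an iterable of (recording, features) trials.

    ``trials`` maps (participant_id, exercise, cl) to a feature dict (or
    to a TrialRecording, which is featurised on the fly).  Output is tidy:
    one row per (participant_id, exercise, cl, feature, value); missing
    trials simply have no rows.  Duplicate trial keys are an error.
    """
    rows = []
    seen = set()
    for key, value in (trials.items() if hasattr(trials, "items") else trials):
        pid, ex, cl = key
        if key in seen:
            raise ValueError(f"duplicate trial {key}")
        seen.add(key)
        if cl not in CL_LEVELS:
            raise ValueError(f"unknown cognitive load {cl!r}")
        feats = extract_trial_features(value) if isinstance(value, TrialRecording) else value
        for name, v in feats.items():
            rows.append(dict(participant_id=pid, exercise=ex, cl=cl, feature=name, value=v))
    return pd.DataFrame(rows, columns=["participant_id", "exercise", "cl", "feature", "value"])


def feature_table_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy table to one row per participant, one column per
    (exercise, feature, CL) — 180 columns for a complete protocol."""
    if tidy.empty:
        return pd.DataFrame()
    wide = tidy.pivot_table(
        index="participant_id",
        columns=["exercise", "feature", "cl"],
        values="value",
        aggfunc="first",
        dropna=False,
    )
    # the dropna=False pivot pads the full exercise x feature product;
    # keep only each task family's own parameters
    valid = [
        (ex, feat, cl)
        for ex, feat, cl in wide.columns
        if feat in (GAIT_FEATURES if ex == "GAIT" else TAPPING_FEATURES)
    ]
    wide = wide[valid]
    wide.columns = ["_".join(c) for c in wide.columns]
    return wide
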