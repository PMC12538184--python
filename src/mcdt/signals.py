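"""Filtering and movement-cycle segmentation of raw inertial trial recordings.

A trial is one continuous 100 Hz stream from a hand- or foot-mounted IMU
while a participant performs one exercise under one cognitive-load
condition.  Tapping exercises (FTAP, THFF, TTHP, HTTP) are segmented on the
angular velocity orthogonal to the movement plane (gyro y); each tap is a
biphasic pattern — a positive opening lobe followed by a negative closing
lobe — delimited by three characteristic times (action start, maximum
amplitude, action end).  The 10 m walking task (GAIT) is segmented in the
sagittal plane into gait cycles with four characteristic times (foot starts
to move, toe-off, heel strike, foot flat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

TAPPING_EXERCISES = ("FTAP", "THFF", "TTHP", "HTTP")
EXERCISES = TAPPING_EXERCISES + ("GAIT",)
CL_LEVELS = ("CL0", "CL1", "CL2", "CL3")

#: Low-pass cutoffs (Hz): tapping movements are faster than gait.
TAPPING_CUTOFF_HZ = 5.0
GAIT_CUTOFF_HZ = 3.0


class ChannelMissingError(KeyError):
    """A required sensor channel is absent from the recording."""


@dataclass
class TrialRecording:
    """One (participant, exercise, cognitive load) sensor stream.

    ``acc`` and ``gyro`` are (n, 3) arrays in m/s^2 and degrees/s with
    columns x, y, z.  ``t`` is seconds, uniform at 1/fs.
    """

    participant_id: str
    exercise: str
    cl: str
    fs: float
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    side: str = "dominant"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        if self.cl not in CL_LEVELS:
            raise ValueError(f"unknown cognitive load {self.cl!r}")
        n = len(self.t)
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError("acc and gyro must be (n, 3) arrays matching t")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs, atol=1e-6):
                raise ValueError("t must be strictly increasing and uniform at 1/fs")

    @property
    def gyro_y(self) -> np.ndarray:
        return self.gyro[:, 1]

    @property
    def n_samples(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class TapCycle:
    """One tap: action start, maximum amplitude, action end (seconds)."""

    t_start: float
    t_peak: float
    t_end: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_peak < self.t_end):
            raise ValueError("tap cycle times must satisfy start < peak < end")


@dataclass(frozen=True)
class GaitCycle:
    """One stride: movement onset, toe-off, heel strike, foot flat (seconds).

    Swing phase is [t_toe_off, t_heel_strike]; stance is the complement
    within the stride.
    """

    t_move: float
    t_toe_off: float
    t_heel_strike: float
    t_flat: float

    def __post_init__(self) -> None:
        times = (self.t_move, self.t_toe_off, self.t_heel_strike, self.t_flat)
        if not all(a < b for a, b in zip(times, times[1:])):
            raise ValueError("gait cycle times must be strictly increasing")


@dataclass(frozen=True)
class TapDetectorSettings:
    """Adaptive-threshold tap detector constants.

    The detection threshold on |gyro y| is max(threshold_floor,
    noise_k * still-phase noise SD); onsets/offsets are threshold
    crossings, with sub-refractory gaps between active regions merged.
    """

    threshold_floor: float = 10.0  # degrees/s
    noise_k: float = 5.0
    #: amplitude-relative term: this fraction of the 95th percentile of
    #: |gyro y| over the movement window, guarding against filter-ring
    #: tails between large-amplitude taps
    relative_frac: float = 0.10
    refractory_s: float = 0.05
    min_duration_s: float = 0.05


@dataclass(frozen=True)
class GaitDetectorSettings:
    """Shank/foot-gyro gait event detector constants (sagittal gyro y)."""

    midswing_min_height: float = 30.0  # degrees/s
    min_stride_s: float = 0.4
    flat_threshold: float = 10.0  # degrees/s: |gyro y| below this is "still"
    flat_hold_s: float = 0.05


def butterworth_lowpass(x: np.ndarray, fs: float, fc: float, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward pass).

    The two-pass design squares the single-pass magnitude response but
    cancels phase lag, so detected event times are not shifted.
    """
    x = np.asarray(x, dtype=float)
    if fc >= fs / 2:
        raise ValueError(f"cutoff {fc} Hz must be below the Nyquist frequency {fs / 2} Hz")
    if x.shape[-1] <= 3 * order:
        raise ValueError("input shorter than 3x the filter order")
    sos = sps.butter(order, fc, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def select_channel(r: TrialRecording):
    """Pick the informative channel(s) for segmentation.

    Tapping tasks use the angular velocity orthogonal to the movement
    plane (gyro y).  GAIT is analysed in the sagittal plane and returns
    the (acc x, acc z, gyro y) triplet.
    """
    if r.gyro.shape[1] < 2 or np.all(np.isnan(r.gyro[:, 1])):
        raise ChannelMissingError("gyro_y")
    if r.exercise == "GAIT":
        if r.acc.shape[1] < 3 or np.all(np.isnan(r.acc[:, 0])) or np.all(np.isnan(r.acc[:, 2])):
            raise ChannelMissingError("acc_x/acc_z")
        return r.acc[:, 0], r.acc[:, 2], r.gyro[:, 1]
    return r.gyro_y


def trim_still_phase(x: np.ndarray, fs: float, still_s: float = 3.0):
    """Split a trial channel into (movement window, initial still segment).

    Every trial starts with a rest phase used for noise and gravity
    estimation; the movement window is everything after it.
    """
    x = np.asarray(x, dtype=float)
    n_still = int(round(still_s * fs))
    if n_still == 0:
        return x, x[:0]
    if x.shape[-1] <= n_still:
        raise ValueError(
            f"trial of {x.shape[-1] / fs:.2f} s is not longer than the {still_s} s still phase"
        )
    return x[..., n_still:], x[..., :n_still]


def _active_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as [start, stop) index pairs."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def segment_taps(
    omega_y: np.ndarray,
    fs: float,
    params: TapDetectorSettings = TapDetectorSettings(),
    noise_sd: float = 0.0,
) -> list[TapCycle]:
    """Detect tap cycles on the filtered movement-window gyro-y channel.

    Threshold crossings of |omega_y| delimit each action; the maximum
    amplitude time is the zero crossing between the positive opening lobe
    and the negative closing lobe.  Partial cycles touching the window
    boundaries are discarded.  Returns an empty list when nothing moves.
    """
    omega_y = np.asarray(omega_y, dtype=float)
    if omega_y.size == 0:
        return []
    thr = max(
        params.threshold_floor,
        params.noise_k * noise_sd,
        params.relative_frac * float(np.percentile(np.abs(omega_y), 95)),
    )
    mask = np.abs(omega_y) > thr
    regions = _active_regions(mask)
    if not regions:
        return []
    # merge regions separated by less than the refractory gap
    gap = int(round(params.refractory_s * fs))
    merged: list[tuple[int, int]] = [regions[0]]
    for start, stop in regions[1:]:
        if start - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    min_len = int(round(params.min_duration_s * fs))
    cycles: list[TapCycle] = []
    for start, stop in merged:
        if start == 0 or stop >= omega_y.size:  # partial cycle at a boundary
            continue
        if stop - start < min_len:
            continue
        seg = omega_y[start:stop]
        i_max = int(np.argmax(seg))
        # first positive-to-negative zero crossing after the opening peak
        sign_change = np.flatnonzero((seg[i_max:-1] > 0) & (seg[i_max + 1:] <= 0))
        i_peak = i_max + (int(sign_change[0]) + 1 if sign_change.size else int(np.argmax(np.abs(seg))))
        i_peak = min(max(i_peak, 1), stop - start - 1)
        cycles.append(
            TapCycle(t_start=start / fs, t_peak=(start + i_peak) / fs, t_end=stop / fs)
        )
    return cycles


def _local_minima(x: np.ndarray) -> np.ndarray:
    idx, _ = sps.find_peaks(-x)
    return idx


def segment_gait(
    r: TrialRecording,
    params: GaitDetectorSettings = GaitDetectorSettings(),
    cutoff_hz: float = GAIT_CUTOFF_HZ,
) -> list[GaitCycle]:
    """Detect gait cycles from the sagittal foot gyro.

    Mid-swing is a positive gyro-y peak of the low-passed signal; toe-off
    is the last negative minimum before mid-swing, heel strike the first
    negative minimum after it.  Movement onset and foot-flat are read
    from the raw channel — where |gyro y| leaves and re-enters the
    stillness band around the swing — because heavy filtering smears the
    edges of stillness.  Returns fewer than two detected strides as an
    empty list with a warning.
    """
    if r.exercise != "GAIT":
        raise ValueError("segment_gait expects a GAIT recording")
    _, _, omega_raw = select_channel(r)
    omega = butterworth_lowpass(omega_raw, r.fs, cutoff_hz)
    fs = r.fs
    peaks, _ = sps.find_peaks(
        omega, height=params.midswing_min_height, distance=max(1, int(params.min_stride_s * fs))
    )
    minima = _local_minima(omega)
    minima = minima[omega[minima] < -params.flat_threshold]
    hold = max(1, int(round(params.flat_hold_s * fs)))
    still = np.abs(omega_raw) < params.flat_threshold
    cycles: list[GaitCycle] = []
    for i, p in enumerate(peaks):
        prev_bound = peaks[i - 1] if i > 0 else 0
        next_bound = peaks[i + 1] if i + 1 < len(peaks) else omega.size
        before = minima[(minima > prev_bound) & (minima < p)]
        after = minima[(minima > p) & (minima < next_bound)]
        if before.size == 0 or after.size == 0:
            continue
        toe_off = int(before[-1])
        heel_strike = int(after[0])
        # movement onset: walk back from toe-off to the end of the still band
        j = toe_off
        while j > prev_bound and not still[j]:
            j -= 1
        t_move = j
        # foot flat: first sample after heel strike still for >= hold samples
        k = heel_strike
        t_flat = None
        while k + hold <= omega.size:
            if still[k : k + hold].all():
                t_flat = k
                break
            k += 1
        if t_flat is None or not (t_move < toe_off < heel_strike < t_flat):
            continue
        cycles.append(
            GaitCycle(
                t_move=t_move / fs,
                t_toe_off=toe_off / fs,
                t_heel_strike=heel_strike / fs,
                t_flat=t_flat / fs,
            )
        )
    if len(cycles) < 2:
        if cycles or peaks.size:
            warnings.warn("fewer than 2 gait strides detected; returning no cycles")
        return []
    return cycles
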