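"""Seeded synthetic cohort: demographics, inertial trial signals, counting responses.

The generator emulates the statistical structure the dual-task analysis
assumes: three diagnostic groups (cognitively healthy older adults OA,
subjective cognitive impairment SCI, mild cognitive impairment MCI) whose
motor output slows, shrinks and becomes more variable as the concurrent
cognitive load rises (serial subtraction by 1/3/7), and whose correct
counting responses decline with both load and diagnosis.  Every draw is
deterministic in (config, seed); per-trial ground truth (cycle times and
counts) is emitted alongside each waveform so segmentation and feature
extraction can be tested for exact parameter recovery.

Waveform models
---------------
Tapping: the movement-plane angular velocity is a train of biphasic pulses
(raised-cosine opening lobe, positive; closing lobe, negative) separated by
a dwell pause, with per-tap log-normal jitter on period and amplitude,
plus Gaussian noise and a slow linear bias drift.  Lobe amplitudes are set
so the integrated angle reaches exactly the configured excursion and
returns to zero at the end of each cycle (zero-velocity-update premise).

Gait: per-stride sagittal angular velocity with a positive mid-swing peak
flanked by negative toe-off and heel-strike lobes; stance is near-zero
angular rate.  Strides tile a 10 m walk at the participant's simulated
velocity, between 3 s standing phases.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import CL_LEVELS, EXERCISES, TAPPING_EXERCISES, TrialRecording

GROUPS = ("OA", "SCI", "MCI")
SEXES = ("F", "M")
EDUCATION_LEVELS = ("primary", "secondary", "superior")

GRAVITY = 9.81  # m/s^2, along sensor z at rest
STILL_S = 3.0  # rest phase preceding (and, for GAIT, following) movement
MOVEMENT_S = 15.0  # tapping movement window
GAIT_DISTANCE_M = 10.0
#: fraction of a tap cycle spent moving (the rest is dwell on contact)
TAP_DUTY = 0.7
#: reaction delay before the first tap of the movement window
TAP_REACTION_S = 0.25
# per-stride template fractions: lobes separated by near-zero gaps so the
# 3 Hz low-pass leaves the event extrema in place; swing (half toe-off
# lobe + gap + swing lobe + gap + half heel-strike lobe) = 0.40 of the
# stride, i.e. a 0.60 stance fraction
GAIT_LOBE_FRAC = 0.12
GAIT_GAP_FRAC = 0.08
#: m/s^2 of movement acceleration per deg/s of angular rate (tapping trials)
ACC_PER_GYRO = 0.002


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class Participant:
    id: str
    group: str
    age: int
    sex: str
    education: str
    fab: int
    mmse: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.education not in EDUCATION_LEVELS:
            raise ConfigurationError(f"unknown education {self.education!r}")
        if not (0 <= self.fab <= 18):
            raise ConfigurationError("FAB must lie in [0, 18]")
        if self.mmse < 24:
            raise ConfigurationError("MMSE below 24 is an exclusion criterion")
        if self.age <= 0:
            raise ConfigurationError("age must be positive")


@dataclass(frozen=True)
class GroupMotorParams:
    """Baseline (no cognitive load) motor characteristics of one group."""

    tap_rate_hz: float
    excursion_deg: float
    variability: float  # log-normal sigma of per-cycle period/amplitude jitter
    stride_time_s: float
    stride_length_m: float


@dataclass(frozen=True)
class TrialTruth:
    """Generator-side ground truth for one trial.

    ``true_cycle_times`` are per-cycle durations (s); ``true_event_times``
    are the characteristic times of each cycle — (start, peak, end) for
    taps, relative to the movement window, and (move, toe-off,
    heel-strike, flat) for gait strides, absolute within the trial.
    """

    true_cycle_times: tuple[float, ...]
    true_tap_count: int
    true_nc: int | None = None
    true_event_times: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.true_tap_count != len(self.true_cycle_times):
            raise ValueError("tap count must equal the number of cycle times")


_DEFAULT_MOTOR = {
    "OA": GroupMotorParams(2.2, 45.0, 0.06, 1.10, 1.25),
    "SCI": GroupMotorParams(2.0, 40.0, 0.09, 1.20, 1.15),
    "MCI": GroupMotorParams(1.8, 34.0, 0.13, 1.30, 1.05),
}
# multiplicative factors at CL0..CL3; smaller = stronger dual-task interference
_DEFAULT_SPEED = {
    "OA": (1.0, 0.96, 0.92, 0.87),
    "SCI": (1.0, 0.93, 0.87, 0.79),
    "MCI": (1.0, 0.88, 0.79, 0.68),
}
_DEFAULT_EXCURSION = {
    "OA": (1.0, 0.97, 0.94, 0.90),
    "SCI": (1.0, 0.95, 0.90, 0.83),
    "MCI": (1.0, 0.91, 0.83, 0.73),
}
# expected correct serial-subtraction answers over 15 s at CL1..CL3
_DEFAULT_RESPONSES = {
    "OA": (14.0, 9.0, 6.0),
    "SCI": (13.0, 8.0, 5.0),
    "MCI": (11.0, 6.0, 3.0),
}
_DEFAULT_AGE = {"OA": (63.0, 6.7), "SCI": (72.0, 10.0), "MCI": (73.0, 9.5)}
_DEFAULT_FAB = {"OA": (16.8, 1.0), "SCI": (15.0, 1.5), "MCI": (13.2, 2.0)}
_DEFAULT_MMSE = {"OA": (29.0, 0.8), "SCI": (28.0, 1.0), "MCI": (26.5, 1.3)}
_DEFAULT_FEMALE = {"OA": 0.60, "SCI": 0.41, "MCI": 0.76}
_DEFAULT_EDUCATION = {
    "OA": (0.02, 0.20, 0.78),
    "SCI": (0.06, 0.23, 0.71),
    "MCI": (0.18, 0.35, 0.47),
}


@dataclass
class CohortConfig:
    """All knobs of the synthetic study, with the study-shaped defaults."""

    n_per_group: dict = field(default_factory=lambda: {"OA": 10, "SCI": 17, "MCI": 17})
    age_params: dict = field(default_factory=lambda: dict(_DEFAULT_AGE))
    fab_params: dict = field(default_factory=lambda: dict(_DEFAULT_FAB))
    mmse_params: dict = field(default_factory=lambda: dict(_DEFAULT_MMSE))
    female_prob: dict = field(default_factory=lambda: dict(_DEFAULT_FEMALE))
    education_probs: dict = field(default_factory=lambda: dict(_DEFAULT_EDUCATION))
    motor_params: dict = field(default_factory=lambda: dict(_DEFAULT_MOTOR))
    speed_factors: dict = field(default_factory=lambda: dict(_DEFAULT_SPEED))
    excursion_factors: dict = field(default_factory=lambda: dict(_DEFAULT_EXCURSION))
    response_rates: dict = field(default_factory=lambda: dict(_DEFAULT_RESPONSES))
    response_cap: int = 20
    gait_midswing_peak: float = 250.0  # deg/s
    gait_negative_peak: float = 100.0  # deg/s (toe-off / heel-strike lobes)
    noise_sd: float = 2.0  # deg/s Gaussian gyro noise
    drift_rate: float = 0.2  # deg/s of bias accumulated per second
    fs: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigurationError("group counts must be >= 0")
        for factors in (self.speed_factors, self.excursion_factors):
            for g in GROUPS:
                f = factors[g]
                if len(f) != 4 or not all(0 < v <= 1 for v in f):
                    raise ConfigurationError("interference factors must lie in (0, 1]")
            for k in range(4):
                if not factors["MCI"][k] <= factors["SCI"][k] <= factors["OA"][k]:
                    raise ConfigurationError(
                        "interference must be ordered MCI <= SCI <= OA at every load"
                    )
        for g in GROUPS:
            if any(r < 0 for r in self.response_rates[g]):
                raise ConfigurationError("response rates must be >= 0")


def _cl_index(cl: str) -> int:
    if cl not in CL_LEVELS:
        raise ConfigurationError(f"unknown cognitive load {cl!r}")
    return CL_LEVELS.index(cl)


def _trial_rng(config: CohortConfig, participant_id: str, exercise: str, cl: str, stream: int = 0):
    """Deterministic per-(participant, exercise, CL) random generator."""
    key = (
        int(config.seed) % (2**31),
        zlib.crc32(participant_id.encode()),
        EXERCISES.index(exercise),
        _cl_index(cl),
        stream,
    )
    return np.random.default_rng(key)


def generate_cohort(config: CohortConfig | None = None) -> list[Participant]:
    """Draw the participant table: group sizes, demographics, FAB/MMSE.

    Ages follow group-specific normal laws matched to the study's
    median/IQR layout; FAB is ordered OA > SCI > MCI in expectation; MMSE
    is truncated at 24 (the exclusion threshold).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(int(config.seed) % (2**31))
    participants: list[Participant] = []
    for group in GROUPS:
        n = int(config.n_per_group.get(group, 0))
        age_loc, age_sd = config.age_params[group]
        fab_loc, fab_sd = config.fab_params[group]
        mmse_loc, mmse_sd = config.mmse_params[group]
        for i in range(n):
            age = int(np.clip(round(rng.normal(age_loc, age_sd)), 50, 95))
            fab = int(np.clip(round(rng.normal(fab_loc, fab_sd)), 0, 18))
            mmse = int(np.clip(round(rng.normal(mmse_loc, mmse_sd)), 24, 30))
            sex = "F" if rng.random() < config.female_prob[group] else "M"
            education = EDUCATION_LEVELS[
                int(rng.choice(3, p=np.asarray(config.education_probs[group]) / np.sum(config.education_probs[group])))
            ]
            participants.append(
                Participant(
                    id=f"{group}{i + 1:02d}",
                    group=group,
                    age=age,
                    sex=sex,
                    education=education,
                    fab=fab,
                    mmse=mmse,
                )
            )
    return participants


def participants_frame(participants: list[Participant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                id=p.id, group=p.group, age=p.age, sex=p.sex,
                education=p.education, fab=p.fab, mmse=p.mmse,
            )
            for p in participants
        ]
    )


def _raised_cosine_lobe(n: int, amplitude: float) -> np.ndarray:
    """sin^2 lobe over n intervals (n+1 samples), zero at both ends.

    Sampled on its exact support the trapezoidal integral equals
    amplitude * n * h / 2 with no discretisation error, which lets the
    generator hit configured excursions exactly.
    """
    i = np.arange(n + 1)
    return amplitude * np.sin(np.pi * i / n) ** 2


def _tapping_waveform(p, exercise, cl, config, rng):
    fs = config.fs
    motor: GroupMotorParams = config.motor_params[p.group]
    k = _cl_index(cl)
    rate = motor.tap_rate_hz * config.speed_factors[p.group][k]
    excursion = motor.excursion_deg * config.excursion_factors[p.group][k]
    n_still = int(round(STILL_S * fs))
    n_move = int(round(MOVEMENT_S * fs))
    n_total = n_still + n_move
    omega = np.zeros(n_total)
    acc_move = np.zeros(n_total)

    cycle_times: list[float] = []
    events: list[tuple[float, float, float]] = []
    pos = n_still + int(round(TAP_REACTION_S * fs))
    while True:
        period = (1.0 / rate) * rng.lognormal(0.0, motor.variability)
        amp_scale = rng.lognormal(0.0, motor.variability)
        n_p = max(8, int(round(period * fs)))
        if pos + n_p > n_total - 2:
            break
        n_d = max(6, int(round(TAP_DUTY * n_p)))
        n_o = n_d // 2
        n_c = n_d - n_o
        exc = excursion * amp_scale
        a_open = 2.0 * exc / (n_o / fs)  # peak deg/s so the lobe integrates to exc
        a_close = 2.0 * exc / (n_c / fs)
        omega[pos : pos + n_o + 1] += _raised_cosine_lobe(n_o, a_open)
        omega[pos + n_o : pos + n_o + n_c + 1] += _raised_cosine_lobe(n_c, -a_close)
        cycle_times.append(n_p / fs)
        events.append(
            ((pos - n_still) / fs, (pos - n_still + n_o) / fs, (pos - n_still + n_d) / fs)
        )
        pos += n_p
    acc_move = ACC_PER_GYRO * omega

    truth = TrialTruth(
        true_cycle_times=tuple(cycle_times),
        true_tap_count=len(cycle_times),
        true_event_times=tuple(events),
    )
    return omega, acc_move, n_total, truth


def _gait_waveform(p, cl, config, rng):
    fs = config.fs
    motor: GroupMotorParams = config.motor_params[p.group]
    k = _cl_index(cl)
    stride_time = motor.stride_time_s / config.speed_factors[p.group][k]
    stride_length = motor.stride_length_m * config.excursion_factors[p.group][k]
    n_strides = int(np.ceil(GAIT_DISTANCE_M / stride_length))
    n_still = int(round(STILL_S * fs))
    n_t = max(20, int(round(stride_time * fs)))
    # per-stride period jitter (half the tapping variability: gait cadence
    # is steadier than self-paced tapping)
    stride_samples = [
        max(20, int(round(n_t * rng.lognormal(0.0, motor.variability * 0.5))))
        for _ in range(n_strides)
    ]
    n_total = n_still + sum(stride_samples) + n_still
    omega = np.zeros(n_total)
    acc_move = np.zeros(n_total)
    cycle_times: list[float] = []
    events: list[tuple[float, float, float, float]] = []
    pos = n_still
    for n_ts in stride_samples:
        n_lobe = max(4, int(round(GAIT_LOBE_FRAC * n_ts)))
        n_gap = max(2, int(round(GAIT_GAP_FRAC * n_ts)))
        q = n_ts - (3 * n_lobe + 2 * n_gap)  # foot-flat dwell opening the stride
        jitter = rng.lognormal(0.0, motor.variability * 0.5)
        i0 = pos + q  # foot starts to move
        p_amp = config.gait_midswing_peak * jitter
        n_amp = config.gait_negative_peak * jitter
        j = i0 + n_lobe + n_gap  # mid-swing lobe start
        k = j + n_lobe + n_gap  # heel-strike lobe start
        omega[i0 : i0 + n_lobe + 1] += _raised_cosine_lobe(n_lobe, -n_amp)
        omega[j : j + n_lobe + 1] += _raised_cosine_lobe(n_lobe, p_amp)
        omega[k : k + n_lobe + 1] += _raised_cosine_lobe(n_lobe, -n_amp)
        acc_move[i0 : k + n_lobe + 1] += 0.003 * np.abs(omega[i0 : k + n_lobe + 1])
        cycle_times.append(n_ts / fs)
        events.append(
            (
                i0 / fs,  # foot starts to move
                (i0 + n_lobe / 2) / fs,  # toe-off (negative minimum)
                (k + n_lobe / 2) / fs,  # heel strike (negative minimum)
                (k + n_lobe) / fs,  # foot flat again
            )
        )
        pos += n_ts
    truth = TrialTruth(
        true_cycle_times=tuple(cycle_times),
        true_tap_count=len(cycle_times),
        true_event_times=tuple(events),
    )
    return omega, acc_move, n_total, truth


def generate_trial(
    p: Participant, exercise: str, cl: str, config: CohortConfig | None = None
) -> tuple[TrialRecording, TrialTruth]:
    """Simulate one trial waveform plus its ground truth.

    Tapping trials are 3 s still + 15 s movement at fs; gait trials are
    3 s standing + enough stride templates to cover 10 m + 3 s standing.
    """
    config = config or CohortConfig()
    config.validate()
    if exercise not in EXERCISES:
        raise ConfigurationError(f"unknown exercise {exercise!r}")
    rng = _trial_rng(config, p.id, exercise, cl)
    if exercise in TAPPING_EXERCISES:
        omega, acc_move, n_total, truth = _tapping_waveform(p, exercise, cl, config, rng)
    else:
        omega, acc_move, n_total, truth = _gait_waveform(p, cl, config, rng)

    fs = config.fs
    t = np.arange(n_total) / fs
    drift = config.drift_rate * t
    gyro = np.zeros((n_total, 3))
    gyro[:, 1] = omega + drift
    if config.noise_sd > 0:
        gyro += rng.normal(0.0, config.noise_sd, size=gyro.shape)
    acc = np.zeros((n_total, 3))
    acc[:, 2] = GRAVITY
    acc[:, 0] = acc_move
    if config.noise_sd > 0:
        acc += rng.normal(0.0, 0.02 * config.noise_sd, size=acc.shape)
    rec = TrialRecording(
        participant_id=p.id, exercise=exercise, cl=cl, fs=fs, t=t, acc=acc, gyro=gyro
    )
    return rec, truth


def generate_responses(
    p: Participant, exercise: str, cl: str, config: CohortConfig | None = None
) -> int:
    """Correct serial-subtraction answers for one dual-task trial.

    Counts are censored-Poisson draws of a group-by-load rate over the
    fixed movement window; counting does not happen at baseline (CL0).
    """
    config = config or CohortConfig()
    config.validate()
    if exercise not in EXERCISES:
        raise ConfigurationError(f"unknown exercise {exercise!r}")
    k = _cl_index(cl)
    if k == 0:
        raise ConfigurationError("correct-response counts exist only under dual task (CL1-CL3)")
    rate = config.response_rates[p.group][k - 1]
    rng = _trial_rng(config, p.id, exercise, cl, stream=1)
    if rate <= 0:
        return 0
    return int(min(rng.poisson(rate), config.response_cap))


def simulate_cohort(config: CohortConfig | None = None, exercises: tuple = EXERCISES):
    """Full synthetic study: participants, all trials with truths, Nc table.

    Returns ``(participants, trials, responses)`` where ``trials`` maps
    (participant_id, exercise, cl) to (TrialRecording, TrialTruth) and
    ``responses`` is a tidy DataFrame (participant_id, exercise, cl, nc).
    """
    config = config or CohortConfig()
    participants = generate_cohort(config)
    trials = {}
    rows = []
    for p in participants:
        for ex in exercises:
            for cl in CL_LEVELS:
                trials[(p.id, ex, cl)] = generate_trial(p, ex, cl, config)
                if cl != "CL0":
                    rows.append(
                        dict(
                            participant_id=p.id,
                            exercise=ex,
                            cl=cl,
                            nc=generate_responses(p, ex, cl, config),
                        )
                    )
    responses = pd.DataFrame(rows, columns=["participant_id", "exercise", "cl", "nc"])
    return participants, trials, responses
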