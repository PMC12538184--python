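"""Kinematic features: closed-form integrals, toy arithmetic, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from mcdt.cohort import generate_trial
from mcdt.kinematics import (
    GAIT_FEATURES,
    TAPPING_FEATURES,
    angular_excursion,
    build_feature_table,
    extract_gait_features,
    extract_tapping_features,
    extract_trial_features,
    feature_table_wide,
    iav,
)
from mcdt.signals import GaitCycle, TapCycle, segment_gait

FS = 100.0


class TestAngularExcursion:
    def test_constant_rate_closed_form(self):
        seg = np.full(51, 90.0)  # 90 deg/s for 0.5 s
        assert angular_excursion(seg, FS) == pytest.approx(45.0, rel=1e-6)

    def test_drift_correction_recovers_biased_cycle(self):
        """A full open-close cycle plus a 2 deg/s bias comes back to the
        unbiased peak angle once linearly detrended."""
        i = np.arange(51)
        lobe = np.sin(np.pi * i / 50) ** 2  # area = 0.25 s x peak
        cycle = np.concatenate([180.0 * lobe, -180.0 * lobe[1:]]) + 2.0  # peak angle 45
        assert angular_excursion(cycle, FS, drift_correct=True) == pytest.approx(45.0, abs=0.5)

    def test_zero_signal(self):
        assert angular_excursion(np.zeros(100), FS) == 0.0

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            angular_excursion(np.array([1.0]), FS)


class TestIav:
    def test_constant_residual(self):
        acc = np.tile([1.0, 0.0, 0.0], (201, 1))  # |a| = 1 for 2 s
        assert iav(acc, FS) == pytest.approx(2.0, rel=1e-6)

    def test_zero_acceleration(self):
        assert iav(np.zeros((100, 3)), FS) == 0.0

    def test_half_sine_pulse(self):
        fs = 10_000.0
        t = np.arange(int(fs) + 1) / fs
        mag = np.sin(np.pi * t)
        assert iav(mag, fs) == pytest.approx(2 / np.pi, rel=1e-6)

    def test_gravity_baseline_removed(self):
        acc = np.tile([0.0, 0.0, 9.81], (300, 1))
        assert iav(acc, FS, still_mean=np.array([0.0, 0.0, 9.81])) == pytest.approx(0.0, abs=1e-12)


def _synthetic_cycle(omega, fs, t0, amp_open, amp_close, half_s):
    n = int(half_s * fs)
    i0 = int(t0 * fs)
    i = np.arange(n + 1)
    omega[i0 : i0 + n + 1] += amp_open * np.sin(np.pi * i / n) ** 2
    omega[i0 + n : i0 + 2 * n + 1] += -amp_close * np.sin(np.pi * i / n) ** 2
    return TapCycle(t_start=t0, t_peak=t0 + half_s, t_end=t0 + 2 * half_s)


class TestTappingFeatures:
    def test_identical_cycles_have_zero_spread(self):
        omega = np.zeros(1500)
        cycles = [
            _synthetic_cycle(omega, FS, 1.0, 200.0, 200.0, 0.2),
            _synthetic_cycle(omega, FS, 3.0, 200.0, 200.0, 0.2),
        ]
        f = extract_tapping_features(cycles, omega, np.zeros((1500, 3)), FS)
        assert f.tap == 2
        assert f.exc_sd == pytest.approx(0.0, abs=1e-9)
        assert f.wo_sd == pytest.approx(0.0, abs=1e-9)
        assert f.wc_sd == pytest.approx(0.0, abs=1e-9)

    def test_toy_means_by_hand(self):
        """Cycles with excursions 30/70 deg and opening peaks 100/140 deg/s
        average to exc 50 and wo 120 (sin^2 lobe of peak A over d seconds
        integrates to A*d/2)."""
        omega = np.zeros(1500)
        c1 = _synthetic_cycle(omega, FS, 1.0, 100.0, 100.0, 0.6)  # 100*0.6/2 = 30
        c2 = _synthetic_cycle(omega, FS, 4.0, 140.0, 140.0, 1.0)  # 140*1.0/2 = 70
        f = extract_tapping_features([c1, c2], omega, np.zeros((1500, 3)), FS)
        assert f.exc == pytest.approx(50.0, rel=1e-3)
        assert f.wo == pytest.approx(120.0, rel=1e-3)
        assert f.wc == pytest.approx(120.0, rel=1e-3)

    def test_empty_cycles_zero_taps_missing_rest(self):
        f = extract_tapping_features([], np.zeros(100), np.zeros((100, 3)), FS)
        assert f.tap == 0
        assert np.isnan(f.exc) and np.isnan(f.wo_sd)

    def test_noiseless_generator_excursion_recovery(self, clean_cfg, clean_cohort):
        p = clean_cohort[0]
        rec, _ = generate_trial(p, "FTAP", "CL0", clean_cfg)
        f = extract_trial_features(rec)
        assert f["exc"] == pytest.approx(clean_cfg.motor_params[p.group].excursion_deg, abs=1.0)

    def test_default_noise_excursion_recovery(self, default_cfg, default_cohort):
        p = default_cohort[0]
        rec, _ = generate_trial(p, "FTAP", "CL0", default_cfg)
        f = extract_trial_features(rec)
        assert f["exc"] == pytest.approx(default_cfg.motor_params[p.group].excursion_deg, rel=0.08)


class TestGaitFeatures:
    def test_velocity_and_stride_length_definitions(self, clean_cfg, clean_cohort):
        rec, truth = generate_trial(clean_cohort[0], "GAIT", "CL0", clean_cfg)
        cycles = segment_gait(rec)
        f = extract_gait_features(cycles, rec)
        assert f.gvel == pytest.approx(10.0 / f.gt, rel=1e-9)
        assert f.gstrd_l == pytest.approx(10.0 / f.gstrd, rel=1e-9)
        assert f.gstrd == truth.true_tap_count

    def test_constant_template_stance_fraction(self, clean_cfg, clean_cohort):
        rec, _ = generate_trial(clean_cohort[0], "GAIT", "CL0", clean_cfg)
        f = extract_gait_features(segment_gait(rec), rec)
        assert f.grs == pytest.approx(0.60, abs=0.01)
        assert f.gstrd_t_sd == pytest.approx(0.0, abs=1e-9)
        assert f.gswt_sd == pytest.approx(0.0, abs=1e-9)

    def test_stride_splits_into_swing_plus_stance(self, default_cfg, default_cohort):
        rec, _ = generate_trial(default_cohort[2], "GAIT", "CL1", default_cfg)
        f = extract_gait_features(segment_gait(rec), rec)
        assert f.gstrd_t == pytest.approx(f.gswt + f.gstt, abs=2.0 / rec.fs + 0.01)

    def test_below_two_cycles_is_missing(self):
        rec, _ = generate_trial_dummy()
        with pytest.warns(UserWarning):
            assert extract_gait_features([], rec) is None


def generate_trial_dummy():
    from mcdt.signals import TrialRecording

    n = 1400
    rec = TrialRecording(
        participant_id="X", exercise="GAIT", cl="CL0", fs=FS,
        t=np.arange(n) / FS, acc=np.zeros((n, 3)), gyro=np.zeros((n, 3)),
    )
    return rec, None


class TestFeatureTable:
    def test_full_protocol_has_180_columns(self, default_cfg, default_cohort):
        # featurised dicts are enough to exercise the table plumbing
        trials = {}
        for p in default_cohort[:2]:
            for ex in ("FTAP", "THFF", "TTHP", "HTTP"):
                for cl in ("CL0", "CL1", "CL2", "CL3"):
                    trials[(p.id, ex, cl)] = {f: 1.0 for f in TAPPING_FEATURES}
            for cl in ("CL0", "CL1", "CL2", "CL3"):
                trials[(p.id, "GAIT", cl)] = {f: 1.0 for f in GAIT_FEATURES}
        wide = feature_table_wide(build_feature_table(trials))
        assert wide.shape[1] == 180

    def test_tapping_only_32_columns_per_cl(self, default_cohort):
        trials = {}
        for p in default_cohort[:2]:
            for ex in ("FTAP", "THFF", "TTHP", "HTTP"):
                trials[(p.id, ex, "CL0")] = {f: 1.0 for f in TAPPING_FEATURES}
        wide = feature_table_wide(build_feature_table(trials))
        assert wide.shape[1] == 32

    def test_empty_trials_empty_table(self):
        assert build_feature_table({}).empty

    def test_duplicate_trial_rejected(self):
        items = [
            (("P1", "FTAP", "CL0"), {"tap": 1.0}),
            (("P1", "FTAP", "CL0"), {"tap": 2.0}),
        ]
        with pytest.raises(ValueError):
            build_feature_table(items)

    def test_feature_count_identity(self):
        assert len(TAPPING_FEATURES) * 4 + len(GAIT_FEATURES) == 45
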