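import numpy as np
import pytest

from mcdt.cohort import CohortConfig, GroupMotorParams, generate_cohort


def noiseless_config(seed: int = 3, variability: float = 0.0) -> CohortConfig:
    """Deterministic-waveform study config: no noise, no drift, no jitter."""
    cfg = CohortConfig(seed=seed, noise_sd=0.0, drift_rate=0.0)
    for g in cfg.motor_params:
        m = cfg.motor_params[g]
        cfg.motor_params[g] = GroupMotorParams(
            m.tap_rate_hz, m.excursion_deg, variability, m.stride_time_s, m.stride_length_m
        )
    return cfg


@pytest.fixture(scope="session")
def clean_cfg():
    return noiseless_config()


@pytest.fixture(scope="session")
def clean_cohort(clean_cfg):
    return generate_cohort(clean_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    return generate_cohort(default_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
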