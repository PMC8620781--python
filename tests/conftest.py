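import numpy as np
import pytest

import gaitmode as gm


@pytest.fixture(scope="session")
def clean_config():
    """Small noise-free config: 5 level-walking strides, no jitter."""
    return gm.SimulationConfig(
        seed=7,
        n_subjects=1,
        n_trials_per_subject=1,
        mode_sequence=["W"] * 5,
        stride_jitter=0.0,
        noise_sd=0.0,
        subject_amp_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    return gm.generate_trial(clean_config, 0, 0)


@pytest.fixture(scope="session")
def noisy_trial():
    cfg = gm.SimulationConfig(seed=3, n_subjects=1, n_trials_per_subject=1)
    return gm.generate_trial(cfg, 0, 0)


@pytest.fixture(scope="session")
def processed_trial(noisy_trial):
    stats = gm.fit_normalizer([gm.conditioned_imu(noisy_trial)], gm.IMU_CHANNELS)
    return gm.preprocess_trial(noisy_trial, stats)


def sinusoid_amplitude(x: np.ndarray, f_hz: float, rate_hz: float) -> float:
    """Amplitude of the f_hz component over the central portion of x.

    The window is trimmed to an integer number of periods so the
    quadrature projection is unbiased even at low frequencies.
    """
    n = len(x)
    start = int(0.2 * n)
    length = int(0.6 * n)
    period = rate_hz / f_hz
    length = int(np.floor(length / period) * period)
    if length < 1:
        raise ValueError("signal too short for one period of f_hz")
    sl = slice(start, start + length)
    xs = x[sl]
    t = np.arange(n)[sl] / rate_hz
    s, c = np.sin(2 * np.pi * f_hz * t), np.cos(2 * np.pi * f_hz * t)
    return 2.0 * np.hypot(xs @ s, xs @ c) / length
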