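"""Signal conditioning: EMG envelope filtering, IMU low-pass filtering,
resampling to a common rate, and Z-score normalization.

All filters are zero-phase (forward-backward) 4th-order Butterworth
designs: EMG is rectified, high-passed at 20 Hz and low-passed at
200 Hz; IMU channels are low-passed at 20 Hz.  IMU data are then
linearly interpolated onto the EMG time grid and standardized per
channel with statistics fitted on training trials only.

Note the conditioned EMG "envelope" may go negative: the 20 Hz
high-pass removes the DC/low-frequency content of the rectified signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

_FILTER_ORDER = 4
_EMG_HP_HZ = 20.0
_EMG_LP_HZ = 200.0
_IMU_LP_HZ = 20.0
# Forward-backward filtering with reflective ("even") padding, 3x the
# filter order, keeps edge transients short and the phase response zero.
_PAD = dict(padtype="even", padlen=3 * _FILTER_ORDER)


def zero_phase_filter(
    x: np.ndarray, cutoff_hz: float, btype: str, rate_hz: float
) -> np.ndarray:
    """One forward-backward 4th-order Butterworth pass (low- or high-pass)."""
    b, a = butter(_FILTER_ORDER, cutoff_hz, btype=btype, fs=rate_hz)
    return filtfilt(b, a, x, axis=-1, **_PAD)


_filtfilt = zero_phase_filter


def condition_emg(raw: np.ndarray, rate_hz: float) -> np.ndarray:
    """Rectify, high-pass at 20 Hz, low-pass at 200 Hz (zero-phase)."""
    if rate_hz < 2 * _EMG_LP_HZ:
        raise ValueError(
            f"EMG rate {rate_hz} Hz is below the Nyquist bound for the "
            f"{_EMG_LP_HZ} Hz low-pass cutoff"
        )
    x = np.abs(np.asarray(raw, dtype=float))
    x = _filtfilt(x, _EMG_HP_HZ, "highpass", rate_hz)
    return _filtfilt(x, _EMG_LP_HZ, "lowpass", rate_hz)


def condition_imu(raw: np.ndarray, rate_hz: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass at 20 Hz per channel."""
    if rate_hz < 2 * _IMU_LP_HZ:
        raise ValueError(
            f"IMU rate {rate_hz} Hz is below the Nyquist bound for the "
            f"{_IMU_LP_HZ} Hz low-pass cutoff"
        )
    return _filtfilt(np.asarray(raw, dtype=float), _IMU_LP_HZ, "lowpass", rate_hz)


def butter_response_sq(
    f_hz: float, cutoff_hz: float, btype: str, rate_hz: Optional[float] = None
) -> float:
    """Analytic |H(f)|^2 of one forward-backward 4th-order Butterworth pass.

    For order n the magnitude of a single pass is
    |H|^2 = 1 / (1 + (f/fc)^(2n)) (low-pass) or 1 / (1 + (fc/f)^(2n))
    (high-pass); forward-backward filtering applies the squared
    magnitude.  When ``rate_hz`` is given, frequencies are prewarped by
    the bilinear transform (f -> tan(pi f / fs) fs / pi) so the formula
    describes the digital filter exactly rather than the analog
    prototype; near the cutoff and far below Nyquist the two coincide.
    """
    n = _FILTER_ORDER
    if rate_hz is not None:
        warp = lambda f: np.tan(np.pi * f / rate_hz)  # noqa: E731
        f_hz, cutoff_hz = warp(f_hz), warp(cutoff_hz)
    if btype == "lowpass":
        return 1.0 / (1.0 + (f_hz / cutoff_hz) ** (2 * n))
    if btype == "highpass":
        return 1.0 / (1.0 + (cutoff_hz / f_hz) ** (2 * n))
    raise ValueError(f"unknown filter type {btype!r}")


def resample(signal: np.ndarray, from_rate_hz: float, to_rate_hz: float) -> np.ndarray:
    """Linear interpolation onto a uniform grid spanning the same duration.

    The target grid has ``round(duration * to_rate) + 1`` points
    including both endpoints, so the first and last samples are
    preserved exactly.
    """
    if from_rate_hz <= 0 or to_rate_hz <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(signal, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    n = x.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples to resample")
    duration = (n - 1) / from_rate_hz
    n_out = int(round(duration * to_rate_hz)) + 1
    t_in = np.arange(n) / from_rate_hz
    t_out = np.linspace(0.0, duration, n_out)
    out = np.empty((x.shape[0], n_out))
    for c in range(x.shape[0]):
        out[c] = np.interp(t_out, t_in, x[c])
    return out[0] if squeeze else out


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizerStats:
    """Per-IMU-channel mean and population standard deviation."""

    mean: np.ndarray  # (n_channels,)
    std: np.ndarray   # (n_channels,)
    channel_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if np.any(self.std <= 0):
            bad = int(np.argmin(self.std))
            name = (
                self.channel_names[bad]
                if self.channel_names is not None
                else f"channel {bad}"
            )
            raise ValueError(f"non-positive standard deviation for {name}")


def fit_normalizer(
    training_imu: Sequence[np.ndarray],
    channel_names: Optional[Sequence[str]] = None,
) -> NormalizerStats:
    """Per-channel mean/std pooled over all training samples."""
    pooled = np.concatenate([np.asarray(x, dtype=float) for x in training_imu], axis=1)
    if pooled.shape[1] < 2:
        raise ValueError("need at least 2 pooled samples per channel")
    mean = pooled.mean(axis=1)
    std = pooled.std(axis=1)  # population std
    if np.any(std <= 0):
        bad = int(np.argmin(std))
        name = channel_names[bad] if channel_names is not None else f"channel {bad}"
        raise ValueError(f"zero-variance channel: {name}")
    return NormalizerStats(
        mean=mean,
        std=std,
        channel_names=tuple(channel_names) if channel_names is not None else None,
    )


def zscore(signal: np.ndarray, stats: NormalizerStats) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    return (x - stats.mean[:, None]) / stats.std[:, None]


# --------------------------------------------------------------------------
# Trial-level composition
# --------------------------------------------------------------------------


@dataclass
class ProcessedTrial:
    """Conditioned, rate-aligned, normalized channels plus metadata."""

    subject_id: int
    trial_id: int
    emg_env: np.ndarray   # (20, n) at rate_hz
    imu_norm: np.ndarray  # (42, n) at rate_hz
    rate_hz: float
    mode_timeline: List[Tuple[str, float, float]]
    true_events: List
    stats: Optional[NormalizerStats] = None


def conditioned_imu(trial) -> np.ndarray:
    """Filtered IMU channels resampled to the EMG rate (pre-normalization).

    This is the stream normalizer statistics are fitted on.
    """
    filtered = condition_imu(trial.imu, trial.imu_rate_hz)
    return resample(filtered, trial.imu_rate_hz, trial.emg_rate_hz)


def preprocess_trial(trial, stats: NormalizerStats) -> ProcessedTrial:
    """Full conditioning chain with externally supplied (training-fold) stats."""
    trial.validate()
    emg_env = condition_emg(trial.emg, trial.emg_rate_hz)
    imu = zscore(conditioned_imu(trial), stats)
    n = min(emg_env.shape[1], imu.shape[1])
    return ProcessedTrial(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        emg_env=emg_env[:, :n],
        imu_norm=imu[:, :n],
        rate_hz=trial.emg_rate_hz,
        mode_timeline=list(trial.mode_timeline),
        true_events=list(trial.true_events),
        stats=stats,
    )
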