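"""Synthetic wearable-sensor gait trials.

Generates multi-rate EMG / IMU / foot-switch recordings with the channel
layout of a lower-limb locomotion experiment: 20 surface-EMG channels at
2000 Hz, 7 IMUs x 6 DOF (tri-axial linear acceleration and angular
velocity) at 286 Hz, and 4 binary foot-switch channels at 2000 Hz that
define ground-truth foot-contact (FC) and toe-off (TO) instants.

Each trial is a sequence of strides; every stride belongs to one
locomotion mode (level walking W, ramp ascent RA1-RA3 at 4/8/12 degrees,
ramp descent RD1-RD3, stair ascent/descent SA/SD, obstacle O, stop ST).
Per (mode, channel) the waveform over one stride is a baseline plus a
small number of Gaussian bumps in stride phase; sharp, mode-independent
marker bumps at phase 0 (FC) and at the stance fraction (TO) give the
inertial channels the local extrema that a sample-wise event classifier
can learn. An anticipatory component that ramps up through stance and
depends on the *next* stride's mode models the anticipatory gait
adjustment that makes mode transitions predictable before toe-off.

EMG channels are generated directly as non-negative activation envelopes
(the post-rectification analog of interference EMG); plantarflexor
envelope amplitude increases with ramp-ascent incline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .event_detector import GaitEvent

# --------------------------------------------------------------------------
# Channel layout
# --------------------------------------------------------------------------

EMG_CHANNELS: Tuple[str, ...] = (
    # right limb, 11 muscles
    "gluteus_maximus_r",
    "gluteus_medius_r",
    "rectus_femoris_r",
    "vastus_medialis_r",
    "vastus_lateralis_r",
    "semitendinosus_r",
    "tibialis_anterior_r",
    "gastrocnemius_medialis_r",
    "gastrocnemius_lateralis_r",
    "soleus_r",
    "peroneus_longus_r",
    # left limb, 9 muscles
    "gluteus_medius_l",
    "rectus_femoris_l",
    "vastus_medialis_l",
    "vastus_lateralis_l",
    "semitendinosus_l",
    "tibialis_anterior_l",
    "gastrocnemius_medialis_l",
    "soleus_l",
    "peroneus_longus_l",
)

PLANTARFLEXOR_CHANNELS: Tuple[str, ...] = (
    "gastrocnemius_medialis_r",
    "gastrocnemius_lateralis_r",
    "soleus_r",
    "gastrocnemius_medialis_l",
    "soleus_l",
)

IMU_SENSORS: Tuple[str, ...] = (
    "pelvis",
    "thigh_r",
    "thigh_l",
    "shank_r",
    "shank_l",
    "foot_r",
    "foot_l",
)
IMU_DOFS: Tuple[str, ...] = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
IMU_CHANNELS: Tuple[str, ...] = tuple(
    f"{sensor}_{dof}" for sensor in IMU_SENSORS for dof in IMU_DOFS
)

FOOTSWITCH_CHANNELS: Tuple[str, ...] = (
    "heel_left",
    "heel_right",
    "toe_left",
    "toe_right",
)

N_EMG = len(EMG_CHANNELS)       # 20
N_IMU = len(IMU_CHANNELS)       # 42
N_FOOTSWITCH = len(FOOTSWITCH_CHANNELS)  # 4

MODES: Tuple[str, ...] = (
    "W", "SA", "SD", "O", "ST",
    "RA1", "RA2", "RA3",
    "RD1", "RD2", "RD3",
)

#: Incline level (1..3) of ramp modes, 0 otherwise.
_RAMP_LEVEL = {"RA1": 1, "RA2": 2, "RA3": 3, "RD1": 1, "RD2": 2, "RD3": 3}


def _channel_side(name: str) -> Optional[str]:
    if name.endswith("_r") or "_r_" in name or name.endswith("right"):
        return "right"
    if name.endswith("_l") or "_l_" in name or name.endswith("left"):
        return "left"
    return None


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


def default_route(incline_level: int) -> List[str]:
    """A per-trial stride/mode sequence that walks every transition family.

    The route mimics a lab circuit: level walking, a ramp ascent bout,
    ramp descent, a stair ascent step, a stair descent step, an obstacle
    crossing and a final stop.  ``incline_level`` (1..3) selects the ramp
    incline so a rotation of routes covers RA1-RA3 / RD1-RD3.
    """
    if incline_level not in (1, 2, 3):
        raise ValueError(f"incline_level must be 1, 2 or 3, got {incline_level}")
    ra = f"RA{incline_level}"
    rd = f"RD{incline_level}"
    return ["W", "W", ra, ra, "W", rd, rd, "W", "SA", "W", "SD", "W", "O", "W", "ST"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for synthetic trial generation.

    ``mode_sequence = None`` selects the built-in route rotation: trial
    ``t`` of every subject uses :func:`default_route` with incline level
    ``t % 3 + 1``, so each subject's trial set covers all three inclines.
    """

    seed: int = 0
    n_subjects: int = 4
    n_trials_per_subject: int = 10
    mode_sequence: Optional[Sequence[str]] = None
    stride_duration_s: float = 1.1
    stride_jitter: float = 0.05           # log-normal sd of the duration factor
    stance_fraction: float = 0.6
    noise_sd: float = 0.25                # additive Gaussian noise, signal units
    emg_rate_hz: float = 2000.0
    imu_rate_hz: float = 286.0
    subject_amp_sd: float = 0.10          # per-subject log-normal amplitude factor
    lead_in_s: float = 0.3                # pre-roll before the first FC
    tail_s: float = 0.3                   # post-roll after the last stride
    incline_angles_deg: Dict[str, float] = field(
        default_factory=lambda: {"A1": 4.0, "A2": 8.0, "A3": 12.0}
    )

    def validate(self) -> None:
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.emg_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_subjects <= 0 or self.n_trials_per_subject <= 0:
            raise ValueError("subject and trial counts must be positive")
        if self.stride_duration_s <= 0:
            raise ValueError("stride_duration_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.mode_sequence is not None:
            if len(self.mode_sequence) == 0:
                raise ValueError("mode_sequence must be nonempty")
            for code in self.mode_sequence:
                if code not in MODES:
                    raise ValueError(f"unknown mode code: {code!r}")

    def route_for_trial(self, trial_id: int) -> List[str]:
        if self.mode_sequence is not None:
            return list(self.mode_sequence)
        return default_route(trial_id % 3 + 1)


# --------------------------------------------------------------------------
# Mode signatures
# --------------------------------------------------------------------------

# Sharp, mode-independent marker bumps that anchor the gait events in the
# inertial channels.  (channel, amplitude); FC markers sit at phase 0, TO
# markers at phase = stance_fraction.  Width in stride-phase units.
_EVENT_BUMP_WIDTH = 0.012
_FC_MARKERS = {"foot_{s}_acc_z": 2.8, "shank_{s}_acc_x": 2.2, "thigh_{s}_acc_z": 1.6}
_TO_MARKERS = {"shank_{s}_gyr_z": -2.8, "foot_{s}_gyr_y": -2.2, "thigh_{s}_gyr_x": -1.6}

_ANTICIPATION_START = 0.15   # stride phase where the anticipatory ramp begins


@dataclass(frozen=True)
class ModeSignature:
    """Per-mode waveform parameters.

    ``imu_bumps[channel]`` / ``emg_bumps[channel]`` are lists of
    ``(amplitude, center_phase, width)`` Gaussian bumps evaluated with
    wrap-around phase distance; ``imu_baseline`` is a per-channel offset.
    ``anticipation_imu`` / ``anticipation_emg`` are the per-channel
    amplitudes contributed to a stride whose *next* stride is this mode.
    """

    mode: str
    imu_baseline: Dict[str, float]
    imu_bumps: Dict[str, List[Tuple[float, float, float]]]
    emg_bumps: Dict[str, List[Tuple[float, float, float]]]
    anticipation_imu: Dict[str, float]
    anticipation_emg: Dict[str, float]


def _signature_rng(mode: str) -> np.random.Generator:
    # Per-mode parameters are a fixed property of the simulator, not of any
    # particular trial, so they are seeded by the mode's position only.
    return np.random.default_rng(np.random.SeedSequence([424242, MODES.index(mode)]))


def _build_signature(mode: str) -> ModeSignature:
    # Ramp modes at different inclines share the EMG burst layout of their
    # family and differ by an incline-dependent gain, which makes the
    # plantarflexor amplitude strictly increasing with incline by
    # construction; their IMU bumps are drawn per mode (separability).
    family = mode[:2] if mode in _RAMP_LEVEL else mode
    rng_emg = np.random.default_rng(
        np.random.SeedSequence([979797, hash_mode_family(family)])
    )
    rng_imu = _signature_rng(mode)
    level = _RAMP_LEVEL.get(mode, 0)
    ascent = mode.startswith("RA")

    imu_baseline: Dict[str, float] = {}
    imu_bumps: Dict[str, List[Tuple[float, float, float]]] = {}
    for ch in IMU_CHANNELS:
        imu_baseline[ch] = float(rng_imu.uniform(-0.3, 0.3))
        n = int(rng_imu.integers(1, 4))
        bumps = []
        for _ in range(n):
            amp = float(rng_imu.uniform(-1.2, 1.2))
            center = float(rng_imu.uniform(0.0, 1.0))
            width = float(rng_imu.uniform(0.06, 0.20))
            bumps.append((amp, center, width))
        imu_bumps[ch] = bumps

    emg_bumps: Dict[str, List[Tuple[float, float, float]]] = {}
    for ch in EMG_CHANNELS:
        n = int(rng_emg.integers(1, 3))
        bumps = []
        for _ in range(n):
            amp = float(rng_emg.uniform(0.3, 1.0))
            center = float(rng_emg.uniform(0.0, 1.0))
            width = float(rng_emg.uniform(0.08, 0.20))
            if level:
                if ascent and ch in PLANTARFLEXOR_CHANNELS:
                    amp *= 1.0 + 0.30 * level   # higher activation at steeper incline
                else:
                    amp *= 1.0 + 0.08 * level
            bumps.append((amp, center, width))
        emg_bumps[ch] = bumps

    rng_ant = np.random.default_rng(
        np.random.SeedSequence([565656, MODES.index(mode)])
    )
    anticipation_imu = {
        ch: float(rng_ant.uniform(-0.9, 0.9)) for ch in IMU_CHANNELS
    }
    rng_ant_emg = np.random.default_rng(
        np.random.SeedSequence([565657, hash_mode_family(family)])
    )
    anticipation_emg = {}
    for ch in EMG_CHANNELS:
        amp = float(rng_ant_emg.uniform(0.0, 0.6))
        # anticipating a steeper ascent raises plantarflexor preparation too,
        # keeping the incline monotonicity structural rather than incidental
        if level and ascent and ch in PLANTARFLEXOR_CHANNELS:
            amp *= 1.0 + 0.30 * level
        elif level:
            amp *= 1.0 + 0.05 * level
        anticipation_emg[ch] = amp
    return ModeSignature(
        mode=mode,
        imu_baseline=imu_baseline,
        imu_bumps=imu_bumps,
        emg_bumps=emg_bumps,
        anticipation_imu=anticipation_imu,
        anticipation_emg=anticipation_emg,
    )


def hash_mode_family(family: str) -> int:
    """Stable small integer for a mode-family string (no builtin hash)."""
    return sum((i + 1) * ord(c) for i, c in enumerate(family))


_SIGNATURES: Dict[str, ModeSignature] = {}


def mode_signature(mode: str) -> ModeSignature:
    if mode not in MODES:
        raise ValueError(f"unknown mode code: {mode!r}")
    if mode not in _SIGNATURES:
        _SIGNATURES[mode] = _build_signature(mode)
    return _SIGNATURES[mode]


def _wrapped_gauss(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    d = np.abs(phase - center)
    d = np.minimum(d, 1.0 - d)
    return np.exp(-0.5 * (d / width) ** 2)


def _anticipation_ramp(phase: np.ndarray, stance_fraction: float) -> np.ndarray:
    ramp = (phase - _ANTICIPATION_START) / (stance_fraction - _ANTICIPATION_START)
    return np.clip(ramp, 0.0, 1.0)


def template_waveform(
    mode: str,
    channel: str,
    phase: np.ndarray,
    stance_fraction: float = 0.6,
    next_mode: Optional[str] = None,
    side_phase_shift: bool = True,
) -> np.ndarray:
    """Noise-free waveform of one channel over stride phase in [0, 1).

    ``next_mode`` adds the anticipatory component of the upcoming mode
    (defaults to ``mode``, i.e. steady-state locomotion).  Left-side
    channels are evaluated half a stride out of phase with the right
    side when ``side_phase_shift`` is set.
    """
    sig = mode_signature(mode)
    nxt = mode_signature(next_mode if next_mode is not None else mode)
    phase = np.asarray(phase, dtype=float)
    p = np.mod(phase, 1.0)
    if side_phase_shift and _channel_side(channel) == "left":
        p = np.mod(p + 0.5, 1.0)

    if channel in IMU_CHANNELS:
        out = np.full_like(p, sig.imu_baseline[channel])
        for amp, center, width in sig.imu_bumps[channel]:
            out += amp * _wrapped_gauss(p, center, width)
        side = _channel_side(channel)
        if side is not None:
            s = side[0]  # "r" / "l"
            for pattern, amp in _FC_MARKERS.items():
                if pattern.format(s=s) == channel:
                    out += amp * _wrapped_gauss(p, 0.0, _EVENT_BUMP_WIDTH)
            for pattern, amp in _TO_MARKERS.items():
                if pattern.format(s=s) == channel:
                    out += amp * _wrapped_gauss(p, stance_fraction, _EVENT_BUMP_WIDTH)
        # Anticipation ramps in the un-shifted (right-stride) phase, since
        # the upcoming transition is anchored to the lead side's stance.
        out += nxt.anticipation_imu[channel] * _anticipation_ramp(
            np.mod(phase, 1.0), stance_fraction
        )
        return out

    if channel in EMG_CHANNELS:
        out = np.full_like(p, 0.05)
        for amp, center, width in sig.emg_bumps[channel]:
            out += amp * _wrapped_gauss(p, center, width)
        out += nxt.anticipation_emg[channel] * _anticipation_ramp(
            np.mod(phase, 1.0), stance_fraction
        )
        return out

    raise ValueError(f"unknown channel: {channel!r}")


def mode_separation(stance_fraction: float = 0.6, n_phase: int = 200) -> float:
    """Minimum pairwise L2 distance between per-mode mean feature vectors.

    The feature vector of a mode is the stride-mean of every EMG and IMU
    channel template (steady state, no anticipation mismatch).  A strictly
    positive value is the noise-free separability margin the classifiers
    rely on.
    """
    phase = (np.arange(n_phase) + 0.5) / n_phase
    means = []
    for mode in MODES:
        v = [
            template_waveform(mode, ch, phase, stance_fraction).mean()
            for ch in EMG_CHANNELS + IMU_CHANNELS
        ]
        means.append(np.asarray(v))
    dmin = math.inf
    for i in range(len(MODES)):
        for j in range(i + 1, len(MODES)):
            dmin = min(dmin, float(np.linalg.norm(means[i] - means[j])))
    return dmin


# --------------------------------------------------------------------------
# Trial container
# --------------------------------------------------------------------------


@dataclass
class SensorTrial:
    """One recording: raw multi-rate channel bundle plus ground truth."""

    subject_id: int
    trial_id: int
    emg: np.ndarray          # (20, n_emg) at emg_rate_hz, arbitrary units
    imu: np.ndarray          # (42, n_imu) at imu_rate_hz
    footswitch: np.ndarray   # (4, n_emg) binary, at emg_rate_hz
    emg_rate_hz: float
    imu_rate_hz: float
    duration_s: float
    mode_timeline: List[Tuple[str, float, float]]  # (mode, start_s, end_s)
    true_events: List[GaitEvent]

    def validate(self) -> None:
        if self.emg.shape[0] != N_EMG:
            raise ValueError(f"expected {N_EMG} EMG channels, got {self.emg.shape[0]}")
        if self.imu.shape[0] != N_IMU:
            raise ValueError(f"expected {N_IMU} IMU channels, got {self.imu.shape[0]}")
        if self.footswitch.shape[0] != N_FOOTSWITCH:
            raise ValueError(
                f"expected {N_FOOTSWITCH} foot-switch channels, "
                f"got {self.footswitch.shape[0]}"
            )
        prev_end = 0.0
        for mode, start, end in self.mode_timeline:
            if mode not in MODES:
                raise ValueError(f"unknown mode code: {mode!r}")
            if not math.isclose(start, prev_end, abs_tol=1e-9) or end <= start:
                raise ValueError("mode_timeline must be contiguous and ordered")
            prev_end = end
        _check_alternation(self.true_events)

    def events_for_side(self, side: str) -> List[GaitEvent]:
        return [e for e in self.true_events if e.side == side]


def _check_alternation(events: Sequence[GaitEvent]) -> None:
    for side in ("left", "right"):
        kinds = [e.kind for e in events if e.side == side]
        times = [e.time_s for e in events if e.side == side]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"{side} events are not strictly increasing in time")
        for i, k in enumerate(kinds):
            expected = "FC" if i % 2 == 0 else "TO"
            if k != expected:
                raise ValueError(f"{side} events do not alternate FC/TO")


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _subject_factor(config: SimulationConfig, subject_id: int) -> float:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 101, int(subject_id)])
    )
    return float(rng.lognormal(mean=0.0, sigma=config.subject_amp_sd))


def generate_trial(
    config: SimulationConfig, subject_id: int, trial_id: int
) -> SensorTrial:
    """Generate one synthetic trial.

    Deterministic in ``(config.seed, subject_id, trial_id)``: the same
    arguments always produce byte-identical arrays.
    """
    config.validate()
    route = config.route_for_trial(trial_id)
    for code in route:
        if code not in MODES:
            raise ValueError(f"unknown mode code: {code!r}")

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 202, int(subject_id), int(trial_id)])
    )
    subj = _subject_factor(config, subject_id)
    n_strides = len(route)

    durations = config.stride_duration_s * rng.lognormal(
        mean=0.0, sigma=config.stride_jitter, size=n_strides
    )
    starts = config.lead_in_s + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    duration_s = float(starts[-1] + durations[-1] + config.tail_s)

    # --- ground-truth events -------------------------------------------------
    events: List[GaitEvent] = []
    for i in range(n_strides):
        fc = float(starts[i])
        to = float(starts[i] + config.stance_fraction * durations[i])
        events.append(GaitEvent("FC", "right", fc))
        events.append(GaitEvent("TO", "right", to))
    left: List[GaitEvent] = []
    for i in range(n_strides):
        fc = float(starts[i] + 0.5 * durations[i])
        to = float(fc + config.stance_fraction * durations[i])
        if to >= duration_s:
            break
        left.append(GaitEvent("FC", "left", fc))
        left.append(GaitEvent("TO", "left", to))
    events.extend(left)
    events.sort(key=lambda e: (e.time_s, e.side, e.kind))

    # --- mode timeline (merge consecutive identical modes) -------------------
    timeline: List[Tuple[str, float, float]] = []
    seg_start = 0.0
    for i in range(n_strides):
        seg_end = duration_s if i == n_strides - 1 else float(starts[i + 1])
        if timeline and timeline[-1][0] == route[i]:
            timeline[-1] = (route[i], timeline[-1][1], seg_end)
        else:
            timeline.append((route[i], seg_start, seg_end))
        seg_start = seg_end

    # --- signals -------------------------------------------------------------
    def synthesize(rate_hz: float, channels: Sequence[str]) -> np.ndarray:
        n = int(round(duration_s * rate_hz)) + 1
        t = np.arange(n) / rate_hz
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_strides - 1)
        phase = (t - starts[idx]) / durations[idx]  # may be <0 (lead-in) / >1 (tail)
        out = np.empty((len(channels), n))
        for s in range(n_strides):
            sel = idx == s
            if not np.any(sel):
                continue
            mode = route[s]
            nxt = route[s + 1] if s + 1 < n_strides else route[s]
            ph = phase[sel]
            for c, ch in enumerate(channels):
                out[c, sel] = template_waveform(
                    mode, ch, ph, config.stance_fraction, next_mode=nxt
                )
        return out * subj

    emg = synthesize(config.emg_rate_hz, EMG_CHANNELS)
    imu = synthesize(config.imu_rate_hz, IMU_CHANNELS)

    if config.noise_sd > 0:
        emg = emg + rng.normal(0.0, config.noise_sd, size=emg.shape)
        imu = imu + rng.normal(0.0, config.noise_sd, size=imu.shape)
    emg = np.maximum(emg, 0.0)  # envelope analog: non-negative

    footswitch = footswitch_from_events(events, duration_s, config.emg_rate_hz)

    trial = SensorTrial(
        subject_id=int(subject_id),
        trial_id=int(trial_id),
        emg=emg,
        imu=imu,
        footswitch=footswitch,
        emg_rate_hz=config.emg_rate_hz,
        imu_rate_hz=config.imu_rate_hz,
        duration_s=duration_s,
        mode_timeline=timeline,
        true_events=events,
    )
    trial.validate()
    return trial


def generate_dataset(config: SimulationConfig) -> List[SensorTrial]:
    """Generate ``n_subjects x n_trials_per_subject`` trials, seeded."""
    config.validate()
    trials = []
    for s in range(config.n_subjects):
        for t in range(config.n_trials_per_subject):
            trials.append(generate_trial(config, s, t))
    return trials


def footswitch_from_events(
    events: Sequence[GaitEvent], duration_s: float, rate_hz: float
) -> np.ndarray:
    """Binary foot-switch channels from an FC/TO event sequence.

    Each side's heel and toe channels are 1 on every [FC, TO) stance
    interval of that side (rising edge at sample ``round(FC * rate)``).
    """
    _check_alternation(list(events))
    n = int(round(duration_s * rate_hz)) + 1
    out = np.zeros((N_FOOTSWITCH, n))
    channel_of_side = {"left": (0, 2), "right": (1, 3)}
    for side, chans in channel_of_side.items():
        side_events = sorted(
            (e for e in events if e.side == side), key=lambda e: e.time_s
        )
        for fc, to in zip(side_events[0::2], side_events[1::2]):
            i0 = int(round(fc.time_s * rate_hz))
            i1 = int(round(to.time_s * rate_hz))
            i0, i1 = max(i0, 0), min(i1, n)
            for c in chans:
                out[c, i0:i1] = 1.0
    return out
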