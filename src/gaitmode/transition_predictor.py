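"""Second-stage locomotion-mode transition prediction.

Stance segmentation from FC/TO events, transition labeling against the
mode timeline, 100 ms / 12 ms sliding-window 62-element featurization
(20 EMG + 42 IMU per-window channel means), per-window classification,
and majority voting with early-prediction offsets relative to TO.

A transition label is the ordered pair "from stance mode" -> "mode the
same leg steps into at its next foot contact".  The closed 19-class
vocabulary groups into three families: walking (7 classes; ramp
destinations are collapsed to RA / RD), ramp ascent (6) and ramp
descent (6).  By default one classifier is trained per family; a
single 19-class model is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .event_detector import GaitEvent
from .mlp_core import TrainedMLP, predict_proba, train, transition_mlp_config

WALKING_TRANSITIONS: Tuple[str, ...] = (
    "W->W", "W->SA", "W->RA", "W->SD", "W->RD", "W->O", "W->ST",
)
RAMP_ASCENT_TRANSITIONS: Tuple[str, ...] = (
    "RA1->RA1", "RA2->RA2", "RA3->RA3", "RA1->W", "RA2->W", "RA3->W",
)
RAMP_DESCENT_TRANSITIONS: Tuple[str, ...] = (
    "RD1->RD1", "RD2->RD2", "RD3->RD3", "RD1->W", "RD2->W", "RD3->W",
)
TRANSITIONS: Tuple[str, ...] = (
    WALKING_TRANSITIONS + RAMP_ASCENT_TRANSITIONS + RAMP_DESCENT_TRANSITIONS
)

FAMILIES: Dict[str, Tuple[str, ...]] = {
    "walking": WALKING_TRANSITIONS,
    "ramp_ascent": RAMP_ASCENT_TRANSITIONS,
    "ramp_descent": RAMP_DESCENT_TRANSITIONS,
}

UNDECIDABLE = "undecidable"

WIN_MS_DEFAULT = 100.0
STEP_MS_DEFAULT = 12.0


def family_of_mode(mode: str) -> Optional[str]:
    """Transition family implied by the stance ('from') mode."""
    if mode == "W":
        return "walking"
    if mode.startswith("RA"):
        return "ramp_ascent"
    if mode.startswith("RD"):
        return "ramp_descent"
    return None


def transition_label(from_mode: str, to_mode: str) -> Optional[str]:
    """Map a (from, to) mode pair onto the closed vocabulary, else None.

    Destinations from walking collapse ramp inclines: W->RA2 is labeled
    "W->RA".  Out-of-vocabulary pairs (e.g. SA->W) return None.
    """
    if from_mode == "W":
        dest = to_mode
        if dest.startswith("RA"):
            dest = "RA"
        elif dest.startswith("RD"):
            dest = "RD"
        label = f"W->{dest}"
        return label if label in TRANSITIONS else None
    label = f"{from_mode}->{to_mode}"
    return label if label in TRANSITIONS else None


# --------------------------------------------------------------------------
# Stance segmentation and labeling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StanceSegment:
    fc_time_s: float
    to_time_s: float
    from_mode: str
    to_mode: str
    transition: Optional[str]  # None = out-of-vocabulary (excluded from training)

    def __post_init__(self) -> None:
        if self.fc_time_s >= self.to_time_s:
            raise ValueError("stance requires fc_time < to_time")


def segment_stance(events: Sequence[GaitEvent]) -> List[Tuple[float, float]]:
    """(FC, TO) intervals of one side, in order; dangling FCs dropped."""
    intervals: List[Tuple[float, float]] = []
    open_fc: Optional[float] = None
    for e in sorted(events, key=lambda ev: ev.time_s):
        if e.kind == "FC":
            open_fc = e.time_s
        elif open_fc is not None:
            intervals.append((open_fc, e.time_s))
            open_fc = None
    return intervals


def mode_at(mode_timeline: Sequence[Tuple[str, float, float]], t: float) -> str:
    # A segment boundary is the foot-contact instant at which the leg steps
    # into the new mode, so a time exactly on a boundary belongs to the
    # segment that *starts* there: scan latest-first.
    for mode, start, end in reversed(list(mode_timeline)):
        if t >= start - 1e-9:
            if t < end + 1e-9:
                return mode
            break
    raise ValueError(f"time {t:.3f} s is outside the mode timeline")


def label_transitions(
    mode_timeline: Sequence[Tuple[str, float, float]],
    stance_intervals: Sequence[Tuple[float, float]],
) -> List[StanceSegment]:
    """Attach (from, to) modes and transition labels to stance intervals.

    ``from_mode`` is the mode active during the stance; ``to_mode`` the
    mode active at the next same-side foot contact.  The final stance
    (no following FC) is dropped; out-of-vocabulary pairs are kept with
    ``transition=None`` so callers can exclude them from training.
    """
    segments: List[StanceSegment] = []
    for i, (fc, to) in enumerate(stance_intervals):
        if i + 1 >= len(stance_intervals):
            break  # no next foot contact observed
        next_fc = stance_intervals[i + 1][0]
        from_mode = mode_at(mode_timeline, fc)
        to_mode = mode_at(mode_timeline, next_fc)
        segments.append(
            StanceSegment(
                fc_time_s=fc,
                to_time_s=to,
                from_mode=from_mode,
                to_mode=to_mode,
                transition=transition_label(from_mode, to_mode),
            )
        )
    return segments


# --------------------------------------------------------------------------
# Sliding windows
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisWindow:
    start_s: float
    end_s: float
    feature: np.ndarray  # (62,) = 20 EMG means then 42 IMU means


def window_count(duration_ms: float, win_ms: float, step_ms: float) -> int:
    """Number of window placements: floor((duration - win)/step) + 1.

    A 1 ns slack absorbs float round-off so a stance of exactly one
    window length yields one window.
    """
    if duration_ms + 1e-9 < win_ms:
        return 0
    return int(np.floor((duration_ms - win_ms + 1e-9) / step_ms)) + 1


def make_windows(
    processed,
    segment,
    win_ms: float = WIN_MS_DEFAULT,
    step_ms: float = STEP_MS_DEFAULT,
) -> List[AnalysisWindow]:
    """Sliding windows anchored at FC, advancing by ``step_ms`` while the
    window end stays within the stance; feature = per-channel mean over
    the window for all 20 EMG and 42 IMU channels (EMG first)."""
    fc = segment.fc_time_s if isinstance(segment, StanceSegment) else segment[0]
    to = segment.to_time_s if isinstance(segment, StanceSegment) else segment[1]
    rate = processed.rate_hz
    duration_ms = (to - fc) * 1000.0
    n_win = window_count(duration_ms, win_ms, step_ms)
    if n_win == 0:
        warnings.warn(
            f"stance of {duration_ms:.0f} ms is shorter than one "
            f"{win_ms:.0f} ms window; no windows produced",
            stacklevel=2,
        )
        return []
    win_n = int(round(win_ms / 1000.0 * rate))
    n_samples = processed.emg_env.shape[1]
    windows: List[AnalysisWindow] = []
    for k in range(n_win):
        start = fc + k * step_ms / 1000.0
        i0 = int(round(start * rate))
        i1 = min(i0 + win_n, n_samples)
        if i1 <= i0:
            break
        feat = np.concatenate(
            [
                processed.emg_env[:, i0:i1].mean(axis=1),
                processed.imu_norm[:, i0:i1].mean(axis=1),
            ]
        )
        windows.append(
            AnalysisWindow(start_s=start, end_s=start + win_ms / 1000.0, feature=feat)
        )
    return windows


# --------------------------------------------------------------------------
# Voting
# --------------------------------------------------------------------------


def vote(
    window_labels: Sequence,
    window_probs: Optional[Sequence[float]] = None,
    class_order: Optional[Sequence] = None,
):
    """Plurality label over window predictions.

    Ties are broken by the larger summed softmax probability of the tied
    labels (``window_probs`` holds each window's probability for its own
    predicted label), then by the lowest class index in ``class_order``.
    """
    labels = list(window_labels)
    if not labels:
        raise ValueError("vote requires at least one window")
    probs = list(window_probs) if window_probs is not None else [0.0] * len(labels)
    counts: Dict = {}
    psums: Dict = {}
    for lab, p in zip(labels, probs):
        counts[lab] = counts.get(lab, 0) + 1
        psums[lab] = psums.get(lab, 0.0) + float(p)
    order = list(class_order) if class_order is not None else sorted(counts.keys(), key=str)

    def rank(lab):
        idx = order.index(lab) if lab in order else len(order)
        return (-counts[lab], -psums[lab], idx)

    return min(counts.keys(), key=rank)


# --------------------------------------------------------------------------
# Family models
# --------------------------------------------------------------------------


@dataclass
class TransitionModel:
    """A trained window classifier plus its label vocabulary."""

    mlp: TrainedMLP
    classes: Tuple[str, ...]

    def predict_windows(self, windows: Sequence[AnalysisWindow]):
        X = np.stack([w.feature for w in windows])
        probs = predict_proba(self.mlp, X)
        idx = probs.argmax(axis=1)
        labels = [self.classes[i] for i in idx]
        own_p = probs[np.arange(len(idx)), idx]
        return labels, own_p


def train_transition_model(
    windows: Sequence[AnalysisWindow],
    labels: Sequence[str],
    classes: Sequence[str],
    seed: int = 0,
    **config_overrides,
) -> TransitionModel:
    """Train a window classifier over the given label vocabulary."""
    classes = tuple(classes)
    X = np.stack([w.feature for w in windows])
    y = np.asarray([classes.index(lab) for lab in labels], dtype=np.int64)
    cfg = transition_mlp_config(
        n_classes=len(classes), seed=seed, n_inputs=X.shape[1], **config_overrides
    )
    return TransitionModel(mlp=train(X, y, cfg), classes=classes)


def predict_at_offset(
    model: TransitionModel,
    windows: Sequence[AnalysisWindow],
    to_time_s: float,
    offset_ms: float,
):
    """Majority vote over windows ending at least ``offset_ms`` before TO.

    The vote is cumulative: every window available up to the cutoff
    participates.  Returns :data:`UNDECIDABLE` when no window qualifies.
    """
    if offset_ms < 0:
        raise ValueError("offset_ms must be non-negative")
    cutoff = to_time_s - offset_ms / 1000.0
    eligible = [w for w in windows if w.end_s <= cutoff + 1e-9]
    if not eligible:
        return UNDECIDABLE
    labels, own_p = model.predict_windows(eligible)
    return vote(labels, own_p, class_order=model.classes)
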