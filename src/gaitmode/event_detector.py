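"""First-stage gait-event classification.

Per-sample FC / TO / Other labeling of the normalized IMU stream, the
42-element instantaneous feature matrix, discretization of per-sample
predictions into timed events, greedy event matching against ground
truth, and prediction-time summary statistics.

Class indices: 0 = Other, 1 = FC, 2 = TO (``EVENT_CLASSES``).  Sign
convention for prediction times: positive means the event was predicted
*before* it truly occurred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

EVENT_CLASSES: Tuple[str, ...] = ("Other", "FC", "TO")
OTHER, FC, TO = 0, 1, 2


@dataclass(frozen=True)
class GaitEvent:
    kind: str    # "FC" | "TO"
    side: str    # "left" | "right"
    time_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("FC", "TO"):
            raise ValueError(f"kind must be 'FC' or 'TO', got {self.kind!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass(frozen=True)
class PredictionTimeStats:
    """Summary of signed prediction-time differences (ms) for one event kind."""

    kind: str
    n_matched: int
    n_missed: int
    mean: float
    std: float
    min: float
    q25: float
    median: float
    q75: float
    max: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "kind": self.kind,
            "n_matched": self.n_matched,
            "n_missed": self.n_missed,
            "mean": self.mean,
            "std": self.std,
            "min": self.min,
            "q25": self.q25,
            "median": self.median,
            "q75": self.q75,
            "max": self.max,
        }


# --------------------------------------------------------------------------
# Per-sample labeling
# --------------------------------------------------------------------------


def label_samples(
    true_events: Sequence[GaitEvent],
    n_samples: int,
    rate_hz: float,
    tolerance_ms: float = 10.0,
) -> np.ndarray:
    """Per-sample class sequence: FC/TO within +-tolerance of an event.

    Samples within the tolerance band of an FC instant are labeled FC,
    likewise TO; everything else is Other.  Where bands overlap, the
    nearer event wins; an FC and a TO at exactly equal distance from a
    sample is a degenerate configuration and raises.
    """
    if tolerance_ms < 0:
        raise ValueError("tolerance_ms must be non-negative")
    times = [e.time_s for e in true_events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("events must be sorted by time")

    labels = np.zeros(n_samples, dtype=np.int64)
    best = np.full(n_samples, np.iinfo(np.int64).max, dtype=np.int64)
    tol = int(round(tolerance_ms / 1000.0 * rate_hz))
    for e in true_events:
        center = int(round(e.time_s * rate_hz))
        lo = max(center - tol, 0)
        hi = min(center + tol, n_samples - 1)
        if hi < lo:
            continue
        idx = np.arange(lo, hi + 1)
        d = np.abs(idx - center)
        cls = FC if e.kind == "FC" else TO
        tie = (d == best[idx]) & (labels[idx] != cls) & (labels[idx] != OTHER)
        if np.any(tie):
            raise ValueError(
                "degenerate labeling: an FC and a TO band overlap at equal distance"
            )
        closer = d < best[idx]
        labels[idx[closer]] = cls
        best[idx[closer]] = d[closer]
    return labels


def build_event_features(processed) -> np.ndarray:
    """Per-sample 42-element feature matrix: the normalized IMU channels.

    Row ``k`` is ``imu_norm[:, k]``; channel order is the documented IMU
    channel order of the simulator (sensor-major, DOF-minor).
    """
    imu = processed.imu_norm
    if imu.shape[0] != 42:
        raise ValueError(f"expected 42 IMU channels, got {imu.shape[0]}")
    return np.ascontiguousarray(imu.T)


# --------------------------------------------------------------------------
# Event discretization and matching
# --------------------------------------------------------------------------


def extract_events(
    per_sample_pred: np.ndarray,
    rate_hz: float,
    refractory_ms: float = 200.0,
    side: str = "right",
) -> List[GaitEvent]:
    """Collapse per-sample FC/TO predictions into discrete events.

    Each maximal run of consecutive identical FC (or TO) predictions
    becomes one event at the run's median sample time; a same-kind event
    within ``refractory_ms`` of the previous one is discarded.
    """
    if refractory_ms <= 0:
        raise ValueError("refractory_ms must be positive")
    pred = np.asarray(per_sample_pred)
    events: List[GaitEvent] = []
    last_time = {FC: -np.inf, TO: -np.inf}
    n = len(pred)
    i = 0
    while i < n:
        cls = pred[i]
        if cls == OTHER:
            i += 1
            continue
        j = i
        while j < n and pred[j] == cls:
            j += 1
        median_idx = int(np.median(np.arange(i, j)))
        t = median_idx / rate_hz
        if t - last_time[cls] >= refractory_ms / 1000.0:
            events.append(GaitEvent(EVENT_CLASSES[cls], side, t))
            last_time[cls] = t
        i = j
    events.sort(key=lambda e: e.time_s)
    return events


@dataclass(frozen=True)
class MatchedEvent:
    predicted: GaitEvent
    truth: GaitEvent
    diff_ms: float  # (truth - predicted) * 1000; positive = predicted early


def match_events(
    predicted: Sequence[GaitEvent],
    truth: Sequence[GaitEvent],
    match_tolerance_ms: float = 100.0,
) -> Tuple[List[MatchedEvent], List[GaitEvent]]:
    """Greedy nearest-in-time one-to-one matching of same-kind events.

    Returns (matched pairs, missed truth events).  Candidate pairs are
    taken in order of increasing |time difference|; each event is used
    at most once.
    """
    tol = match_tolerance_ms / 1000.0
    candidates = []
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth):
            if p.kind != t.kind:
                continue
            dt = abs(p.time_s - t.time_s)
            if dt <= tol + 1e-12:
                candidates.append((dt, ti, pi))
    candidates.sort()
    used_p: set = set()
    used_t: set = set()
    matched: List[MatchedEvent] = []
    for dt, ti, pi in candidates:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        p, t = predicted[pi], truth[ti]
        matched.append(MatchedEvent(p, t, (t.time_s - p.time_s) * 1000.0))
    matched.sort(key=lambda m: m.truth.time_s)
    missed = [t for ti, t in enumerate(truth) if ti not in used_t]
    return matched, missed


def prediction_time_stats(
    diffs_ms: Sequence[float], kind: str, n_missed: int = 0
) -> PredictionTimeStats:
    """Summary statistics of signed prediction times for one event kind.

    Quantiles use the linear-interpolation convention; std is the
    population standard deviation.
    """
    d = np.asarray(list(diffs_ms), dtype=float)
    if d.size == 0:
        raise ValueError(f"no matched {kind} events to summarize")
    q25, q50, q75 = np.percentile(d, [25, 50, 75])
    return PredictionTimeStats(
        kind=kind,
        n_matched=int(d.size),
        n_missed=int(n_missed),
        mean=float(d.mean()),
        std=float(d.std()),
        min=float(d.min()),
        q25=float(q25),
        median=float(q50),
        q75=float(q75),
        max=float(d.max()),
    )


# --------------------------------------------------------------------------
# Stage-1 pipeline helpers
# --------------------------------------------------------------------------


def make_training_set(
    processed_trials: Sequence,
    tolerance_ms: float = 10.0,
    other_ratio: float = 3.0,
    edge_exclude_ms: float = 50.0,
    rng: Optional[np.random.Generator] = None,
    side: str = "right",
) -> Tuple[np.ndarray, np.ndarray]:
    """Pooled per-sample (features, labels) for the event classifier.

    All FC/TO-band samples are kept; the dominant Other class is randomly
    subsampled to ``other_ratio`` times the event-sample count.  The
    first and last ``edge_exclude_ms`` of each trial are excluded
    (filter edge effects).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    xs, ys = [], []
    for p in processed_trials:
        feats = build_event_features(p)
        n = feats.shape[0]
        events = sorted(
            (e for e in p.true_events if e.side == side), key=lambda e: e.time_s
        )
        labels = label_samples(events, n, p.rate_hz, tolerance_ms)
        edge = int(round(edge_exclude_ms / 1000.0 * p.rate_hz))
        valid = np.arange(edge, n - edge)
        ev_idx = valid[labels[valid] != OTHER]
        other_idx = valid[labels[valid] == OTHER]
        n_keep = min(int(round(other_ratio * ev_idx.size)), other_idx.size)
        keep = rng.choice(other_idx, size=n_keep, replace=False)
        keep.sort()
        sel = np.concatenate([ev_idx, keep])
        sel.sort()
        xs.append(feats[sel])
        ys.append(labels[sel])
    return np.concatenate(xs), np.concatenate(ys)


def detect(
    model,
    processed,
    refractory_ms: float = 200.0,
    edge_exclude_ms: float = 50.0,
    side: str = "right",
) -> List[GaitEvent]:
    """Run the trained event MLP over a processed trial and discretize."""
    from .mlp_core import predict

    feats = build_event_features(processed)
    pred = predict(model, feats)
    edge = int(round(edge_exclude_ms / 1000.0 * processed.rate_hz))
    if edge > 0:
        pred[:edge] = OTHER
        pred[-edge:] = OTHER
    return extract_events(pred, processed.rate_hz, refractory_ms, side=side)
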