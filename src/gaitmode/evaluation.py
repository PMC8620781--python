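"""LOOCV orchestration and the metric suite.

Confusion matrices, per-class precision/recall/F1, aggregate (pooled)
accuracy, per-offset accuracy curves, and stage-1 prediction-time
statistics, evaluated with intra-subject leave-one-out cross-validation:
per subject, each trial serves as the test set once while the remaining
trials train both classifier stages and the IMU normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import event_detector as ed
from . import preprocess as pp
from . import transition_predictor as tp
from .mlp_core import event_mlp_config, train

#: Offset (ms before TO) at which each family's headline confusion
#: matrix and per-class metrics are reported.
HEADLINE_OFFSET_MS = {"walking": 50.0, "ramp_ascent": 150.0, "ramp_descent": 250.0}


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    classes: Tuple[str, ...]
    counts: np.ndarray  # (n, n); rows = actual, columns = predicted

    def to_dict(self) -> Dict:
        return {"classes": list(self.classes), "counts": self.counts.tolist()}


def confusion_matrix(
    actual: Sequence, predicted: Sequence, classes: Sequence
) -> ConfusionMatrix:
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in index:
            raise ValueError(f"unknown actual label {a!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def precision_recall_f1(cm: ConfusionMatrix) -> Dict[str, Dict[str, float]]:
    """Per-class precision, recall and F1.

    Zero-denominator cells are reported as 0.0 with ``"undefined": True``
    flagged on the class entry; F1 is 0 when precision + recall = 0.
    """
    if cm.counts.size == 0:
        raise ValueError("empty confusion matrix")
    out: Dict[str, Dict[str, float]] = {}
    for i, cls in enumerate(cm.classes):
        tp_ = float(cm.counts[i, i])
        row = float(cm.counts[i, :].sum())
        col = float(cm.counts[:, i].sum())
        entry: Dict[str, float] = {}
        undefined = False
        recall = tp_ / row if row > 0 else 0.0
        precision = tp_ / col if col > 0 else 0.0
        if row == 0 or col == 0:
            undefined = True
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        entry.update(precision=precision, recall=recall, f1=f1)
        if undefined:
            entry["undefined"] = True
        out[cls] = entry
    return out


def aggregate_accuracy(cm: ConfusionMatrix) -> float:
    """Pooled (micro) accuracy: trace over total count."""
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


# --------------------------------------------------------------------------
# LOOCV
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Fold:
    subject_id: int
    test_trial_id: int
    train: tuple
    test: object


def loocv_split(trials: Sequence) -> List[Fold]:
    """Intra-subject leave-one-trial-out folds, deterministically ordered."""
    by_subject: Dict[int, List] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    folds: List[Fold] = []
    for sid in sorted(by_subject):
        subject_trials = sorted(by_subject[sid], key=lambda t: t.trial_id)
        if len(subject_trials) < 2:
            raise ValueError(f"subject {sid} has fewer than 2 trials")
        for test in subject_trials:
            train_set = tuple(t for t in subject_trials if t is not test)
            folds.append(
                Fold(
                    subject_id=sid,
                    test_trial_id=test.trial_id,
                    train=train_set,
                    test=test,
                )
            )
    return folds


# --------------------------------------------------------------------------
# Experiment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    offsets_ms: Tuple[float, ...] = (350.0, 250.0, 150.0, 50.0)
    label_tolerance_ms: float = 10.0
    refractory_ms: float = 200.0
    match_tolerance_ms: float = 100.0
    edge_exclude_ms: float = 50.0
    other_ratio: float = 3.0
    win_ms: float = 100.0
    step_ms: float = 12.0
    max_epochs: int = 100
    early_stop_patience: int = 10
    single_model: bool = False  # one 19-class model instead of 3 family models


@dataclass
class MetricsReport:
    """Pooled LOOCV results for both pipeline stages."""

    event_stats: Dict[str, ed.PredictionTimeStats]
    event_recall: Dict[str, float]
    event_precision: Dict[str, float]
    transition_accuracy: Dict[str, Dict[float, Dict[str, float]]]
    transition_accuracy_subject_mean: Dict[str, Dict[float, float]]
    confusions: Dict[str, ConfusionMatrix]
    per_class: Dict[str, Dict[str, Dict[str, float]]]
    n_folds: int
    n_missed_transitions: int
    config: PipelineConfig

    def to_dict(self) -> Dict:
        return {
            "n_folds": self.n_folds,
            "n_missed_transitions": self.n_missed_transitions,
            "event_recall": {k: self.event_recall[k] for k in sorted(self.event_recall)},
            "event_precision": {
                k: self.event_precision[k] for k in sorted(self.event_precision)
            },
            "event_stats": {
                k: self.event_stats[k].to_dict() for k in sorted(self.event_stats)
            },
            "transition_accuracy": {
                fam: {
                    f"{off:g}": dict(sorted(vals.items()))
                    for off, vals in sorted(offs.items())
                }
                for fam, offs in sorted(self.transition_accuracy.items())
            },
            "transition_accuracy_subject_mean": {
                fam: {f"{off:g}": v for off, v in sorted(offs.items())}
                for fam, offs in sorted(self.transition_accuracy_subject_mean.items())
            },
            "confusions": {
                fam: cm.to_dict() for fam, cm in sorted(self.confusions.items())
            },
            "per_class": {
                fam: {c: dict(sorted(m.items())) for c, m in sorted(d.items())}
                for fam, d in sorted(self.per_class.items())
            },
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in sorted(self.config.__dict__.items())
            },
        }


def _fold_seed(seed: int, tag: int, sid: int, tid: int) -> int:
    ss = np.random.SeedSequence([seed, tag, sid, tid])
    return int(ss.generate_state(1)[0] % (2**31))


def _processed_from_cache(trial, cache, stats) -> pp.ProcessedTrial:
    emg_env, imu_cond = cache[(trial.subject_id, trial.trial_id)]
    imu_norm = pp.zscore(imu_cond, stats)
    n = min(emg_env.shape[1], imu_norm.shape[1])
    return pp.ProcessedTrial(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        emg_env=emg_env[:, :n],
        imu_norm=imu_norm[:, :n],
        rate_hz=trial.emg_rate_hz,
        mode_timeline=list(trial.mode_timeline),
        true_events=list(trial.true_events),
        stats=stats,
    )


def _match_stances(
    true_segments: Sequence[tp.StanceSegment],
    detected_intervals: Sequence[Tuple[float, float]],
    tolerance_s: float,
) -> Tuple[List[Tuple[tp.StanceSegment, Tuple[float, float]]], int]:
    """Greedy one-to-one matching of true stances to detected intervals
    by FC proximity; both FC and TO must fall within tolerance."""
    candidates = []
    for ti, seg in enumerate(true_segments):
        for di, (fc, to) in enumerate(detected_intervals):
            if (
                abs(fc - seg.fc_time_s) <= tolerance_s
                and abs(to - seg.to_time_s) <= tolerance_s
            ):
                candidates.append((abs(fc - seg.fc_time_s), ti, di))
    candidates.sort()
    used_t: set = set()
    used_d: set = set()
    pairs = []
    for _, ti, di in candidates:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        pairs.append((true_segments[ti], detected_intervals[di]))
    missed = len(true_segments) - len(pairs)
    pairs.sort(key=lambda p: p[0].fc_time_s)
    return pairs, missed


def run_experiment(dataset: Sequence, config: PipelineConfig) -> MetricsReport:
    """Full two-stage LOOCV experiment on a trial collection.

    Per fold: fit the IMU normalizer on the training trials, train the
    stage-1 event MLP and the stage-2 transition models (training windows
    anchored at foot-switch truth), then detect events on the held-out
    trial and predict its transitions at every configured offset
    (inference windows anchored at the *detected* FC/TO).  Results are
    pooled across folds and subjects.  Fully seeded and deterministic.
    """
    # Conditioning (filtering + resampling) is fold-independent: cache it.
    cache = {}
    for t in dataset:
        emg_env = pp.condition_emg(t.emg, t.emg_rate_hz)
        imu_cond = pp.conditioned_imu(t)
        cache[(t.subject_id, t.trial_id)] = (emg_env, imu_cond)

    folds = loocv_split(dataset)
    diffs: Dict[str, List[float]] = {"FC": [], "TO": []}
    missed_events: Dict[str, int] = {"FC": 0, "TO": 0}
    n_detected: Dict[str, int] = {"FC": 0, "TO": 0}
    records: List[Tuple[str, float, str, str, int]] = []
    n_missed_transitions = 0

    for fold in folds:
        sid, tid = fold.subject_id, fold.test_trial_id
        stats = pp.fit_normalizer(
            [cache[(t.subject_id, t.trial_id)][1] for t in fold.train]
        )
        train_proc = [_processed_from_cache(t, cache, stats) for t in fold.train]
        test_proc = _processed_from_cache(fold.test, cache, stats)

        # ---- stage 1: event classifier -----------------------------------
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404, sid, tid]))
        X1, y1 = ed.make_training_set(
            train_proc,
            tolerance_ms=config.label_tolerance_ms,
            other_ratio=config.other_ratio,
            edge_exclude_ms=config.edge_exclude_ms,
            rng=rng,
        )
        event_model = train(
            X1,
            y1,
            event_mlp_config(
                seed=_fold_seed(config.seed, 303, sid, tid),
                max_epochs=config.max_epochs,
                early_stop_patience=config.early_stop_patience,
            ),
        )

        # ---- stage 2: transition models (anchored at truth) --------------
        fam_windows: Dict[str, List[tp.AnalysisWindow]] = {f: [] for f in tp.FAMILIES}
        fam_labels: Dict[str, List[str]] = {f: [] for f in tp.FAMILIES}
        for proc in train_proc:
            true_right = [e for e in proc.true_events if e.side == "right"]
            segments = tp.label_transitions(
                proc.mode_timeline, tp.segment_stance(true_right)
            )
            for seg in segments:
                if seg.transition is None:
                    continue
                fam = tp.family_of_mode(seg.from_mode)
                if fam is None:
                    continue
                wins = tp.make_windows(proc, seg, config.win_ms, config.step_ms)
                fam_windows[fam].extend(wins)
                fam_labels[fam].extend([seg.transition] * len(wins))

        models: Dict[str, tp.TransitionModel] = {}
        if config.single_model:
            all_wins = [w for f in sorted(fam_windows) for w in fam_windows[f]]
            all_labs = [l for f in sorted(fam_labels) for l in fam_labels[f]]
            shared = tp.train_transition_model(
                all_wins,
                all_labs,
                tp.TRANSITIONS,
                seed=_fold_seed(config.seed, 505, sid, tid),
                max_epochs=config.max_epochs,
                early_stop_patience=config.early_stop_patience,
            )
            for fam in tp.FAMILIES:
                models[fam] = shared
        else:
            for fam in sorted(tp.FAMILIES):
                if len(set(fam_labels[fam])) < 2:
                    continue
                models[fam] = tp.train_transition_model(
                    fam_windows[fam],
                    fam_labels[fam],
                    tp.FAMILIES[fam],
                    seed=_fold_seed(config.seed, 505 + list(sorted(tp.FAMILIES)).index(fam), sid, tid),
                    max_epochs=config.max_epochs,
                    early_stop_patience=config.early_stop_patience,
                )

        # ---- test trial: detect events, predict transitions --------------
        detected = ed.detect(
            event_model,
            test_proc,
            refractory_ms=config.refractory_ms,
            edge_exclude_ms=config.edge_exclude_ms,
        )
        true_right = [e for e in test_proc.true_events if e.side == "right"]
        matched, missed = ed.match_events(
            detected, true_right, config.match_tolerance_ms
        )
        for m in matched:
            diffs[m.truth.kind].append(m.diff_ms)
        for e in missed:
            missed_events[e.kind] += 1
        for e in detected:
            n_detected[e.kind] += 1

        true_segments = tp.label_transitions(
            test_proc.mode_timeline, tp.segment_stance(true_right)
        )
        true_segments = [s for s in true_segments if s.transition is not None]
        detected_intervals = tp.segment_stance(detected)
        pairs, miss = _match_stances(
            true_segments, detected_intervals, config.match_tolerance_ms / 1000.0
        )
        n_missed_transitions += miss
        for seg, (fc, to) in pairs:
            fam = tp.family_of_mode(seg.from_mode)
            if fam is None or fam not in models:
                continue
            wins = tp.make_windows(test_proc, (fc, to), config.win_ms, config.step_ms)
            if not wins:
                continue
            for off in config.offsets_ms:
                pred = tp.predict_at_offset(models[fam], wins, to, off)
                records.append((fam, off, seg.transition, pred, sid))

    # ---- pooling ----------------------------------------------------------
    event_stats = {}
    event_recall = {}
    event_precision = {}
    for kind in ("FC", "TO"):
        n_matched = len(diffs[kind])
        total = n_matched + missed_events[kind]
        event_recall[kind] = n_matched / total if total else 0.0
        event_precision[kind] = (
            n_matched / n_detected[kind] if n_detected[kind] else 0.0
        )
        if n_matched:
            event_stats[kind] = ed.prediction_time_stats(
                diffs[kind], kind, n_missed=missed_events[kind]
            )

    transition_accuracy: Dict[str, Dict[float, Dict[str, float]]] = {}
    subject_mean: Dict[str, Dict[float, float]] = {}
    confusions: Dict[str, ConfusionMatrix] = {}
    per_class: Dict[str, Dict[str, Dict[str, float]]] = {}
    for fam in sorted(tp.FAMILIES):
        fam_records = [r for r in records if r[0] == fam]
        if not fam_records:
            continue
        transition_accuracy[fam] = {}
        subject_mean[fam] = {}
        for off in sorted(set(r[1] for r in fam_records)):
            rs = [r for r in fam_records if r[1] == off]
            decided = [r for r in rs if r[3] != tp.UNDECIDABLE]
            n_undecidable = len(rs) - len(decided)
            correct = sum(1 for r in decided if r[2] == r[3])
            acc = correct / len(decided) if decided else 0.0
            transition_accuracy[fam][off] = {
                "accuracy": acc,
                "n": len(decided),
                "n_undecidable": n_undecidable,
            }
            per_subj = []
            for s in sorted(set(r[4] for r in decided)):
                ss = [r for r in decided if r[4] == s]
                per_subj.append(sum(1 for r in ss if r[2] == r[3]) / len(ss))
            subject_mean[fam][off] = float(np.mean(per_subj)) if per_subj else 0.0

        head = HEADLINE_OFFSET_MS[fam]
        head_rs = [
            r for r in fam_records if r[1] == head and r[3] != tp.UNDECIDABLE
        ]
        if head_rs:
            # the shared 19-class model may predict outside the family
            classes = tp.TRANSITIONS if config.single_model else tp.FAMILIES[fam]
            cm = confusion_matrix(
                [r[2] for r in head_rs], [r[3] for r in head_rs], classes
            )
            confusions[fam] = cm
            per_class[fam] = precision_recall_f1(cm)

    return MetricsReport(
        event_stats=event_stats,
        event_recall=event_recall,
        event_precision=event_precision,
        transition_accuracy=transition_accuracy,
        transition_accuracy_subject_mean=subject_mean,
        confusions=confusions,
        per_class=per_class,
        n_folds=len(folds),
        n_missed_transitions=n_missed_transitions,
        config=config,
    )
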