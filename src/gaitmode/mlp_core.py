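"""Minimal feed-forward network shared by both classifier stages.

A numpy implementation of a ReLU/softmax multilayer perceptron trained
with Adam on (optionally class-weighted) categorical cross-entropy,
with a stratified internal validation split and patience-based early
stopping.  Everything is deterministic given ``MLPConfig.seed``.

Named presets reproduce the two stage architectures: the gait-event
model uses one hidden layer of 64 units with batch size 16; the
transition model one hidden layer of 128 units with batch size 64.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class MLPConfig:
    n_inputs: int
    hidden_layers: Tuple[int, ...]
    n_classes: int
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.1
    monitor: str = "accuracy"            # "accuracy" | "loss"
    class_weight: Optional[str] = None   # None | "balanced"

    def validate(self) -> None:
        if self.n_inputs <= 0 or self.n_classes <= 0 or self.batch_size <= 0:
            raise ValueError("counts must be positive")
        if any(h <= 0 for h in self.hidden_layers):
            raise ValueError("hidden layer sizes must be positive")
        if self.max_epochs <= 0 or self.early_stop_patience <= 0:
            raise ValueError("epoch counts must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("early_stop_patience must not exceed max_epochs")
        if self.monitor not in ("accuracy", "loss"):
            raise ValueError(f"unknown monitor {self.monitor!r}")

    def n_parameters(self) -> int:
        dims = [self.n_inputs, *self.hidden_layers, self.n_classes]
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))


def event_mlp_config(seed: int = 0, **overrides) -> MLPConfig:
    """Preset for the gait-event classifier: 42 -> 64 -> 3, batch 16."""
    base = MLPConfig(
        n_inputs=42,
        hidden_layers=(64,),
        n_classes=3,
        batch_size=16,
        seed=seed,
        class_weight="balanced",
    )
    return replace(base, **overrides)


def transition_mlp_config(n_classes: int, seed: int = 0, **overrides) -> MLPConfig:
    """Preset for the transition classifier: 62 -> 128 -> C, batch 64."""
    base = MLPConfig(
        n_inputs=62,
        hidden_layers=(128,),
        n_classes=n_classes,
        batch_size=64,
        seed=seed,
    )
    return replace(base, **overrides)


@dataclass
class TrainedMLP:
    config: MLPConfig
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    history: Dict[str, List[float]]  # "train_loss", "val_metric"


# --------------------------------------------------------------------------
# Forward / backward
# --------------------------------------------------------------------------


def _forward(weights, biases, x):
    """Returns (activations per layer, softmax probabilities)."""
    acts = [x]
    h = x
    for w, b in zip(weights[:-1], biases[:-1]):
        h = np.maximum(h @ w + b, 0.0)
        acts.append(h)
    logits = h @ weights[-1] + biases[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return acts, probs


def _loss(probs, y, sample_w):
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-(sample_w * np.log(p)).sum() / sample_w.sum())


def _stratified_split(
    y: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; classes too small to split stay in train."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size))
        n_val = min(n_val, idx.size - 1)  # keep at least one in train
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    train = np.sort(np.concatenate(train_idx))
    val = np.sort(np.concatenate(val_idx))
    return train, val


def train(features: np.ndarray, labels: np.ndarray, config: MLPConfig) -> TrainedMLP:
    """Mini-batch Adam on categorical cross-entropy with early stopping.

    Monitors the configured validation metric each epoch and stops
    ``early_stop_patience`` epochs after the best epoch if no
    improvement follows; the best-epoch weights are restored.
    """
    config.validate()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    if X.ndim != 2 or X.shape[1] != config.n_inputs:
        raise ValueError(
            f"feature width {X.shape[-1]} does not match n_inputs {config.n_inputs}"
        )
    if y.min() < 0 or y.max() >= config.n_classes:
        raise ValueError("label index out of range for n_classes")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes present in labels")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    tr, va = _stratified_split(y, config.val_fraction, rng)
    if va.size == 0:  # degenerate tiny data: validate on train
        va = tr
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    # class weights (inverse frequency over the training portion)
    cw = np.ones(config.n_classes)
    if config.class_weight == "balanced":
        counts = np.bincount(ytr, minlength=config.n_classes).astype(float)
        present = counts > 0
        cw[present] = counts[present].sum() / (present.sum() * counts[present])
        cw[~present] = 0.0

    # Glorot-uniform init
    dims = [config.n_inputs, *config.hidden_layers, config.n_classes]
    weights, biases = [], []
    for a, b in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (a + b))
        weights.append(rng.uniform(-limit, limit, size=(a, b)))
        biases.append(np.zeros(b))

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    def val_metric() -> float:
        _, p = _forward(weights, biases, Xva)
        if config.monitor == "accuracy":
            return float((p.argmax(axis=1) == yva).mean())
        w = cw[yva]
        return -_loss(p, yva, w)

    history: Dict[str, List[float]] = {"train_loss": [], "val_metric": []}
    best_metric = -np.inf
    best_epoch = -1
    best_state: Optional[Tuple[list, list]] = None

    n = Xtr.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_wsum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            wb = cw[yb]
            acts, probs = _forward(weights, biases, xb)
            wsum = wb.sum()
            p = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            epoch_loss += float(-(wb * np.log(p)).sum())
            epoch_wsum += wsum

            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            delta = (probs - onehot) * (wb / wsum)[:, None]
            t_step += 1
            for layer in range(len(weights) - 1, -1, -1):
                gw = acts[layer].T @ delta
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0)
                # Adam update
                mw[layer] = beta1 * mw[layer] + (1 - beta1) * gw
                vw[layer] = beta2 * vw[layer] + (1 - beta2) * gw * gw
                mb[layer] = beta1 * mb[layer] + (1 - beta1) * gb
                vb[layer] = beta2 * vb[layer] + (1 - beta2) * gb * gb
                mhat_w = mw[layer] / (1 - beta1**t_step)
                vhat_w = vw[layer] / (1 - beta2**t_step)
                mhat_b = mb[layer] / (1 - beta1**t_step)
                vhat_b = vb[layer] / (1 - beta2**t_step)
                weights[layer] -= config.learning_rate * mhat_w / (np.sqrt(vhat_w) + eps)
                biases[layer] -= config.learning_rate * mhat_b / (np.sqrt(vhat_b) + eps)

        history["train_loss"].append(epoch_loss / max(epoch_wsum, 1e-12))
        metric = val_metric()
        history["val_metric"].append(metric)
        if metric > best_metric:
            best_metric = metric
            best_epoch = epoch
            best_state = ([w.copy() for w in weights], [b.copy() for b in biases])
        elif epoch - best_epoch >= config.early_stop_patience:
            break

    assert best_state is not None
    return TrainedMLP(
        config=config,
        weights=best_state[0],
        biases=best_state[1],
        history=history,
    )


def predict_proba(model: TrainedMLP, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.config.n_inputs:
        raise ValueError(
            f"feature width {X.shape[1]} does not match n_inputs "
            f"{model.config.n_inputs}"
        )
    _, probs = _forward(model.weights, model.biases, X)
    return probs


def predict(model: TrainedMLP, features: np.ndarray) -> np.ndarray:
    """Argmax class indices (ties resolved to the lowest index)."""
    return predict_proba(model, features).argmax(axis=1)


def grid_search(
    candidate_configs: Sequence[MLPConfig],
    features: np.ndarray,
    labels: np.ndarray,
) -> MLPConfig:
    """Train each candidate and return the one with the best validation
    accuracy; ties go to the candidate with fewer parameters."""
    if len(candidate_configs) == 0:
        raise ValueError("need at least one candidate config")
    best: Optional[Tuple[float, int, int]] = None  # (-acc, n_params, order)
    best_config = None
    for i, cfg in enumerate(candidate_configs):
        cfg_acc = replace(cfg, monitor="accuracy")
        model = train(features, labels, cfg_acc)
        acc = max(model.history["val_metric"])
        key = (-acc, cfg.n_parameters(), i)
        if best is None or key < best:
            best = key
            best_config = cfg
    return best_config


# --------------------------------------------------------------------------
# Serialization: JSON header + raw float64 weight payload in one file
# --------------------------------------------------------------------------

_MAGIC = b"GMLP"


def save_model(model: TrainedMLP, path) -> None:
    header = {
        "config": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in model.config.__dict__.items()
            }
        },
        "shapes": [list(w.shape) for w in model.weights],
        "history": model.history,
    }
    hdr = json.dumps(header, sort_keys=True).encode("utf-8")
    with open(path, "wb") as f:
        f.write(_MAGIC)
        f.write(struct.pack("<I", len(hdr)))
        f.write(hdr)
        for w, b in zip(model.weights, model.biases):
            f.write(np.ascontiguousarray(w, dtype="<f8").tobytes())
            f.write(np.ascontiguousarray(b, dtype="<f8").tobytes())


def load_model(path) -> TrainedMLP:
    with open(path, "rb") as f:
        if f.read(4) != _MAGIC:
            raise ValueError(f"{path} is not a gaitmode model file")
        (hlen,) = struct.unpack("<I", f.read(4))
        header = json.loads(f.read(hlen).decode("utf-8"))
        cfg_d = dict(header["config"])
        cfg_d["hidden_layers"] = tuple(cfg_d["hidden_layers"])
        config = MLPConfig(**cfg_d)
        weights, biases = [], []
        for shape in header["shapes"]:
            a, b = shape
            w = np.frombuffer(f.read(8 * a * b), dtype="<f8").reshape(a, b).copy()
            bias = np.frombuffer(f.read(8 * b), dtype="<f8").copy()
            weights.append(w)
            biases.append(bias)
    return TrainedMLP(
        config=config, weights=weights, biases=biases, history=header["history"]
    )
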