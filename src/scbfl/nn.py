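"""From-scratch dense feed-forward network with mini-batch SGD.

This is the substrate both federation algorithms operate on: an L-layer
multilayer perceptron with ReLU hidden activations and a sigmoid output,
trained on binary cross-entropy with plain SGD (no momentum, no weight
decay). Inverted dropout can be applied to the last hidden layer during
training. Everything is deterministic given a seed.

Weight matrix ``l`` has shape (m_{l-1}, m_l) where m_0 is the input
dimension; the bias of layer ``l`` has length m_l.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import Cohort

__all__ = [
    "ModelParams",
    "TrainConfig",
    "GradientSet",
    "init_model",
    "forward",
    "train_local",
    "evaluate_scores",
    "cross_entropy",
    "save_model",
    "load_model",
]

_FORMAT_VERSION = 1
_EPS = 1e-12


@dataclass
class ModelParams:
    """Per-layer weight matrices and bias vectors of a dense network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases) or not self.weights:
            raise ValueError("need equally many (>=1) weight and bias arrays")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.ndim != 2 or b.ndim != 1 or W.shape[1] != b.shape[0]:
                raise ValueError(f"layer {l}: weight/bias shapes inconsistent")
            if l and self.weights[l - 1].shape[1] != W.shape[0]:
                raise ValueError(f"layer {l}: fan-in does not match previous layer")
            if not (np.isfinite(W).all() and np.isfinite(b).all()):
                raise ValueError(f"layer {l}: non-finite parameters")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        """(m_0, m_1, ..., m_L)."""
        return (self.weights[0].shape[0],) + tuple(W.shape[1] for W in self.weights)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_weight_params(self) -> int:
        return sum(W.size for W in self.weights)

    def copy(self) -> "ModelParams":
        return ModelParams(
            weights=[W.copy() for W in self.weights],
            biases=[b.copy() for b in self.biases],
        )


@dataclass
class TrainConfig:
    """Hyperparameters for one local training loop."""

    learning_rate: float = 0.01
    batch_size: int = 32
    epochs_per_loop: int = 5
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class GradientSet:
    """Per-layer weight deltas accumulated over one local loop
    (weights after the loop minus weights before)."""

    deltas: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        for l, G in enumerate(self.deltas):
            if not np.isfinite(G).all():
                raise ValueError(f"layer {l}: non-finite gradient entries")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.deltas[0].shape[0],) + tuple(G.shape[1] for G in self.deltas)


def init_model(layer_sizes: tuple[int, ...], seed: int = 0) -> ModelParams:
    """Initialise with zero-mean Gaussian weights scaled by 1/sqrt(fan-in)
    and zero biases; deterministic given ``seed``."""
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2 or any(s < 1 for s in sizes):
        raise ValueError("layer_sizes needs >= 2 positive entries")
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, 1.0 / np.sqrt(sizes[l]), size=(sizes[l], sizes[l + 1]))
        for l in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]
    return ModelParams(weights=weights, biases=biases)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_pass(
    model: ModelParams,
    X: np.ndarray,
    dropout_mask: np.ndarray | None,
    keep_prob: float,
):
    """Run the network, returning scores, post-activation hidden outputs
    and pre-activations (needed by backprop).

    Dropout, when a mask is supplied, applies to the *last hidden layer*
    with inverted scaling 1/keep_prob.
    """
    L = model.n_layers
    hidden: list[np.ndarray] = []
    pre: list[np.ndarray] = []
    A = X
    for l in range(L - 1):
        Z = A @ model.weights[l] + model.biases[l]
        A = np.maximum(Z, 0.0)
        if dropout_mask is not None and l == L - 2:
            A = A * dropout_mask / keep_prob
        pre.append(Z)
        hidden.append(A)
    Z = A @ model.weights[-1] + model.biases[-1]
    scores = _sigmoid(Z[:, 0]) if Z.shape[1] == 1 else _sigmoid(Z)
    return scores, hidden, pre


def forward(
    model: ModelParams,
    features: np.ndarray,
    mode: str = "eval",
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass.

    Returns ``(scores, hidden_activations)`` where scores lie in (0, 1) and
    hidden_activations are the post-ReLU layer outputs (used for APoZ). In
    ``train`` mode a dropout mask drawn from ``seed`` is applied to the last
    hidden layer with inverted scaling; in ``eval`` mode dropout is a no-op.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"features have width {X.shape[-1]}, model expects {model.layer_sizes[0]}"
        )
    if mode not in ("train", "eval"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = None
    keep = 1.0
    if mode == "train" and dropout_rate > 0.0 and model.n_layers >= 2:
        keep = 1.0 - dropout_rate
        rng = np.random.default_rng(seed)
        mask = (rng.random((X.shape[0], model.layer_sizes[-2])) < keep).astype(np.float64)
    scores, hidden, _ = _forward_pass(model, X, mask, keep)
    return scores, hidden


def cross_entropy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy; scores clipped away from {0, 1}."""
    p = np.clip(scores, _EPS, 1.0 - _EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def _backward(
    model: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    dropout_mask: np.ndarray | None,
    keep_prob: float,
):
    """Gradients of mean BCE w.r.t. every weight and bias."""
    L = model.n_layers
    scores, hidden, pre = _forward_pass(model, X, dropout_mask, keep_prob)
    n = X.shape[0]
    acts = [X] + hidden
    dW = [None] * L
    db = [None] * L
    # d(mean BCE)/dZ_L for sigmoid output is (p - y)/n
    delta = ((scores - y) / n)[:, None]
    for l in range(L - 1, -1, -1):
        dW[l] = acts[l].T @ delta
        db[l] = delta.sum(axis=0)
        if l:
            dA = delta @ model.weights[l].T
            if dropout_mask is not None and l - 1 == L - 2:
                dA = dA * dropout_mask / keep_prob
            delta = dA * (pre[l - 1] > 0.0)
    return dW, db, scores


def train_local(
    model: ModelParams, shard: Cohort, cfg: TrainConfig
) -> tuple[ModelParams, GradientSet]:
    """Train a copy of ``model`` on one client shard for
    ``cfg.epochs_per_loop`` epochs of mini-batch SGD on binary
    cross-entropy, shuffling each epoch with the seeded RNG.

    Returns the updated model and the weight-delta gradient set
    (updated minus original); the input model is never modified.
    """
    if shard.n_samples == 0:
        raise ValueError("cannot train on an empty shard")
    updated = model.copy()
    rng = np.random.default_rng(cfg.seed)
    X_all, y_all = shard.features, shard.labels
    n = shard.n_samples
    keep = 1.0 - cfg.dropout_rate

    for epoch in range(cfg.epochs_per_loop):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            X, y = X_all[batch], y_all[batch]
            mask = None
            if cfg.dropout_rate > 0.0 and updated.n_layers >= 2:
                mask = (
                    rng.random((X.shape[0], updated.layer_sizes[-2])) < keep
                ).astype(np.float64)
            dW, db, scores = _backward(updated, X, y, mask, keep)
            loss = cross_entropy(scores, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            for l in range(updated.n_layers):
                updated.weights[l] -= cfg.learning_rate * dW[l]
                updated.biases[l] -= cfg.learning_rate * db[l]

    deltas = [Wn - Wo for Wn, Wo in zip(updated.weights, model.weights)]
    return updated, GradientSet(deltas=deltas)


def evaluate_scores(model: ModelParams, cohort: Cohort) -> np.ndarray:
    """Eval-mode scores, order-aligned with the cohort's rows."""
    scores, _ = forward(model, cohort.features, mode="eval")
    return scores


def save_model(model: ModelParams, path: str | Path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_model(path: str | Path) -> ModelParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')!r}")
    return ModelParams(
        weights=[np.asarray(W, dtype=np.float64) for W in payload["weights"]],
        biases=[np.asarray(b, dtype=np.float64) for b in payload["biases"]],
    )
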