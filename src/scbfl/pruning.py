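"""Structured neuron pruning by average percentage of zeros (APoZ).

A hidden neuron whose ReLU activation is zero on most validation examples
contributes little downstream; APoZ(c) is the fraction of validation
examples on which neuron c's activation is exactly zero. Pruning removes
the neurons with the globally highest APoZ — a fixed percentage of the
neurons remaining at each global loop, until a target fraction of the
original neurons is gone. Removal is structural: the neuron's incoming
weight column, outgoing weight row and bias entry are deleted, which is
exactly equivalent to forcing its activation to zero.

The server decides the prune on the central validation set and broadcasts
keep-masks; clients apply identical masks so gradient shapes stay
congruent. Only hidden neurons are pruned: input features and the output
unit are always retained, and no layer is ever emptied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import floor
from pathlib import Path

import numpy as np

from .data import Cohort
from .nn import ModelParams, forward

__all__ = [
    "APoZTable",
    "PruneState",
    "init_prune_state",
    "compute_apoz",
    "prune_step",
    "apply_mask",
    "save_prune_state",
]


@dataclass
class APoZTable:
    """Per-hidden-layer APoZ vectors on the current (possibly shrunken) model."""

    values: list[np.ndarray]
    n_examples: int
    output_dim: int = 1  # dense-layer activations are scalar

    def __post_init__(self) -> None:
        for l, v in enumerate(self.values):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"hidden layer {l}: APoZ outside [0, 1]")


@dataclass
class PruneState:
    """Keep-masks over ORIGINAL hidden-neuron indices plus the schedule.

    ``index_maps[l]`` lists, in current order, the original index of every
    surviving neuron of hidden layer l. ``step_keep`` records the
    current-position keep indices of the most recent prune step so that
    models at the *previous* size (e.g. clients that trained before the
    prune) can be brought into line.
    """

    keep_masks: list[np.ndarray]
    original_hidden_sizes: tuple[int, ...]
    rate_per_loop: float
    total_fraction: float
    step_keep: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        for l, m in enumerate(self.keep_masks):
            if m.dtype != np.bool_ or m.shape != (self.original_hidden_sizes[l],):
                raise ValueError(f"hidden layer {l}: malformed keep mask")
            if not m.any():
                raise ValueError(f"hidden layer {l}: every layer must keep >= 1 neuron")

    @property
    def index_maps(self) -> list[np.ndarray]:
        return [np.flatnonzero(m) for m in self.keep_masks]

    @property
    def original_total(self) -> int:
        return int(sum(self.original_hidden_sizes))

    @property
    def remaining_total(self) -> int:
        return int(sum(m.sum() for m in self.keep_masks))

    @property
    def pruned_total(self) -> int:
        return self.original_total - self.remaining_total

    @property
    def target_total(self) -> int:
        return floor(self.total_fraction * self.original_total)

    @property
    def target_reached(self) -> bool:
        return self.pruned_total >= self.target_total

    def copy(self) -> "PruneState":
        return PruneState(
            keep_masks=[m.copy() for m in self.keep_masks],
            original_hidden_sizes=self.original_hidden_sizes,
            rate_per_loop=self.rate_per_loop,
            total_fraction=self.total_fraction,
            step_keep=None if self.step_keep is None else [k.copy() for k in self.step_keep],
        )


def init_prune_state(
    hidden_sizes: tuple[int, ...],
    rate_per_loop: float = 0.10,
    total_fraction: float = 0.47,
) -> PruneState:
    if not 0.0 < rate_per_loop <= 1.0 or not 0.0 <= total_fraction < 1.0:
        raise ValueError("need rate_per_loop in (0,1] and total_fraction in [0,1)")
    return PruneState(
        keep_masks=[np.ones(int(m), dtype=bool) for m in hidden_sizes],
        original_hidden_sizes=tuple(int(m) for m in hidden_sizes),
        rate_per_loop=rate_per_loop,
        total_fraction=total_fraction,
    )


def compute_apoz(model: ModelParams, validation: Cohort) -> APoZTable:
    """APoZ of every hidden neuron on the validation set.

    An eval-mode forward pass over all N validation examples; a neuron's
    APoZ is the count of examples whose post-ReLU activation is exactly
    zero, divided by M*N with M = 1 for scalar dense activations. The
    output layer is excluded.
    """
    if validation is None or validation.n_samples == 0:
        raise ValueError("APoZ needs a non-empty validation set")
    _, hidden = forward(model, validation.features, mode="eval")
    values = [(A == 0.0).mean(axis=0) for A in hidden]
    return APoZTable(values=values, n_examples=validation.n_samples)


def _slice_model(model: ModelParams, keep_current: list[np.ndarray]) -> ModelParams:
    """Structurally remove hidden neurons given current-position keep indices."""
    weights = [W.copy() for W in model.weights]
    biases = [b.copy() for b in model.biases]
    for l, keep in enumerate(keep_current):
        weights[l] = weights[l][:, keep]
        biases[l] = biases[l][keep]
        weights[l + 1] = weights[l + 1][keep, :]
    return ModelParams(weights=weights, biases=biases)


def prune_step(
    model: ModelParams, state: PruneState, apoz: APoZTable
) -> tuple[ModelParams, PruneState]:
    """Remove one loop's worth of the highest-APoZ hidden neurons.

    The step size is k = min(max(1, floor(rate_per_loop * remaining)),
    neurons still owed to the target). Ranking is global across hidden
    layers, highest APoZ first (ties broken by layer then index for
    determinism); a layer's last surviving neuron is skipped and the
    next-ranked taken instead. When the target is already reached the
    call is a no-op returning the inputs unchanged (compare
    ``state.pruned_total`` to detect it).
    """
    n_hidden = len(state.keep_masks)
    if len(apoz.values) != n_hidden:
        raise ValueError("APoZ table does not match the model's hidden layers")
    budget = state.target_total - state.pruned_total
    if budget <= 0:
        return model, state

    remaining = state.remaining_total
    k = min(max(1, floor(state.rate_per_loop * remaining)), budget)

    candidates = [
        (float(apoz.values[l][c]), l, int(c))
        for l in range(n_hidden)
        for c in range(len(apoz.values[l]))
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    layer_left = [int(m.sum()) for m in state.keep_masks]
    to_remove: list[set[int]] = [set() for _ in range(n_hidden)]
    taken = 0
    for _, l, c in candidates:
        if taken == k:
            break
        if layer_left[l] <= 1:
            continue  # never empty a layer
        to_remove[l].add(c)
        layer_left[l] -= 1
        taken += 1

    new_state = state.copy()
    keep_current = []
    index_maps = state.index_maps
    for l in range(n_hidden):
        cur = np.array(
            [i for i in range(len(apoz.values[l])) if i not in to_remove[l]],
            dtype=np.intp,
        )
        keep_current.append(cur)
        dropped_original = index_maps[l][sorted(to_remove[l])]
        new_state.keep_masks[l][dropped_original] = False
    new_state.step_keep = keep_current

    return _slice_model(model, keep_current), new_state


def apply_mask(model_any: ModelParams, state: PruneState) -> ModelParams:
    """Shrink a model to the state's surviving neurons.

    Accepts a model at either the ORIGINAL hidden sizes (slices it down)
    or the current pruned sizes (returned unchanged — idempotent).
    """
    hidden = model_any.layer_sizes[1:-1]
    current = tuple(int(m.sum()) for m in state.keep_masks)
    if hidden == current:
        return model_any
    if hidden == state.original_hidden_sizes:
        return _slice_model(model_any, state.index_maps)
    raise ValueError(
        f"model hidden sizes {hidden} match neither original "
        f"{state.original_hidden_sizes} nor current {current}"
    )


def save_prune_state(state: PruneState, path: str | Path) -> None:
    payload = {
        "keep_masks": [m.astype(int).tolist() for m in state.keep_masks],
        "original_hidden_sizes": list(state.original_hidden_sizes),
        "schedule": {
            "rate_per_loop": state.rate_per_loop,
            "total_fraction": state.total_fraction,
        },
        "pruned_total": state.pruned_total,
        "original_total": state.original_total,
    }
    Path(path).write_text(json.dumps(payload) + "\n")
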