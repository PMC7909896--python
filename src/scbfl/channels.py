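"""Channel-norm gradient sparsification — the upload algorithm.

A *channel* is a path through the network identified by one neuron per
layer, (t_1, ..., t_L) — the artificial analogue of a neural circuit. The
parameters a channel carries are, by convention, the full input-weight
column feeding its first-layer neuron plus one inter-layer edge for each
subsequent layer; distinct channels therefore share parameters (all channels
with the same t_1 share that input column).

Each client, after a local training loop, computes the Euclidean norm of its
weight-delta gradient over every channel, stores them in an L-dimensional
tensor of shape (m_1, ..., m_L), thresholds at the top-alpha rank, and
uploads only the gradient entries lying on selected channels; everything
else is zeroed. Bias deltas are never uploaded.

Indices here are 0-based throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np

from .nn import GradientSet

__all__ = [
    "ChannelNormTensor",
    "ProcessedGradient",
    "channel_entry_set",
    "channel_norms",
    "selection_threshold",
    "process_gradients",
    "save_processed_gradient",
    "load_processed_gradient",
]


@dataclass
class ChannelNormTensor:
    """Euclidean channel norms in an L-dimensional tensor of shape
    (m_1, ..., m_L); ``alpha`` and ``threshold`` are filled once a
    selection cutoff has been computed."""

    norms: np.ndarray
    alpha: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.norms < 0):
            raise ValueError("channel norms must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.norms.size


@dataclass
class ProcessedGradient:
    """The sparse gradient actually uploaded (G-tilde).

    ``deltas`` match the source gradient's shapes with entries off selected
    channels zeroed; ``masks`` are the per-position boolean selection maps
    (a selected position can still carry an exact-zero gradient value).
    """

    deltas: list[np.ndarray]
    masks: list[np.ndarray]
    selected_channels: set[tuple[int, ...]]
    channel_fraction: float
    parameter_fraction: float
    alpha: float = 1.0
    mode: str = "positive"

    @property
    def n_uploaded_entries(self) -> int:
        """Count of parameter values actually communicated (nonzeros of G-tilde)."""
        return int(sum(np.count_nonzero(G) for G in self.deltas))


def channel_entry_set(
    channel: tuple[int, ...], layer_sizes: tuple[int, ...]
) -> set[tuple[int, int, int]]:
    """Weight positions carried by one channel, as (layer, row, col) triples
    with 0-based indices (layer 0 is the input weight matrix).

    Channel (t_1, ..., t_L) owns the whole input column into t_1 —
    {(0, i, t_1) for every input i} — plus the single edge
    (l, t_l, t_{l+1}) for each later layer; the set has m_0 + (L-1)
    elements.
    """
    sizes = tuple(int(s) for s in layer_sizes)
    L = len(sizes) - 1
    if len(channel) != L:
        raise ValueError(f"channel must have {L} indices, got {len(channel)}")
    for l, t in enumerate(channel):
        if not 0 <= t < sizes[l + 1]:
            raise IndexError(f"channel index {t} out of range for layer {l + 1}")
    entries = {(0, i, channel[0]) for i in range(sizes[0])}
    for l in range(1, L):
        entries.add((l, channel[l - 1], channel[l]))
    return entries


def channel_norms(gradient: GradientSet) -> ChannelNormTensor:
    """Euclidean norm of the gradient over every channel.

    The squared norm decomposes into one term per layer — the summed squared
    input column for t_1 plus one squared edge per later layer — so the full
    tensor is a broadcast sum of L arrays rather than a loop over channels.
    """
    G = gradient.deltas
    L = len(G)
    hidden_shape = tuple(g.shape[1] for g in G)  # (m_1, ..., m_L)
    sq = np.zeros(hidden_shape)
    # input-column term, varies only along t_1
    col = (G[0] ** 2).sum(axis=0)
    sq += col.reshape((hidden_shape[0],) + (1,) * (L - 1))
    # one edge term per later layer, varies along (t_l, t_{l+1})
    for l in range(1, L):
        term = G[l] ** 2
        shape = (1,) * (l - 1) + term.shape + (1,) * (L - 1 - l)
        sq += term.reshape(shape)
    return ChannelNormTensor(norms=np.sqrt(sq))


def selection_threshold(norm_tensor: ChannelNormTensor, alpha: float) -> float:
    """Descending-rank cutoff: the value at rank ceil(alpha * K) of the
    sorted channel norms, so at least that many channels satisfy
    norm >= threshold (exactly that many when norms are distinct)."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    K = norm_tensor.n_channels
    if K == 0:
        raise ValueError("empty norm tensor")
    k = ceil(alpha * K)
    flat = np.sort(norm_tensor.norms.ravel())[::-1]
    threshold = float(flat[k - 1])
    norm_tensor.alpha = float(alpha)
    norm_tensor.threshold = threshold
    return threshold


def process_gradients(
    gradient: GradientSet, alpha: float, mode: str = "positive"
) -> ProcessedGradient:
    """Sparsify a gradient set by channel-norm rank.

    ``positive`` keeps the entries of channels whose norm is at or above the
    top-alpha threshold and zeroes the rest; ``negative`` discards the
    channels strictly below that threshold and keeps the remainder. Ties at
    the threshold are kept inclusively in both modes, so the selected count
    is exactly ceil(alpha * K) when norms are distinct and can exceed it
    under ties. Bias deltas never appear: uploads cover weights only.
    """
    if mode not in ("positive", "negative"):
        raise ValueError(f"mode must be 'positive' or 'negative', got {mode!r}")
    tensor = channel_norms(gradient)
    threshold = selection_threshold(tensor, alpha)
    # under inclusive ties, keeping norm >= threshold and discarding
    # norm < threshold coincide; both modes share the selection map
    sel = tensor.norms >= threshold

    G = gradient.deltas
    L = len(G)
    masks: list[np.ndarray] = []
    # layer 0: whole input column t_1 is on every channel through t_1
    col_sel = sel.any(axis=tuple(range(1, L))) if L > 1 else sel
    masks.append(np.broadcast_to(col_sel, G[0].shape).copy())
    for l in range(1, L):
        other = tuple(ax for ax in range(L) if ax not in (l - 1, l))
        edge_sel = sel.any(axis=other) if other else sel
        masks.append(edge_sel.copy())

    deltas = [g * m for g, m in zip(G, masks)]
    selected = {tuple(int(i) for i in ix) for ix in np.argwhere(sel)}
    total_entries = sum(g.size for g in G)
    nonzero = sum(int(np.count_nonzero(d)) for d in deltas)
    return ProcessedGradient(
        deltas=deltas,
        masks=[m.astype(bool) for m in masks],
        selected_channels=selected,
        channel_fraction=float(sel.sum() / sel.size),
        parameter_fraction=float(nonzero / total_entries),
        alpha=float(alpha),
        mode=mode,
    )


def save_processed_gradient(pg: ProcessedGradient, path: str | Path) -> None:
    """Serialize as a sparse (layer, row, col, value) triplet list — the
    simulated wire format whose length is the upload-volume accounting."""
    triplets = []
    for l, d in enumerate(pg.deltas):
        for r, c in np.argwhere(d != 0.0):
            triplets.append([int(l), int(r), int(c), float(d[r, c])])
    payload = {
        "alpha": pg.alpha,
        "mode": pg.mode,
        "channel_fraction": pg.channel_fraction,
        "parameter_fraction": pg.parameter_fraction,
        "layer_shapes": [list(d.shape) for d in pg.deltas],
        "entries": triplets,
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def load_processed_gradient(path: str | Path) -> list[np.ndarray]:
    """Rebuild the dense per-layer delta matrices from the wire format."""
    payload = json.loads(Path(path).read_text())
    deltas = [np.zeros(tuple(s)) for s in payload["layer_shapes"]]
    for l, r, c, v in payload["entries"]:
        deltas[l][r, c] = v
    return deltas
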