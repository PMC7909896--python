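"""Client-server orchestration: SCBFL and the federated-averaging baseline.

One *global loop* is: every client downloads the server weights, trains
locally for a few epochs, and uploads either a channel-sparsified gradient
(SCBFL) or its full weights (FedAvg); the server aggregates, optionally
prunes on the central validation set, and is scored on the test set.

Aggregation for SCBFL averages, at each weight position, over the clients
that selected that position, then scales by the decay rate before adding to
the server weights — with a single client and decay 1 this reduces to the
literal "add the processed gradient to the server weights". Biases are
never uploaded: clients train and keep their own, and the server's stay at
initialisation, so a download never overwrites a client's learned biases.

Everything is synchronous, full-participation and deterministic given the
master seed (client c at loop t trains with seed master_seed + c + t * n_clients).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import ProcessedGradient, process_gradients
from .data import FederationSplit
from .metrics import UploadAccountant, auc_pr, auc_roc, upload_fraction
from .nn import GradientSet, ModelParams, TrainConfig, evaluate_scores, init_model, train_local
from .pruning import PruneState, _slice_model, compute_apoz, init_prune_state, prune_step

__all__ = [
    "FederationConfig",
    "RunLog",
    "server_update",
    "client_sync",
    "average_weights",
    "run_scbfl",
    "run_fedavg",
    "run_federation",
]


@dataclass
class FederationConfig:
    """Everything one federated run needs.

    Defaults follow the reference distributed-learning setting: 5 clients,
    a 64-32-1 network, update rate alpha = 0.30, decay 0.8, full download,
    100 global loops of 5 local epochs at batch size 32, and — when pruning
    is enabled — 10% of the remaining neurons per loop until 47% of the
    original hidden neurons are gone.
    """

    n_clients: int = 5
    hidden_sizes: tuple[int, ...] = (64, 32)
    global_loops: int = 100
    alpha: float = 0.30
    decay: float = 0.8
    download_rate: float = 1.0
    selection_mode: str = "positive"
    algorithm: str = "scbfl"
    pruning_enabled: bool = False
    prune_rate_per_loop: float = 0.10
    prune_total_fraction: float = 0.47
    train: TrainConfig = field(default_factory=TrainConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must lie in (0, 1]")
        if self.download_rate != 1.0:
            raise ValueError("only full download (download_rate = 1.0) is implemented")
        if self.algorithm not in ("scbfl", "fedavg"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.selection_mode not in ("positive", "negative"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.n_clients < 1 or self.global_loops < 0:
            raise ValueError("need n_clients >= 1 and global_loops >= 0")


@dataclass
class RunLog:
    """One record per completed global loop, plus run-level accounting."""

    records: list[dict] = field(default_factory=list)
    cumulative_uploaded_entries: int = 0

    def append(self, record: dict) -> None:
        self.records.append(record)

    @property
    def n_loops(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def final(self) -> dict:
        if not self.records:
            raise ValueError("empty run log")
        return self.records[-1]


def server_update(
    server: ModelParams, uploads: list[ProcessedGradient], decay: float
) -> ModelParams:
    """Aggregate sparse uploads into a new server model.

    At each weight position, the update is the mean of the values from the
    clients that *selected* that position (positions selected by nobody are
    untouched), scaled by ``decay``. Biases are never modified.
    """
    out = server.copy()
    if not uploads:
        return out
    for pg in uploads:
        for d, W in zip(pg.deltas, server.weights):
            if d.shape != W.shape:
                raise ValueError(
                    "upload shape does not match the server model "
                    "(was a prune mask missed?)"
                )
    for l in range(server.n_layers):
        total = np.zeros_like(server.weights[l])
        count = np.zeros_like(server.weights[l])
        for pg in uploads:
            total += pg.deltas[l]
            count += pg.masks[l]
        np.divide(total, count, out=total, where=count > 0)
        out.weights[l] += decay * total
    return out


def average_weights(models: list[ModelParams]) -> list[np.ndarray]:
    """Per-layer arithmetic mean of the models' weight matrices — the
    federated-averaging aggregation step (shards are equal-sized by
    construction, so the mean is unweighted)."""
    if not models:
        raise ValueError("need at least one model to average")
    n_layers = models[0].n_layers
    return [np.mean([m.weights[l] for m in models], axis=0) for l in range(n_layers)]


def client_sync(client: ModelParams, server: ModelParams) -> ModelParams:
    """Download: replace the client's weights with the server's, keeping
    the client's own (locally trained, never uploaded) biases."""
    for Wc, Ws in zip(client.weights, server.weights):
        if Wc.shape != Ws.shape:
            raise ValueError("client and server shapes disagree")
    return ModelParams(
        weights=[W.copy() for W in server.weights],
        biases=[b.copy() for b in client.biases],
    )


def _client_seed(master_seed: int, client: int, loop: int, n_clients: int) -> int:
    return int(master_seed + client + loop * n_clients)


def _score_server(server: ModelParams, split: FederationSplit):
    if split.test is None:
        return float("nan"), float("nan")
    scores = evaluate_scores(server, split.test)
    return auc_roc(scores, split.test.labels), auc_pr(scores, split.test.labels)


def _run(split: FederationSplit, cfg: FederationConfig) -> tuple[ModelParams, RunLog]:
    if len(split.client_shards) != cfg.n_clients:
        raise ValueError(
            f"split has {len(split.client_shards)} shards, config expects {cfg.n_clients}"
        )
    for c, shard in enumerate(split.client_shards):
        if shard.n_samples == 0:
            raise ValueError(f"client {c} has an empty shard")

    n_features = split.client_shards[0].n_features
    sizes = (n_features, *cfg.hidden_sizes, 1)
    server = init_model(sizes, seed=cfg.master_seed)
    clients = [server.copy() for _ in range(cfg.n_clients)]
    original_params = server.n_weight_params

    state: PruneState | None = None
    if cfg.pruning_enabled:
        if split.validation is None:
            raise ValueError("pruning needs a validation set")
        state = init_prune_state(
            cfg.hidden_sizes, cfg.prune_rate_per_loop, cfg.prune_total_fraction
        )

    log = RunLog()
    accountant = UploadAccountant()

    for loop in range(cfg.global_loops):
        seeds = [
            _client_seed(cfg.master_seed, c, loop, cfg.n_clients)
            for c in range(cfg.n_clients)
        ]
        uploads: list[ProcessedGradient] = []
        fractions: list[float] = []
        loop_entries = 0

        for c in range(cfg.n_clients):
            clients[c] = client_sync(clients[c], server)
            cfg_c = replace(cfg.train, seed=seeds[c])
            clients[c], grad = train_local(clients[c], split.client_shards[c], cfg_c)
            if cfg.algorithm == "scbfl":
                pg = process_gradients(grad, cfg.alpha, cfg.selection_mode)
                uploads.append(pg)
                fractions.append(upload_fraction(pg, server))
                loop_entries += pg.n_uploaded_entries
            else:  # fedavg uploads full weight matrices
                loop_entries += server.n_weight_params
                fractions.append(1.0)

        if cfg.algorithm == "scbfl":
            server = server_update(server, uploads, cfg.decay)
        else:
            server = ModelParams(
                weights=average_weights(clients),
                biases=[b.copy() for b in server.biases],
            )

        pruned_this_loop = 0
        if state is not None and not state.target_reached:
            apoz = compute_apoz(server, split.validation)
            before = state.pruned_total
            server, state = prune_step(server, state, apoz)
            pruned_this_loop = state.pruned_total - before
            if pruned_this_loop and state.step_keep is not None:
                clients = [_slice_model(cl, state.step_keep) for cl in clients]

        accountant.record(loop_entries)
        roc, pr = _score_server(server, split)
        log.append(
            {
                "loop": loop,
                "auc_roc": roc,
                "auc_pr": pr,
                "mean_upload_fraction": float(np.mean(fractions)),
                "uploaded_entries": loop_entries,
                "cumulative_uploaded_entries": accountant.cumulative_entries,
                "neurons_remaining": (
                    state.remaining_total if state is not None else sum(cfg.hidden_sizes)
                ),
                "pruned_this_loop": pruned_this_loop,
                "weight_params": server.n_weight_params,
                "original_weight_params": original_params,
                "client_seeds": tuple(seeds),
            }
        )

    log.cumulative_uploaded_entries = accountant.cumulative_entries
    return server, log


def run_scbfl(split: FederationSplit, cfg: FederationConfig) -> tuple[ModelParams, RunLog]:
    """Channel-sparsified federated learning (optionally with pruning)."""
    if cfg.algorithm != "scbfl":
        raise ValueError("cfg.algorithm must be 'scbfl'")
    return _run(split, cfg)


def run_fedavg(split: FederationSplit, cfg: FederationConfig) -> tuple[ModelParams, RunLog]:
    """Federated averaging baseline: full-weight uploads, server = mean."""
    if cfg.algorithm != "fedavg":
        raise ValueError("cfg.algorithm must be 'fedavg'")
    return _run(split, cfg)


def run_federation(split: FederationSplit, cfg: FederationConfig) -> tuple[ModelParams, RunLog]:
    """Dispatch on ``cfg.algorithm``."""
    return run_scbfl(split, cfg) if cfg.algorithm == "scbfl" else run_fedavg(split, cfg)
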