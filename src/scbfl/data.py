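"""Synthetic clinical-style cohorts and federation splits.

The simulator is exercised on cohorts that mimic the statistical structure of
hospital medication/mortality data: each sample is an admission, each feature a
binary medication-exposure indicator (most medications are rare, so the design
matrix is sparse), and the label a binary survival outcome. Outcomes are drawn
from a logistic-linear model in the binary features, which keeps the learning
problem honest (an MLP can learn it, and a plain logistic fit can verify it).

Cohorts can also be written to / read from plain CSV so user-supplied data can
be fed to the federation instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "FederationSplit",
    "generate_cohort",
    "split_federation",
    "write_cohort_csv",
    "read_cohort_csv",
]


@dataclass
class Cohort:
    """A binary-feature cohort with a binary outcome label.

    Attributes
    ----------
    features : ndarray of shape (n_samples, n_features), entries in {0, 1}
        Exposure indicators (e.g. one column per medication).
    labels : ndarray of shape (n_samples,), entries in {0, 1}
        Outcome (1 = event, e.g. death).
    feature_prevalence : ndarray of shape (n_features,) or None
        Per-feature Bernoulli rates used by the generator (None for cohorts
        loaded from file).
    truth : dict or None
        Generating coefficients ``{"intercept": float, "effects": ndarray}``
        kept for diagnostics; None for real data.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_prevalence: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on n_samples")
        if self.features.shape[0] == 0:
            raise ValueError("cohort must contain at least one sample")
        if not np.isin(self.features, (0.0, 1.0)).all():
            raise ValueError("feature entries must be 0/1")
        if not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("labels must be 0/1")
        if self.feature_prevalence is not None:
            prev = np.asarray(self.feature_prevalence, dtype=np.float64)
            if np.any(prev <= 0.0) or np.any(prev >= 1.0):
                raise ValueError("prevalence entries must lie in (0, 1)")
            self.feature_prevalence = prev

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "Cohort":
        """Row-subset view (copies) sharing prevalence/truth metadata."""
        idx = np.asarray(indices, dtype=np.intp)
        return Cohort(
            features=self.features[idx].copy(),
            labels=self.labels[idx].copy(),
            feature_prevalence=self.feature_prevalence,
            truth=self.truth,
        )


@dataclass
class FederationSplit:
    """Train/validation/test partition with the training rows sharded to clients."""

    client_shards: list[Cohort]
    validation: Cohort | None
    test: Cohort | None
    split_fractions: tuple[float, float, float]
    shard_indices: list[np.ndarray] = field(default_factory=list)
    validation_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    test_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    @property
    def n_clients(self) -> int:
        return len(self.client_shards)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def generate_cohort(
    n_samples: int,
    n_features: int,
    n_informative: int,
    base_log_odds: float = -1.5,
    effect_scale: float = 1.0,
    prevalence_shape: tuple[float, float] = (0.3, 3.0),
    seed: int = 0,
) -> Cohort:
    """Generate a sparse binary-feature cohort with a logistic outcome.

    Per-feature prevalences are drawn from a right-skewed Beta distribution
    (default Beta(0.3, 3.0), clipped to [0.001, 0.5]) so most features are
    rare, as medication exposures are. ``n_informative`` features receive a
    nonzero logistic coefficient of magnitude ``effect_scale`` with random
    sign; labels are Bernoulli(sigmoid(base_log_odds + x . beta)).

    The same (arguments, seed) pair always yields a bit-identical cohort.
    """
    if n_samples < 1 or n_features < 1:
        raise ValueError("n_samples and n_features must be positive")
    if not 0 <= n_informative <= n_features:
        raise ValueError("need 0 <= n_informative <= n_features")
    a, b = prevalence_shape
    if a <= 0 or b <= 0:
        raise ValueError("prevalence_shape parameters must be positive")

    rng = np.random.default_rng(seed)
    prevalence = np.clip(rng.beta(a, b, size=n_features), 0.001, 0.5)
    X = (rng.random((n_samples, n_features)) < prevalence).astype(np.float64)

    beta = np.zeros(n_features)
    if n_informative:
        idx = rng.choice(n_features, size=n_informative, replace=False)
        beta[idx] = effect_scale * rng.choice((-1.0, 1.0), size=n_informative)

    p = _sigmoid(base_log_odds + X @ beta)
    y = (rng.random(n_samples) < p).astype(np.float64)

    return Cohort(
        features=X,
        labels=y,
        feature_prevalence=prevalence,
        truth={"intercept": float(base_log_odds), "effects": beta},
    )


def split_federation(
    cohort: Cohort,
    n_clients: int = 5,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    shard_skew: float = 0.0,
    seed: int = 0,
) -> FederationSplit:
    """Partition a cohort into client shards, validation and test sets.

    Rows are permuted by ``seed`` and then split ``fractions`` =
    (train, validation, test); validation and test sizes are floored and the
    remainder goes to training, which is divided into ``n_clients`` shards
    whose sizes differ by at most one row.

    ``shard_skew`` in [0, 1] controls label heterogeneity across shards:
    0 gives IID shards; at ``skew`` > 0 that fraction of the training rows is
    laid out label-sorted before contiguous sharding, so shards become
    label-imbalanced (non-IID) as skew approaches 1.
    """
    if n_clients < 1:
        raise ValueError("n_clients must be >= 1")
    if not 0.0 <= shard_skew <= 1.0:
        raise ValueError("shard_skew must lie in [0, 1]")
    fr = np.asarray(fractions, dtype=np.float64)
    if fr.shape != (3,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 non-negative values summing to 1")

    n = cohort.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)

    n_val = int(np.floor(fr[1] * n))
    n_test = int(np.floor(fr[2] * n))
    n_train = n - n_val - n_test
    if n_train < n_clients and n_train > 0:
        raise ValueError(
            f"train partition of {n_train} rows cannot fill {n_clients} shards"
        )

    train_idx = perm[:n_train]
    val_idx = perm[n_train : n_train + n_val]
    test_idx = perm[n_train + n_val :]

    if shard_skew > 0.0 and n_train > 0:
        k = int(np.floor(shard_skew * n_train))
        order = np.argsort(cohort.labels[train_idx], kind="stable")
        sorted_part = train_idx[order][:k]
        rest = np.setdiff1d(train_idx, sorted_part, assume_unique=True)
        train_idx = np.concatenate([sorted_part, rng.permutation(rest)])

    # contiguous shards; the first (n_train mod n_clients) shards get one extra row
    base, extra = divmod(n_train, n_clients)
    shard_indices: list[np.ndarray] = []
    start = 0
    for c in range(n_clients):
        size = base + (1 if c < extra else 0)
        shard_indices.append(np.sort(train_idx[start : start + size]))
        start += size

    shards = [cohort.subset(ix) for ix in shard_indices]
    validation = cohort.subset(val_idx) if n_val else None
    test = cohort.subset(test_idx) if n_test else None

    return FederationSplit(
        client_shards=shards,
        validation=validation,
        test=test,
        split_fractions=tuple(float(f) for f in fr),
        shard_indices=shard_indices,
        validation_indices=np.sort(val_idx),
        test_indices=np.sort(test_idx),
    )


def write_cohort_csv(cohort: Cohort, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a cohort as CSV (header ``f1..fN,label``, 0/1 values).

    If ``sidecar`` is given, it is written next to the CSV as
    ``<path>.json`` recording generator configuration and seed.
    """
    path = Path(path)
    cols = [f"f{i + 1}" for i in range(cohort.n_features)]
    df = pd.DataFrame(cohort.features.astype(np.int64), columns=cols)
    df["label"] = cohort.labels.astype(np.int64)
    df.to_csv(path, index=False)
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort_csv` (or any CSV whose
    last column is named ``label`` and holds 0/1 outcomes)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column")
    y = df.pop("label").to_numpy(dtype=np.float64)
    X = df.to_numpy(dtype=np.float64)
    return Cohort(features=X, labels=y)
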