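"""Experiment configuration: a versioned YAML schema resolving to the
library's dataclasses, with field-level validation messages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .data import Cohort, generate_cohort, read_cohort_csv
from .federation import FederationConfig
from .nn import TrainConfig

__all__ = ["DataConfig", "SweepConfig", "ExperimentConfig", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised with the offending field in the message."""


@dataclass
class DataConfig:
    """Exactly one data source: the synthetic generator or a cohort CSV."""

    csv_path: str | None = None
    n_samples: int = 2000
    n_features: int = 200
    n_informative: int = 20
    base_log_odds: float = -1.5
    effect_scale: float = 3.0
    prevalence_shape: tuple[float, float] = (0.3, 3.0)
    # split
    n_clients: int = 5
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)
    shard_skew: float = 0.0

    def load_cohort(self, seed: int) -> Cohort:
        if self.csv_path is not None:
            return read_cohort_csv(self.csv_path)
        return generate_cohort(
            n_samples=self.n_samples,
            n_features=self.n_features,
            n_informative=self.n_informative,
            base_log_odds=self.base_log_odds,
            effect_scale=self.effect_scale,
            prevalence_shape=self.prevalence_shape,
            seed=seed,
        )


@dataclass
class SweepConfig:
    alphas: list[float] = field(default_factory=list)
    prune_rates: list[float] = field(default_factory=list)
    total_fractions: list[float] = field(default_factory=list)
    seeds: list[int] = field(default_factory=lambda: [0])


@dataclass
class ExperimentConfig:
    data: DataConfig = field(default_factory=DataConfig)
    federation: FederationConfig = field(default_factory=FederationConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    output_dir: str = "results"
    master_seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def resolved(self) -> dict:
        """Full configuration as plain data — written into summaries so a
        run can be reproduced bit-for-bit."""
        d = asdict(self)
        d["federation"]["hidden_sizes"] = list(self.federation.hidden_sizes)
        return d


def _take(section: dict, cls, name: str, **extra):
    """Build a dataclass from a config section, rejecting unknown keys."""
    known = set(cls.__dataclass_fields__)
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"{name}: unknown field(s) {sorted(unknown)}")
    merged = {**section, **extra}
    for key in ("fractions", "prevalence_shape", "hidden_sizes"):
        if key in merged and merged[key] is not None:
            merged[key] = tuple(merged[key])
    try:
        return cls(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load YAML (all sections optional) and apply dotted-key overrides,
    e.g. ``{"federation.alpha": 0.1}``."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded

    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"schema_version: expected {SCHEMA_VERSION}, got {version}")

    for key, value in (overrides or {}).items():
        parts = key.split(".")
        node = raw
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value

    known_sections = {"data", "federation", "sweep", "train", "output_dir", "master_seed"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ConfigError(f"unknown top-level section(s) {sorted(unknown)}")

    train = _take(raw.get("train", {}), TrainConfig, "train")
    fed_section = dict(raw.get("federation", {}))
    fed = _take(fed_section, FederationConfig, "federation", train=train)
    data = _take(raw.get("data", {}), DataConfig, "data")
    sweep = _take(raw.get("sweep", {}), SweepConfig, "sweep")

    return ExperimentConfig(
        data=data,
        federation=fed,
        sweep=sweep,
        output_dir=str(raw.get("output_dir", "results")),
        master_seed=int(raw.get("master_seed", 0)),
    )
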