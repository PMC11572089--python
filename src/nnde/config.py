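"""Run configuration: YAML file and/or overrides, validated against the grid.

An empty config means "replicate the full study grid": every combination of
sample size {50,100,200,500}, IV count {3,5,10}, network shape
{(2),(7),(30),(10,10),(50,50)}, IV distribution {uniform, skewed} and DV type
{continuous, binary_balanced, binary_imbalanced}, at 1000 replications each.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .datagen import ConfigurationError
from .montecarlo import (
    DV_TYPES,
    IV_DISTS,
    N_IVS,
    SAMPLE_SIZES,
    SHAPES,
    Condition,
    replication_grid,
    str_to_shape,
)
from .nnet import NetworkConfig

__all__ = ["RunConfig", "load_config"]

_NN_FIELDS = {f.name for f in dataclasses.fields(NetworkConfig)} - {"hidden_sizes", "task"}

_KNOWN_KEYS = {
    "sample_sizes",
    "n_ivs",
    "shapes",
    "iv_dists",
    "dv_types",
    "reps",
    "base_seed",
    "nn",
    "output",
    "jsonl",
    "n_jobs",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated simulation request: grid filters plus run parameters."""

    sample_sizes: tuple = SAMPLE_SIZES
    n_ivs: tuple = N_IVS
    shapes: tuple = SHAPES
    iv_dists: tuple = IV_DISTS
    dv_types: tuple = DV_TYPES
    reps: int = 1000
    base_seed: int = 1
    nn_overrides: dict = field(default_factory=dict)
    output: str | None = None
    jsonl: str | None = None
    n_jobs: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.sample_sizes = _validate_subset("sample_sizes", self.sample_sizes, SAMPLE_SIZES, int)
        self.n_ivs = _validate_subset("n_ivs", self.n_ivs, N_IVS, int)
        shapes = tuple(
            str_to_shape(s) if isinstance(s, str) else tuple(s) for s in self.shapes
        )
        self.shapes = _validate_subset("shapes", shapes, SHAPES, tuple)
        self.iv_dists = _validate_subset("iv_dists", self.iv_dists, IV_DISTS, str)
        self.dv_types = _validate_subset("dv_types", self.dv_types, DV_TYPES, str)
        if self.reps < 1:
            raise ConfigurationError(f"reps must be >= 1, got {self.reps}")
        unknown_nn = set(self.nn_overrides) - _NN_FIELDS
        if unknown_nn:
            raise ConfigurationError(f"unknown nn override(s): {sorted(unknown_nn)}")

    def conditions(self) -> list[Condition]:
        return replication_grid(
            dv_types=self.dv_types,
            iv_dists=self.iv_dists,
            sample_sizes=self.sample_sizes,
            n_ivs=self.n_ivs,
            shapes=self.shapes,
        )

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(**self.nn_overrides)


def _validate_subset(name, values, allowed, cast):
    values = tuple(cast(v) for v in values)
    if not values:
        raise ConfigurationError(f"{name} must not be empty")
    bad = [v for v in values if v not in allowed]
    if bad:
        raise ConfigurationError(f"{name} contains values outside the grid: {bad}")
    return values


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Unknown keys are rejected with the offending name; an empty file yields
    the full replication defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    nn = data.pop("nn", {}) or {}
    return RunConfig(nn_overrides=dict(nn), **data)
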