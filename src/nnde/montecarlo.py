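"""Condition-grid driver: replications, exclusion accounting, DE proportions.

A *condition* is one cell of the simulation grid (sample size x IV count x
network shape x IV distribution x DV type).  Each replication generates a
fresh null dataset, splits it 80:20, trains the network under the standard
protocol, and scores the test partition against the decision-error criteria.
Excluded replications (constant predictions; single-class test truths) are
removed from both the numerator and the denominator of the DE proportion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import metrics as _metrics
from .datagen import (
    SKEWED_PROBS,
    UNIFORM_PROBS,
    ConfigurationError,
    DatasetSpec,
    generate_dataset,
    split_dataset,
)
from .metrics import (
    BINARY_CRITERIA,
    CONTINUOUS_CRITERIA,
    DECriterion,
    Exclusion,
    MetricsReport,
    evaluate_criteria,
    evaluate_test_set,
)
from .nnet import NetworkConfig, predict, train_network

logger = logging.getLogger(__name__)

__all__ = [
    "SAMPLE_SIZES",
    "N_IVS",
    "SHAPES",
    "IV_DISTS",
    "DV_TYPES",
    "TRAIN_FRACTION",
    "RESULT_COLUMNS",
    "Condition",
    "ReplicationOutcome",
    "ConditionResult",
    "shape_to_str",
    "str_to_shape",
    "replication_grid",
    "derive_seed",
    "run_replication",
    "run_condition",
    "run_grid",
    "compare_to_reference",
]

# The replication grid.
SAMPLE_SIZES = (50, 100, 200, 500)
N_IVS = (3, 5, 10)
SHAPES = ((2,), (7,), (30,), (10, 10), (50, 50))
IV_DISTS = ("uniform", "skewed")
DV_TYPES = ("continuous", "binary_balanced", "binary_imbalanced")
TRAIN_FRACTION = 0.8

RESULT_COLUMNS = [
    "dv_type",
    "iv_dist",
    "sample_size",
    "n_iv",
    "shape",
    "criterion_metric",
    "criterion_threshold",
    "reps",
    "excluded",
    "de_count",
    "de_proportion",
]

_IV_PROBS = {"uniform": UNIFORM_PROBS, "skewed": SKEWED_PROBS}
_DV_RATES = {"binary_balanced": 0.5, "binary_imbalanced": 0.1}


def shape_to_str(shape: tuple[int, ...]) -> str:
    return "(" + ",".join(str(h) for h in shape) + ")"


def str_to_shape(text: str) -> tuple[int, ...]:
    parts = text.strip().strip("()").split(",")
    shape = tuple(int(p) for p in parts if p.strip())
    if not shape:
        raise ConfigurationError(f"cannot parse network shape from {text!r}")
    return shape


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation grid."""

    sample_size: int
    n_iv: int
    shape: tuple[int, ...]
    iv_dist: str
    dv_type: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(h) for h in self.shape))
        if self.iv_dist not in _IV_PROBS:
            raise ConfigurationError(f"iv_dist must be one of {IV_DISTS}, got {self.iv_dist!r}")
        if self.dv_type not in DV_TYPES:
            raise ConfigurationError(f"dv_type must be one of {DV_TYPES}, got {self.dv_type!r}")

    @property
    def task(self) -> str:
        return "regression" if self.dv_type == "continuous" else "classification"

    def dataset_spec(self) -> DatasetSpec:
        if self.dv_type == "continuous":
            return DatasetSpec(
                n_total=self.sample_size, n_iv=self.n_iv,
                iv_probs=_IV_PROBS[self.iv_dist], dv_kind="continuous",
                label=self.iv_dist,
            )
        return DatasetSpec(
            n_total=self.sample_size, n_iv=self.n_iv,
            iv_probs=_IV_PROBS[self.iv_dist], dv_kind="binary",
            dv_positive_rate=_DV_RATES[self.dv_type], label=self.iv_dist,
        )

    def default_criteria(self) -> tuple[DECriterion, ...]:
        return CONTINUOUS_CRITERIA if self.task == "regression" else BINARY_CRITERIA

    def key(self) -> str:
        """Canonical text form; the input to seed derivation and result keys."""
        return (
            f"n={self.sample_size}|k={self.n_iv}|shape={shape_to_str(self.shape)}"
            f"|iv={self.iv_dist}|dv={self.dv_type}"
        )


def replication_grid(
    dv_types=DV_TYPES,
    iv_dists=IV_DISTS,
    sample_sizes=SAMPLE_SIZES,
    n_ivs=N_IVS,
    shapes=SHAPES,
) -> list[Condition]:
    """Full (optionally filtered) factorial list of conditions, in table order."""
    return [
        Condition(sample_size=n, n_iv=k, shape=tuple(shape), iv_dist=dist, dv_type=dv)
        for dv in dv_types
        for dist in iv_dists
        for shape in shapes
        for n in sample_sizes
        for k in n_ivs
    ]


def derive_seed(base_seed: int, condition: Condition, rep_index: int) -> int:
    """Stable, collision-resistant per-replication seed (< 2^31).

    Hashes the canonical condition text plus indices, so any single
    replication can be re-run in isolation from (base_seed, condition, rep).
    """
    if rep_index < 0:
        raise ConfigurationError("rep_index must be nonnegative")
    text = f"{base_seed}|{condition.key()}|rep={rep_index}"
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class ReplicationOutcome:
    """Everything recorded for one simulated fit."""

    condition: Condition
    rep_index: int
    seed: int
    report: MetricsReport
    flags: dict
    best_epoch: int
    stopped_epoch: int

    def to_record(self) -> dict:
        rec = {
            "condition": self.condition.key(),
            "rep_index": self.rep_index,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
            "flags": self.flags,
        }
        rec.update(self.report.to_record())
        return rec


@dataclass
class ConditionResult:
    """Aggregated DE accounting for one grid cell."""

    condition: Condition
    reps_attempted: int
    reps_excluded: int
    de_counts: dict
    criteria: tuple

    @property
    def reps_included(self) -> int:
        return self.reps_attempted - self.reps_excluded

    @property
    def de_proportions(self) -> dict:
        m = self.reps_included
        return {
            label: (count / m if m > 0 else float("nan"))
            for label, count in self.de_counts.items()
        }

    def to_rows(self) -> list[dict]:
        rows = []
        props = self.de_proportions
        for criterion in self.criteria:
            rows.append(
                {
                    "dv_type": self.condition.dv_type,
                    "iv_dist": self.condition.iv_dist,
                    "sample_size": self.condition.sample_size,
                    "n_iv": self.condition.n_iv,
                    "shape": shape_to_str(self.condition.shape),
                    "criterion_metric": criterion.metric,
                    "criterion_threshold": criterion.threshold,
                    "reps": self.reps_attempted,
                    "excluded": self.reps_excluded,
                    "de_count": self.de_counts[criterion.label],
                    "de_proportion": props[criterion.label],
                }
            )
        return rows


def _nn_config_for(condition: Condition, nn_config: NetworkConfig | None) -> NetworkConfig:
    base = nn_config if nn_config is not None else NetworkConfig()
    return dataclasses.replace(base, hidden_sizes=condition.shape, task=condition.task)


def run_replication(
    condition: Condition,
    nn_config: NetworkConfig | None = None,
    seed: int = 0,
    rep_index: int = 0,
    criteria=None,
) -> ReplicationOutcome:
    """One end-to-end simulated fit, fully determined by ``seed``.

    generate -> split 80:20 -> standardize -> train with early stopping ->
    predict on test -> exclusion check -> metrics -> criteria flags.
    """
    config = _nn_config_for(condition, nn_config)
    if criteria is None:
        criteria = condition.default_criteria()
    rng = np.random.default_rng(seed)
    data = generate_dataset(condition.dataset_spec(), rng)
    split = split_dataset(data, TRAIN_FRACTION, rng)
    net, trace, scaler = train_network(split, config, rng)
    scores = predict(net, scaler, split.test.iv_matrix)
    report = evaluate_test_set(split.test.dv_vector, scores, config.task)
    flags = evaluate_criteria(report, criteria)
    return ReplicationOutcome(
        condition=condition,
        rep_index=rep_index,
        seed=seed,
        report=report,
        flags=flags,
        best_epoch=trace.best_epoch,
        stopped_epoch=trace.stopped_epoch,
    )


def run_condition(
    condition: Condition,
    reps: int,
    base_seed: int,
    nn_config: NetworkConfig | None = None,
    criteria=None,
    n_jobs: int = 1,
    jsonl_handle=None,
) -> ConditionResult:
    """Run ``reps`` independent replications of one condition and aggregate.

    Replications are keyed by :func:`derive_seed`, so results are identical
    regardless of execution order or worker count.  Excluded replications are
    dropped from both numerator and denominator.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    if criteria is None:
        criteria = condition.default_criteria()

    def one(rep: int) -> ReplicationOutcome:
        return run_replication(
            condition, nn_config, derive_seed(base_seed, condition, rep), rep, criteria
        )

    if n_jobs == 1:
        outcomes = [one(rep) for rep in range(reps)]
    else:
        outcomes = Parallel(n_jobs=n_jobs)(delayed(one)(rep) for rep in range(reps))

    de_counts = {c.label: 0 for c in criteria}
    excluded = 0
    for outcome in outcomes:
        if jsonl_handle is not None:
            jsonl_handle.write(json.dumps(outcome.to_record()) + "\n")
        if outcome.report.exclusion is not Exclusion.INCLUDED:
            excluded += 1
            continue
        for label, flag in outcome.flags.items():
            de_counts[label] += int(flag)
    if excluded == reps:
        logger.warning("condition %s: all %d replications excluded", condition.key(), reps)
    return ConditionResult(
        condition=condition,
        reps_attempted=reps,
        reps_excluded=excluded,
        de_counts=de_counts,
        criteria=tuple(criteria),
    )


def run_grid(
    conditions,
    reps: int,
    base_seed: int,
    nn_config: NetworkConfig | None = None,
    criteria=None,
    n_jobs: int = 1,
    jsonl_handle=None,
) -> pd.DataFrame:
    """Run every condition and return the long results table.

    ``criteria=None`` applies each condition's task-appropriate default set.
    Deterministic given ``base_seed``; per-condition seeds are isolated, so a
    subset grid reproduces the corresponding cells of the full grid.
    """
    conditions = list(conditions)
    if not conditions:
        raise ConfigurationError("condition list is empty")
    rows = []
    for i, condition in enumerate(conditions):
        result = run_condition(
            condition, reps, base_seed, nn_config, criteria, n_jobs, jsonl_handle
        )
        logger.info(
            "[%d/%d] %s: excluded %d/%d",
            i + 1, len(conditions), condition.key(), result.reps_excluded, reps,
        )
        rows.extend(result.to_rows())
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


_MERGE_KEYS = [
    "dv_type", "iv_dist", "sample_size", "n_iv", "shape",
    "criterion_metric", "criterion_threshold",
]


def compare_to_reference(
    results: pd.DataFrame, fixture: pd.DataFrame, k_sigma: float = 3.0
) -> pd.DataFrame:
    """Cell-by-cell comparison of simulated DE proportions to reference values.

    A cell passes when ``|p_hat - p_ref| <= k_sigma * sqrt(p_ref(1-p_ref)/m)
    + 1/m`` with ``m`` the included replications; the 1/m floor keeps
    printed-zero reference cells testable.  Cells missing from the fixture are
    reported as untestable rather than failed.
    """
    fixture = fixture.rename(columns={"de_proportion": "ref_proportion"})
    merged = results.merge(
        fixture[_MERGE_KEYS + ["ref_proportion"]], on=_MERGE_KEYS, how="left"
    )
    m = (merged["reps"] - merged["excluded"]).astype(float)
    p_ref = merged["ref_proportion"]
    se = np.sqrt(p_ref * (1.0 - p_ref) / m)
    merged["m_included"] = m
    merged["tolerance"] = k_sigma * se + 1.0 / m
    merged["abs_error"] = (merged["de_proportion"] - p_ref).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["z"] = np.where(
            se > 0, (merged["de_proportion"] - p_ref) / se, np.nan
        )
    merged["status"] = np.where(
        p_ref.isna(),
        "untestable",
        np.where(merged["abs_error"] <= merged["tolerance"], "pass", "fail"),
    )
    return merged
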