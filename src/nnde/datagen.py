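"""Null-data generators: ordinal predictors with no population-level link to the outcome.

Datasets emulate Likert-style questionnaire studies: every independent
variable (IV) is a 5-category ordinal item, the dependent variable (DV) is
either a standard-normal score or a Bernoulli label, and IVs and DV are drawn
independently, so any predictive performance measured downstream is pure
sampling artifact.  All sampling is driven by an explicit
``numpy.random.Generator`` so every dataset is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "UNIFORM_PROBS",
    "SKEWED_PROBS",
    "DatasetSpec",
    "TabularDataset",
    "TrainTestSplit",
    "sample_iv_matrix",
    "sample_dv",
    "generate_dataset",
    "split_dataset",
    "independence_audit",
    "sample_signal_dv",
]

#: Ordinal item categories (Likert-style 1..5).
CATEGORIES = np.arange(1, 6)

#: Equal-probability category weights.
UNIFORM_PROBS: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)

#: Right-shifted (skewed) category weights.
SKEWED_PROBS: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.35)

_MIN_AUDIT_N = 10_000


class ConfigurationError(ValueError):
    """Raised when a spec, split, or audit request is invalid."""


@dataclass(frozen=True)
class DatasetSpec:
    """Description of one null data-generating process.

    Parameters
    ----------
    n_total:
        Total sample size before the train/test split (>= 10).
    n_iv:
        Number of ordinal independent variables.
    iv_probs:
        Probabilities of categories 1..5; must sum to 1.
    dv_kind:
        ``"continuous"`` (N(0,1) outcome) or ``"binary"`` (Bernoulli outcome).
    dv_positive_rate:
        P(DV = 1) for binary outcomes; ignored for continuous.
    label:
        Free-text tag (e.g. ``"uniform"``, ``"imbalanced"``).
    """

    n_total: int
    n_iv: int
    iv_probs: tuple[float, ...] = UNIFORM_PROBS
    dv_kind: str = "continuous"
    dv_positive_rate: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_total < 10:
            raise ConfigurationError(f"n_total must be >= 10, got {self.n_total}")
        if self.n_iv < 1:
            raise ConfigurationError(f"n_iv must be >= 1, got {self.n_iv}")
        probs = tuple(float(p) for p in self.iv_probs)
        object.__setattr__(self, "iv_probs", probs)
        _validate_probs(probs)
        if self.dv_kind not in ("continuous", "binary"):
            raise ConfigurationError(f"dv_kind must be 'continuous' or 'binary', got {self.dv_kind!r}")
        if self.dv_kind == "binary" and not (0.0 < self.dv_positive_rate < 1.0):
            raise ConfigurationError(
                f"dv_positive_rate must lie in (0, 1), got {self.dv_positive_rate}"
            )


def _validate_probs(probs: tuple[float, ...]) -> None:
    if len(probs) != len(CATEGORIES):
        raise ConfigurationError(f"iv_probs must have {len(CATEGORIES)} entries, got {len(probs)}")
    if any(p < 0 for p in probs):
        raise ConfigurationError(f"iv_probs must be nonnegative, got {probs}")
    if abs(math.fsum(probs) - 1.0) > 1e-12:
        raise ConfigurationError(f"iv_probs must sum to 1 (got sum {math.fsum(probs)!r})")


@dataclass
class TabularDataset:
    """One realized dataset: an n x k ordinal IV matrix and a length-n DV."""

    iv_matrix: np.ndarray
    dv_vector: np.ndarray
    spec: DatasetSpec

    def __post_init__(self) -> None:
        self.iv_matrix = np.asarray(self.iv_matrix)
        self.dv_vector = np.asarray(self.dv_vector)
        if self.iv_matrix.ndim != 2:
            raise ValueError("iv_matrix must be 2-dimensional")
        if self.iv_matrix.shape[0] != self.dv_vector.shape[0]:
            raise ValueError("iv_matrix and dv_vector row counts differ")
        if self.iv_matrix.size and (
            self.iv_matrix.min() < CATEGORIES[0] or self.iv_matrix.max() > CATEGORIES[-1]
        ):
            raise ValueError("iv_matrix entries must lie in {1,...,5}")

    @property
    def n(self) -> int:
        return self.iv_matrix.shape[0]

    @property
    def n_iv(self) -> int:
        return self.iv_matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"iv_{j + 1}": self.iv_matrix[:, j] for j in range(self.n_iv)}
        cols["dv"] = self.dv_vector
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: DatasetSpec | None = None) -> "TabularDataset":
        frame = pd.read_csv(path)
        iv_cols = [c for c in frame.columns if c.startswith("iv_")]
        if not iv_cols or "dv" not in frame.columns:
            raise ValueError("expected columns iv_1..iv_k and dv")
        iv = frame[iv_cols].to_numpy(dtype=np.int64)
        dv = frame["dv"].to_numpy()
        if spec is None:
            values = np.unique(dv)
            binary = np.isin(values, [0.0, 1.0]).all()
            spec = DatasetSpec(
                n_total=max(len(dv), 10),
                n_iv=iv.shape[1],
                dv_kind="binary" if binary else "continuous",
                dv_positive_rate=float(dv.mean()) if binary else 0.5,
            )
        if spec.dv_kind == "binary":
            dv = dv.astype(np.int64)
        return cls(iv_matrix=iv, dv_vector=dv, spec=spec)


@dataclass
class TrainTestSplit:
    """Random partition of one dataset into a training and a testing portion."""

    train: TabularDataset
    test: TabularDataset
    train_fraction: float


def sample_iv_matrix(
    n: int, k: int, iv_probs, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ``n x k`` matrix of independent ordinal items on {1,...,5}."""
    if n < 1 or k < 1:
        raise ConfigurationError("n and k must be positive")
    probs = tuple(float(p) for p in iv_probs)
    _validate_probs(probs)
    return rng.choice(CATEGORIES, size=(n, k), p=probs)


def sample_dv(n: int, spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw the outcome: N(0,1) draws or Bernoulli(dv_positive_rate) labels."""
    if spec.dv_kind == "continuous":
        return rng.normal(loc=0.0, scale=1.0, size=n)
    p = spec.dv_positive_rate
    return rng.choice(np.array([0, 1]), size=n, p=(1.0 - p, p))


def generate_dataset(spec: DatasetSpec, rng: np.random.Generator) -> TabularDataset:
    """Realize one dataset from a spec: the IV matrix first, then the DV.

    IVs and DV come from the same generator stream but are mutually
    independent draws, so there is no population-level association.
    """
    iv = sample_iv_matrix(spec.n_total, spec.n_iv, spec.iv_probs, rng)
    dv = sample_dv(spec.n_total, spec, rng)
    return TabularDataset(iv_matrix=iv, dv_vector=dv, spec=spec)


def split_dataset(
    data: TabularDataset, train_fraction: float, rng: np.random.Generator
) -> TrainTestSplit:
    """Uniformly random, unstratified partition into train and test rows.

    The training portion holds ``round(train_fraction * n)`` rows; the test
    portion is the remainder and must be non-empty.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    n = data.n
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise ConfigurationError(
            f"split of n={n} at fraction {train_fraction} leaves an empty partition"
        )
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    make = lambda idx: TabularDataset(
        iv_matrix=data.iv_matrix[idx], dv_vector=data.dv_vector[idx], spec=data.spec
    )
    return TrainTestSplit(train=make(train_idx), test=make(test_idx), train_fraction=train_fraction)


def independence_audit(
    spec: DatasetSpec, n_audit: int, rng: np.random.Generator
) -> float:
    """Max |Pearson r| between each IV and the DV on one large audit draw.

    A large-sample check that the generator really is null: at ``n_audit``
    draws the null correlation bound is about ``3 / sqrt(n_audit)``.
    Refuses n_audit below 10^4, where the bound is too loose to be informative.
    """
    if n_audit < _MIN_AUDIT_N:
        raise ConfigurationError(
            f"n_audit={n_audit} is too small for a meaningful audit; use at least {_MIN_AUDIT_N}"
        )
    audit_spec = replace(spec, n_total=n_audit)
    data = generate_dataset(audit_spec, rng)
    dv = data.dv_vector.astype(float)
    max_r = 0.0
    for j in range(data.n_iv):
        r = np.corrcoef(data.iv_matrix[:, j].astype(float), dv)[0, 1]
        max_r = max(max_r, abs(float(r)))
    return max_r


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def sample_signal_dv(
    iv_matrix: np.ndarray,
    effect: float,
    dv_kind: str,
    rng: np.random.Generator,
    positive_rate: float = 0.5,
) -> np.ndarray:
    """Outcome with a real (linear-in-IV1) signal, for power/sanity fixtures.

    Continuous: ``DV = effect * z1 + N(0,1)`` with ``z1`` the standardized
    first IV column.  Binary: ``P(DV=1) = sigmoid(logit(positive_rate) +
    effect * z1)``.  ``effect=0`` reduces to the null generator's
    distribution exactly.
    """
    if effect < 0:
        raise ConfigurationError("effect must be nonnegative")
    iv_matrix = np.asarray(iv_matrix)
    x1 = iv_matrix[:, 0].astype(float)
    sd = x1.std()
    z1 = (x1 - x1.mean()) / sd if sd > 0 else np.zeros_like(x1)
    n = iv_matrix.shape[0]
    if dv_kind == "continuous":
        return effect * z1 + rng.normal(size=n)
    if dv_kind == "binary":
        logit = math.log(positive_rate / (1.0 - positive_rate))
        p = _sigmoid(logit + effect * z1)
        return (rng.random(n) < p).astype(np.int64)
    raise ConfigurationError(f"dv_kind must be 'continuous' or 'binary', got {dv_kind!r}")
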