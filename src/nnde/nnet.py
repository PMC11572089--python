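"""A minimal fully connected feed-forward network engine in numpy.

Implements the fitting protocol the decision-error simulation studies:
train-fitted standardization, SELU hidden activations, a single linear or
sigmoid output unit, exact backpropagation, Adam updates, and validation-based
early stopping with best-weight restoration.  No regularization, schedules, or
multi-class outputs — deliberately the plain workflow a practitioner gets from
framework defaults.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .datagen import ConfigurationError, TrainTestSplit

__all__ = [
    "SELU_LAMBDA",
    "SELU_ALPHA",
    "NetworkConfig",
    "Scaler",
    "Network",
    "TrainingTrace",
    "selu",
    "selu_grad",
    "standardize",
    "compute_loss",
    "adam_step",
    "backprop_gradients",
    "init_network",
    "train_network",
    "predict",
    "network_to_json",
    "network_from_json",
]

SELU_LAMBDA = 1.05070098
SELU_ALPHA = 1.67326324

_CLIP = 1e-7


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture plus training hyperparameters.

    Defaults mirror the common framework defaults for this workflow: Adam with
    learning rate 1e-3, betas (.9, .999), epsilon 1e-7; minibatches of 32; a
    random 20% validation holdout; at most 100 epochs with patience 10;
    LeCun-normal initialization (the scheme recommended for SELU).
    """

    hidden_sizes: tuple[int, ...] = (2,)
    task: str = "regression"
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.2
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    batch_size: int = 32
    init_scheme: str = "lecun_normal"
    standardize_dv: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        if self.task not in ("regression", "classification"):
            raise ConfigurationError(f"task must be 'regression' or 'classification', got {self.task!r}")
        if any(h < 1 for h in self.hidden_sizes):
            raise ConfigurationError("hidden layer sizes must be positive")
        if not (1 <= self.patience <= self.max_epochs):
            raise ConfigurationError("patience must satisfy 1 <= patience <= max_epochs")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ConfigurationError("validation_fraction must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ConfigurationError("beta1 and beta2 must lie in [0, 1)")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be positive")
        if self.init_scheme not in ("lecun_normal", "glorot_uniform"):
            raise ConfigurationError(f"unknown init_scheme {self.init_scheme!r}")


@dataclass
class Scaler:
    """Per-feature location/scale fitted on the training rows only.

    Uses the divisor-n (population) standard deviation; a constant training
    column gets scale 1 so it maps to all zeros instead of dividing by zero.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)  # ddof=0
        scale = np.where(scale > 0.0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def standardize(split: TrainTestSplit) -> tuple[np.ndarray, np.ndarray, Scaler]:
    """Scale train and test features with statistics from the train rows only.

    Only the features are transformed; the DV is untouched.  Fitting on the
    training rows alone keeps test-set information out of the model.
    """
    scaler = Scaler.fit(split.train.iv_matrix)
    return (
        scaler.transform(split.train.iv_matrix),
        scaler.transform(split.test.iv_matrix),
        scaler,
    )


def selu(x):
    """Scaled exponential linear unit: λx for x>0, λα(e^x − 1) otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0.0, SELU_LAMBDA * x, SELU_LAMBDA * SELU_ALPHA * np.expm1(x))


def selu_grad(x):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0.0, SELU_LAMBDA, SELU_LAMBDA * SELU_ALPHA * np.exp(np.minimum(x, 0.0)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class Network:
    """Weights/biases chaining input -> hidden layers (SELU) -> one output unit."""

    weights: list  # weights[l] has shape (fan_in, fan_out)
    biases: list
    task: str

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def _forward_cached(self, X: np.ndarray):
        """Return (pre-activations per layer, activations per layer incl. input)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} features, got {X.shape[1]}")
        zs, acts = [], [X]
        a = X
        n_layers = len(self.weights)
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            zs.append(z)
            a = selu(z) if l < n_layers - 1 else z
            acts.append(a)
        return zs, acts

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output: raw scores (regression) or probabilities (classification)."""
        _, acts = self._forward_cached(X)
        out = acts[-1][:, 0]
        if self.task == "classification":
            out = _sigmoid(out)
        return out


@dataclass
class TrainingTrace:
    """Per-epoch loss record with early-stopping bookkeeping (1-based epochs)."""

    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch - 1]


def compute_loss(task: str, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MSE for regression; mean binary cross-entropy (clipped) for classification."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if task == "regression":
        return float(np.mean((y_true - y_pred) ** 2))
    p = np.clip(y_pred, _CLIP, 1.0 - _CLIP)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def adam_step(param, grad, m, v, t, *, learning_rate=1e-3, beta1=0.9, beta2=0.999, epsilon=1e-7):
    """One bias-corrected Adam update; returns (new param, new m, new v)."""
    m = beta1 * m + (1.0 - beta1) * grad
    v = beta2 * v + (1.0 - beta2) * grad**2
    m_hat = m / (1.0 - beta1**t)
    v_hat = v / (1.0 - beta2**t)
    param = param - learning_rate * m_hat / (np.sqrt(v_hat) + epsilon)
    return param, m, v


def backprop_gradients(net: Network, X: np.ndarray, y: np.ndarray, task: str):
    """Exact gradients of compute_loss w.r.t. every weight and bias.

    Returns (weight gradients, bias gradients) with the same shapes as the
    network's parameter lists.  For classification, the sigmoid + cross-entropy
    pair collapses to the usual (p − y)/n output delta.
    """
    y = np.asarray(y, dtype=float)
    zs, acts = net._forward_cached(X)
    n = len(y)
    out = acts[-1][:, 0]
    if task == "classification":
        p = _sigmoid(out)
        delta = ((p - y) / n)[:, None]
    else:
        delta = (2.0 * (out - y) / n)[:, None]
    grads_W = [None] * len(net.weights)
    grads_b = [None] * len(net.biases)
    for l in range(len(net.weights) - 1, -1, -1):
        grads_W[l] = acts[l].T @ delta
        grads_b[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ net.weights[l].T) * selu_grad(zs[l - 1])
    return grads_W, grads_b


def init_network(
    n_features: int, config: NetworkConfig, rng: np.random.Generator
) -> Network:
    """Zero biases; LeCun-normal (SD 1/sqrt(fan_in)) or Glorot-uniform weights."""
    dims = (n_features, *config.hidden_sizes, 1)
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        if config.init_scheme == "lecun_normal":
            W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        weights.append(W)
        biases.append(np.zeros(fan_out))
    return Network(weights=weights, biases=biases, task=config.task)


def train_network(
    split: TrainTestSplit, config: NetworkConfig, rng: np.random.Generator | None = None
) -> tuple[Network, TrainingTrace, Scaler]:
    """Fit the network with minibatch Adam and validation early stopping.

    A random ``validation_fraction`` of the training rows is held out once per
    fit; after each epoch the validation loss is evaluated, and training stops
    once ``patience`` epochs pass without a strict improvement.  The weights
    snapshotted at the best validation epoch are restored before returning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X_train, _, scaler = standardize(split)
    y_train = np.asarray(split.train.dv_vector, dtype=float)
    if config.task == "regression" and config.standardize_dv:
        y_scaler = Scaler.fit(y_train[:, None])
        y_train = y_scaler.transform(y_train[:, None])[:, 0]

    n_train = len(y_train)
    n_val = int(round(config.validation_fraction * n_train))
    if n_val < 1 or n_train - n_val < 1:
        raise ConfigurationError(
            f"training partition of {n_train} rows cannot hold out a "
            f"{config.validation_fraction:.0%} validation subset"
        )
    perm = rng.permutation(n_train)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    X_fit, y_fit = X_train[fit_idx], y_train[fit_idx]
    X_val, y_val = X_train[val_idx], y_train[val_idx]

    net = init_network(X_train.shape[1], config, rng)
    m_W = [np.zeros_like(W) for W in net.weights]
    v_W = [np.zeros_like(W) for W in net.weights]
    m_b = [np.zeros_like(b) for b in net.biases]
    v_b = [np.zeros_like(b) for b in net.biases]

    trace = TrainingTrace()
    best_val = np.inf
    best_weights = None
    wait = 0
    t = 0
    n_fit = len(y_fit)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n_fit)
        for start in range(0, n_fit, config.batch_size):
            batch = order[start : start + config.batch_size]
            grads_W, grads_b = backprop_gradients(net, X_fit[batch], y_fit[batch], config.task)
            t += 1
            for l in range(len(net.weights)):
                net.weights[l], m_W[l], v_W[l] = adam_step(
                    net.weights[l], grads_W[l], m_W[l], v_W[l], t,
                    learning_rate=config.learning_rate, beta1=config.beta1,
                    beta2=config.beta2, epsilon=config.epsilon,
                )
                net.biases[l], m_b[l], v_b[l] = adam_step(
                    net.biases[l], grads_b[l], m_b[l], v_b[l], t,
                    learning_rate=config.learning_rate, beta1=config.beta1,
                    beta2=config.beta2, epsilon=config.epsilon,
                )
        trace.train_losses.append(compute_loss(config.task, y_fit, net.forward(X_fit)))
        val_loss = compute_loss(config.task, y_val, net.forward(X_val))
        trace.val_losses.append(val_loss)
        if val_loss < best_val:  # strict improvement, min_delta = 0
            best_val = val_loss
            best_weights = (copy.deepcopy(net.weights), copy.deepcopy(net.biases))
            trace.best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    trace.stopped_epoch = len(trace.val_losses)
    net.weights, net.biases = best_weights
    return net, trace, scaler


def predict(net: Network, scaler: Scaler, X_raw: np.ndarray) -> np.ndarray:
    """Apply the fitted scaler then the network to raw (unscaled) features."""
    return net.forward(scaler.transform(X_raw))


def network_to_json(net: Network) -> str:
    """Serialize weights layer by layer (row-major nested lists)."""
    payload = {
        "task": net.task,
        "layers": [
            {"weights": W.tolist(), "biases": b.tolist()}
            for W, b in zip(net.weights, net.biases)
        ],
    }
    return json.dumps(payload)


def network_from_json(text: str) -> Network:
    payload = json.loads(text)
    weights = [np.asarray(layer["weights"], dtype=float) for layer in payload["layers"]]
    biases = [np.asarray(layer["biases"], dtype=float) for layer in payload["layers"]]
    return Network(weights=weights, biases=biases, task=payload["task"])
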