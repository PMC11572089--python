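"""Network engine: activations, losses, gradients, Adam, training protocol."""

import numpy as np
import pytest

from nnde.datagen import (
    DatasetSpec,
    TabularDataset,
    TrainTestSplit,
    generate_dataset,
    sample_signal_dv,
    split_dataset,
)
from nnde.metrics import auc_rank, r_squared
from nnde.nnet import (
    SELU_ALPHA,
    SELU_LAMBDA,
    Network,
    NetworkConfig,
    Scaler,
    adam_step,
    backprop_gradients,
    compute_loss,
    init_network,
    network_from_json,
    network_to_json,
    predict,
    selu,
    standardize,
    train_network,
)

ALL_SHAPES = [(2,), (7,), (30,), (10, 10), (50, 50)]


def _toy_split(n=20, k=3, seed=0, binary=False):
    spec = DatasetSpec(
        n_total=n, n_iv=k,
        dv_kind="binary" if binary else "continuous",
    )
    data = generate_dataset(spec, np.random.default_rng(seed))
    return split_dataset(data, 0.8, np.random.default_rng(seed + 1))


class TestSelu:
    def test_closed_form_values(self):
        assert selu(0.0) == pytest.approx(0.0, abs=1e-15)
        assert selu(1.0) == pytest.approx(SELU_LAMBDA)
        # limit x -> -inf is -lambda*alpha
        assert selu(-50.0) == pytest.approx(-SELU_LAMBDA * SELU_ALPHA, rel=1e-9)

    def test_monotone_increasing(self):
        x = np.linspace(-6, 6, 500)
        assert np.all(np.diff(selu(x)) > 0)


class TestScaler:
    def test_train_columns_standardized(self):
        split = _toy_split(n=30, k=4)
        X_train, _, _ = standardize(split)
        assert np.allclose(X_train.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(X_train.std(axis=0), 1.0, atol=1e-10)

    def test_test_transform_uses_train_statistics(self):
        # train column {1,3}: mean 2, population SD 1, so test value 5 -> 3
        scaler = Scaler.fit(np.array([[1.0], [3.0]]))
        assert scaler.transform(np.array([[5.0]]))[0, 0] == pytest.approx(3.0)

    def test_constant_column_maps_to_zero(self):
        scaler = Scaler.fit(np.full((5, 1), 4.0))
        out = scaler.transform(np.full((3, 1), 4.0))
        assert np.all(out == 0.0)


class TestForward:
    def test_zero_network_outputs(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        zeros = lambda task: Network(
            weights=[np.zeros((3, 2)), np.zeros((2, 1))],
            biases=[np.zeros(2), np.zeros(1)],
            task=task,
        )
        assert np.allclose(zeros("regression").forward(X), 0.0)
        assert np.allclose(zeros("classification").forward(X), 0.5)

    def test_single_unit_hand_composition(self):
        # w1=1,b1=0,w2=1,b2=0, x=1 -> selu(1) = lambda
        net = Network(
            weights=[np.ones((1, 1)), np.ones((1, 1))],
            biases=[np.zeros(1), np.zeros(1)],
            task="regression",
        )
        out = net.forward(np.array([[1.0]]))
        assert out[0] == pytest.approx(SELU_LAMBDA)

    def test_dimension_mismatch_raises(self):
        net = init_network(3, NetworkConfig(hidden_sizes=(2,)), np.random.default_rng(0))
        with pytest.raises(ValueError):
            net.forward(np.zeros((4, 5)))


class TestLoss:
    @pytest.mark.parametrize(
        "task,y,p,expected",
        [
            ("regression", [1.0, 2.0], [1.0, 2.0], 0.0),
            ("regression", [0.0, 2.0], [0.0, 0.0], 2.0),
            ("classification", [1.0], [0.5], np.log(2.0)),
        ],
    )
    def test_closed_forms(self, task, y, p, expected):
        assert compute_loss(task, np.array(y), np.array(p)) == pytest.approx(expected, rel=1e-9)

    def test_cross_entropy_clipping_keeps_loss_finite(self):
        loss = compute_loss("classification", np.array([1.0]), np.array([0.0]))
        assert np.isfinite(loss)


class TestAdam:
    def test_single_step_closed_form(self):
        # m_hat=0.5, v_hat=0.25 -> step = lr * 0.5/0.5 = lr
        w, m, v = adam_step(
            np.array(1.0), np.array(0.5), np.array(0.0), np.array(0.0), 1,
            learning_rate=1e-3, beta1=0.9, beta2=0.999, epsilon=1e-12,
        )
        assert w == pytest.approx(0.999, abs=1e-9)

    def test_zero_gradient_leaves_param_unchanged(self):
        w, _, _ = adam_step(np.array(2.0), np.array(0.0), np.array(0.0), np.array(0.0), 1)
        assert w == pytest.approx(2.0)

    def test_step_magnitude_approaches_learning_rate(self):
        w = np.array(0.0)
        m = v = np.array(0.0)
        for t in range(1, 200):
            w_new, m, v = adam_step(w, np.array(0.3), m, v, t, learning_rate=1e-3)
            step = w_new - w
            w = w_new
        assert step == pytest.approx(-1e-3, rel=1e-3)


@pytest.mark.parametrize("shape", ALL_SHAPES, ids=str)
@pytest.mark.parametrize("task", ["regression", "classification"])
def test_backprop_matches_central_finite_differences(shape, task):
    """Analytic gradients agree with a finite-difference oracle on every shape."""
    rng = np.random.default_rng(hash((shape, task)) % 2**31)
    n, k = 6, 3
    X = rng.normal(size=(n, k))
    y = (rng.random(n) < 0.5).astype(float) if task == "classification" else rng.normal(size=n)
    cfg = NetworkConfig(hidden_sizes=shape, task=task)
    net = init_network(k, cfg, rng)
    grads_W, grads_b = backprop_gradients(net, X, y, task)
    h = 1e-5
    # check a deterministic sample of coordinates in every layer
    for l in range(len(net.weights)):
        W = net.weights[l]
        idxs = [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]
        for i, j in idxs:
            orig = W[i, j]
            W[i, j] = orig + h
            up = compute_loss(task, y, net.forward(X))
            W[i, j] = orig - h
            down = compute_loss(task, y, net.forward(X))
            W[i, j] = orig
            numeric = (up - down) / (2 * h)
            assert grads_W[l][i, j] == pytest.approx(numeric, rel=1e-4, abs=1e-8)
        b = net.biases[l]
        orig = b[0]
        b[0] = orig + h
        up = compute_loss(task, y, net.forward(X))
        b[0] = orig - h
        down = compute_loss(task, y, net.forward(X))
        b[0] = orig
        assert grads_b[l][0] == pytest.approx((up - down) / (2 * h), rel=1e-4, abs=1e-8)


def test_gradient_zero_at_perfect_regression_fit():
    rng = np.random.default_rng(5)
    net = init_network(2, NetworkConfig(hidden_sizes=(2,)), rng)
    X = rng.normal(size=(8, 2))
    y = net.forward(X)
    grads_W, grads_b = backprop_gradients(net, X, y, "regression")
    assert all(np.allclose(g, 0.0, atol=1e-12) for g in grads_W + grads_b)


def test_output_bias_gradient_is_two_mean_residual():
    net = Network(
        weights=[np.zeros((1, 1)), np.zeros((1, 1))],
        biases=[np.zeros(1), np.array([0.5])],
        task="regression",
    )
    X = np.zeros((4, 1))
    y = np.array([0.0, 0.0, 1.0, 1.0])  # preds all 0.5 -> residual 0, grad 2*mean(pred-y)=0
    _, grads_b = backprop_gradients(net, X, y, "regression")
    assert grads_b[-1][0] == pytest.approx(0.0, abs=1e-12)
    y2 = np.zeros(4)
    _, grads_b2 = backprop_gradients(net, X, y2, "regression")
    assert grads_b2[-1][0] == pytest.approx(2 * 0.5)


class TestTraining:
    def test_early_stopping_contract(self):
        split = _toy_split(n=60, k=3, seed=11)
        cfg = NetworkConfig(hidden_sizes=(7,), task="regression")
        net, trace, scaler = train_network(split, cfg, np.random.default_rng(2))
        assert trace.stopped_epoch <= cfg.max_epochs
        assert trace.stopped_epoch - trace.best_epoch <= cfg.patience
        assert trace.best_val_loss == pytest.approx(min(trace.val_losses), abs=1e-12)
        assert all(np.isfinite(trace.train_losses))
        assert all(np.isfinite(w).all() for w in net.weights)

    def test_training_is_deterministic_given_seed(self):
        split = _toy_split(n=40, k=3, seed=3)
        cfg = NetworkConfig(hidden_sizes=(2,), task="regression")
        n1, t1, s1 = train_network(split, cfg, np.random.default_rng(9))
        n2, t2, s2 = train_network(split, cfg, np.random.default_rng(9))
        assert all(np.array_equal(a, b) for a, b in zip(n1.weights, n2.weights))
        assert t1.val_losses == t2.val_losses

    def test_validation_subset_must_be_nonempty(self):
        split = _toy_split(n=10, k=2, seed=4)
        cfg = NetworkConfig(hidden_sizes=(2,), validation_fraction=0.01)
        with pytest.raises(Exception):
            train_network(split, cfg, np.random.default_rng(0))

    def test_signal_data_reaches_high_test_r2(self):
        """End-to-end power sanity: a strong linear signal is learned (R^2 > .5)."""
        rng = np.random.default_rng(42)
        spec = DatasetSpec(n_total=500, n_iv=3)
        data = generate_dataset(spec, rng)
        dv = sample_signal_dv(data.iv_matrix, effect=5.0, dv_kind="continuous", rng=rng)
        data = TabularDataset(data.iv_matrix, dv, spec)
        split = split_dataset(data, 0.8, rng)
        cfg = NetworkConfig(hidden_sizes=(7,), task="regression")
        net, _, scaler = train_network(split, cfg, rng)
        scores = predict(net, scaler, split.test.iv_matrix)
        assert r_squared(split.test.dv_vector, scores) > 0.5

    def test_signal_data_reaches_high_test_auc(self):
        rng = np.random.default_rng(43)
        spec = DatasetSpec(n_total=500, n_iv=3, dv_kind="binary", dv_positive_rate=0.5)
        data = generate_dataset(spec, rng)
        dv = sample_signal_dv(data.iv_matrix, effect=5.0, dv_kind="binary", rng=rng)
        data = TabularDataset(data.iv_matrix, dv, spec)
        split = split_dataset(data, 0.8, rng)
        cfg = NetworkConfig(hidden_sizes=(7,), task="classification")
        net, _, scaler = train_network(split, cfg, rng)
        scores = predict(net, scaler, split.test.iv_matrix)
        assert auc_rank(split.test.dv_vector, scores) > 0.8


def test_predict_composes_scaler_and_forward(rng):
    split = _toy_split(n=30, k=3, seed=6, binary=True)
    cfg = NetworkConfig(hidden_sizes=(2,), task="classification")
    net, _, scaler = train_network(split, cfg, np.random.default_rng(1))
    scores = predict(net, scaler, split.test.iv_matrix)
    manual = net.forward(scaler.transform(split.test.iv_matrix))
    assert np.array_equal(scores, manual)
    assert np.all((scores > 0) & (scores < 1))


def test_network_json_round_trip():
    net = init_network(3, NetworkConfig(hidden_sizes=(4, 2), task="classification"),
                       np.random.default_rng(0))
    back = network_from_json(network_to_json(net))
    assert back.task == net.task
    assert all(np.array_equal(a, b) for a, b in zip(back.weights, net.weights))
    X = np.random.default_rng(1).normal(size=(5, 3))
    assert np.allclose(back.forward(X), net.forward(X))
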