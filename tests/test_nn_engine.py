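"""Numerical correctness of the neural-network engine.

Gradient checks against central finite differences, batch-norm
train/eval semantics, checkpoint round trips, and the pooled metric.
"""

import numpy as np
import pytest

from microstress import _nn


def finite_diff_grad(model, X, Y, param, eps=1e-6):
    g = np.zeros_like(param)
    flat = param.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        lp = np.mean((model.forward(X, training=True) - Y) ** 2)
        flat[i] = orig - eps
        lm = np.mean((model.forward(X, training=True) - Y) ** 2)
        flat[i] = orig
        gf[i] = (lp - lm) / (2 * eps)
    return g


@pytest.mark.parametrize("acts", [
    ["relu", "linear"],
    ["gaussian", "linear"],
    ["sigmoid", "sigmoid"],
])
def test_backward_matches_finite_differences(acts):
    rng = np.random.default_rng(3)
    model = _nn.mlp([4, 6, 2], acts, rng)
    X = rng.normal(size=(8, 4)) + 0.3  # offset keeps ReLU kinks away from 0
    Y = rng.normal(size=(8, 2))
    pred = model.forward(X, training=True)
    model.backward(2.0 * (pred - Y) / pred.size)
    analytic = [g.copy() for g in model.grads()]
    numeric = [finite_diff_grad(model, X, Y, p) for p in model.params()]
    for a, n in zip(analytic, numeric):
        assert np.allclose(a, n, rtol=1e-5, atol=1e-7)


def test_batchnorm_backward_matches_finite_differences():
    rng = np.random.default_rng(4)
    model = _nn.mlp([3, 5, 1], ["relu", "linear"], rng, bn_layers={0})
    X = rng.normal(size=(12, 3))
    Y = rng.normal(size=(12, 1))
    pred = model.forward(X, training=True)
    model.backward(2.0 * (pred - Y) / pred.size)
    analytic = [g.copy() for g in model.grads()]
    # freeze running stats so repeated forwards in training mode are comparable
    numeric = [finite_diff_grad(model, X, Y, p) for p in model.params()]
    for a, n in zip(analytic, numeric):
        assert np.allclose(a, n, rtol=1e-4, atol=1e-6)


def test_batchnorm_eval_uses_running_stats():
    rng = np.random.default_rng(0)
    bn = _nn.BatchNorm(3, momentum=0.0)  # running stats = last batch
    X = rng.normal(loc=5.0, scale=2.0, size=(64, 3))
    bn.forward(X, training=True)
    single = bn.forward(X[:1], training=False)
    full = bn.forward(X, training=False)[:1]
    assert np.allclose(single, full)  # batch-size independent at inference


def test_fit_reduces_loss_and_is_deterministic():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(64, 3))
    Y = (X @ np.array([[1.0], [-2.0], [0.5]])) + 0.1

    def run():
        r = np.random.default_rng(11)
        m = _nn.mlp([3, 16, 1], ["relu", "linear"], r)
        res = _nn.fit_mse(m, X, Y, epochs=200, batch_size=16, rng=r, eval_every=50)
        return m, res

    m1, r1 = run()
    m2, r2 = run()
    assert r1.history[-1][1] < r1.history[0][1]
    assert r1.best_r2 > 0.95
    for p1, p2 in zip(m1.params(), m2.params()):
        assert np.array_equal(p1, p2)


def test_best_checkpoint_restored():
    """The returned model reproduces the best logged R², not the last."""
    rng = np.random.default_rng(6)
    X = rng.normal(size=(32, 2))
    Y = X.sum(axis=1, keepdims=True)
    r = np.random.default_rng(2)
    m = _nn.mlp([2, 8, 1], ["relu", "linear"], r)
    res = _nn.fit_mse(m, X, Y, epochs=300, batch_size=8, rng=r, eval_every=100)
    pred = m.forward(X, training=False)
    assert _nn.pooled_r_squared(Y, pred) >= res.best_r2 - 1e-9


def test_divergence_raises():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(16, 2)) * 1e200
    Y = rng.normal(size=(16, 1)) * 1e200
    r = np.random.default_rng(2)
    m = _nn.mlp([2, 4, 1], ["relu", "linear"], r)
    with pytest.raises(_nn.TrainingDivergence):
        _nn.fit_mse(m, X, Y, epochs=200, batch_size=8, rng=r, lr=1e3, eval_every=10)


class TestPooledR2:
    def test_perfect_and_mean_predictions(self):
        y = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]])
        assert _nn.pooled_r_squared(y, y) == 1.0
        assert _nn.pooled_r_squared(y, np.tile(y.mean(axis=0), (3, 1))) == 0.0

    def test_zero_variance_columns_excluded(self):
        y = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        yhat = np.array([[1.0, 6.0], [2.0, 6.0], [4.0, 6.0]])
        # constant column 2 ignored: R² = 1 - 1/2
        assert np.isclose(_nn.pooled_r_squared(y, yhat), 0.5)

    def test_all_constant_degenerate(self):
        y = np.full((4, 2), 3.0)
        assert _nn.pooled_r_squared(y, y) == 1.0
        assert _nn.pooled_r_squared(y, y + 1) == 0.0

    def test_weighted_matches_raw_unit_pooling(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(50, 3)) * np.array([1.0, 10.0, 100.0])
        yhat = y + rng.normal(size=y.shape)
        mean, sd = y.mean(axis=0), y.std(axis=0)
        raw = _nn.pooled_r_squared(y, yhat)
        z = _nn.pooled_r_squared((y - mean) / sd, (yhat - mean) / sd, weights=sd**2)
        assert np.isclose(raw, z)


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(9)
    m = _nn.mlp([3, 4, 2], ["relu", "linear"], rng, bn_layers={0})
    path = tmp_path / "ckpt.npz"
    _nn.save_checkpoint(path, {"net": m.state_dict()}, {"tag": "x", "n": 3})
    groups, meta = _nn.load_checkpoint(path)
    assert meta == {"tag": "x", "n": 3}
    m2 = _nn.mlp([3, 4, 2], ["relu", "linear"], np.random.default_rng(1), bn_layers={0})
    m2.load_state_dict(groups["net"])
    X = rng.normal(size=(5, 3))
    assert np.array_equal(m.forward(X, False), m2.forward(X, False))
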