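"""Minimal feedforward neural-network engine on numpy.

Implements exactly what the pipeline's architectures need — dense layers,
ReLU / sigmoid / linear / Gaussian activations, batch normalization, the
Adam optimizer and a mini-batch MSE training loop with periodic pooled-R²
checkpointing — with fully seeded, bit-reproducible behaviour.  All
parameters are float64; a single ``numpy.random.Generator`` drives both
initialization and batch shuffling, so identical seeds give identical
trained models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dense",
    "Activation",
    "BatchNorm",
    "Sequential",
    "Adam",
    "pooled_r_squared",
    "fit_mse",
    "TrainingDivergence",
]


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def pooled_r_squared(y: np.ndarray, yhat: np.ndarray,
                     weights: np.ndarray | None = None) -> float:
    """Multi-output R² pooled over columns.

    ``1 − Σ_cols Σ_rows (y−ŷ)² / Σ_cols Σ_rows (y−ȳ_col)²`` with
    zero-variance columns excluded from both sums.  ``weights`` scales
    each column's contribution — pass the raw-unit column variances when
    y/ŷ are standardized to recover the raw-unit pooled value.  If every
    column is constant the metric degenerates: 1.0 when predictions
    match the constants exactly, else 0.0.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
        yhat = yhat[:, None]
    col_var = y.var(axis=0)
    live = col_var > 0
    if not live.any():
        ss_res = float(((y - yhat) ** 2).sum())
        return 1.0 if ss_res == 0.0 else 0.0
    w = np.ones(y.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    yl, pl, wl = y[:, live], yhat[:, live], w[live]
    ss_res = float((wl * ((yl - pl) ** 2).sum(axis=0)).sum())
    ss_tot = float((wl * ((yl - yl.mean(axis=0)) ** 2).sum(axis=0)).sum())
    return 1.0 - ss_res / ss_tot


class Layer:
    """Base class; layers expose aligned ``params``/``grads`` lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, init: str = "he"):
        if init == "he":
            scale = math.sqrt(2.0 / n_in)
        else:  # glorot
            scale = math.sqrt(1.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Activation(Layer):
    """Elementwise nonlinearity: relu | sigmoid | linear | gaussian.

    ``gaussian`` is the radial f(x) = exp(−x²) used in the augmentation
    network's central hidden layer.
    """

    def __init__(self, kind: str):
        if kind not in ("relu", "sigmoid", "linear", "gaussian"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def forward(self, x, training):
        self._x = x
        if self.kind == "relu":
            y = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            # stable piecewise form: exp is only ever taken of -|x|
            e = np.exp(-np.abs(x))
            y = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        elif self.kind == "gaussian":
            y = np.exp(-np.square(x))
        else:
            y = x
        self._y = y
        return y

    def backward(self, grad):
        if self.kind == "relu":
            return grad * (self._x > 0)
        if self.kind == "sigmoid":
            return grad * self._y * (1.0 - self._y)
        if self.kind == "gaussian":
            return grad * (-2.0 * self._x * self._y)
        return grad


class BatchNorm(Layer):
    """1-D batch normalization with learned scale/shift.

    Training uses per-batch statistics and updates exponential running
    moments; inference uses the running moments, so outputs are
    independent of inference batch size.
    """

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, x.shape[0])
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, inv_std, m = self._cache
        self.dgamma[...] = (grad * xhat).sum(axis=0)
        self.dbeta[...] = grad.sum(axis=0)
        # standard batchnorm backward through batch statistics
        gx = self.gamma * grad
        return (inv_std / m) * (m * gx - gx.sum(axis=0) - xhat * (gx * xhat).sum(axis=0))


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    # -- checkpointing -------------------------------------------------
    def state_dict(self) -> list:
        state = []
        for layer in self.layers:
            entry = [p.copy() for p in layer.params()]
            if isinstance(layer, BatchNorm):
                entry += [layer.running_mean.copy(), layer.running_var.copy()]
            state.append(entry)
        return state

    def load_state_dict(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            ps = layer.params()
            for p, saved in zip(ps, entry):
                p[...] = saved
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = entry[len(ps)]
                layer.running_var[...] = entry[len(ps) + 1]


def mlp(
    widths: list[int],
    activations: list[str],
    rng: np.random.Generator,
    bn_layers: set[int] | None = None,
) -> Sequential:
    """Build a fully connected stack.

    ``widths`` has length L+1; ``activations`` length L (one per dense
    layer).  ``bn_layers`` holds 0-based dense-layer indices that get a
    BatchNorm between the affine map and its activation.
    """
    if len(activations) != len(widths) - 1:
        raise ValueError("need one activation per dense layer")
    bn_layers = bn_layers or set()
    layers: list[Layer] = []
    for i, act in enumerate(activations):
        init = "he" if act in ("relu", "gaussian") else "glorot"
        layers.append(Dense(widths[i], widths[i + 1], rng, init=init))
        if i in bn_layers:
            layers.append(BatchNorm(widths[i + 1]))
        layers.append(Activation(act))
    return layers_to_seq(layers)


def layers_to_seq(layers: list[Layer]) -> Sequential:
    return Sequential(layers)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def save_checkpoint(path, groups: dict[str, list], meta: dict) -> None:
    """Write named state-dict groups plus a JSON metadata block to .npz."""
    arrays: dict[str, np.ndarray] = {}
    for gname, state in groups.items():
        for i, entry in enumerate(state):
            for j, arr in enumerate(entry):
                arrays[f"{gname}.{i}.{j}"] = arr
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, list], dict]:
    """Inverse of :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        groups: dict[str, dict[tuple[int, int], np.ndarray]] = {}
        for key in data.files:
            if key == "__meta__":
                continue
            gname, i, j = key.rsplit(".", 2)
            groups.setdefault(gname, {})[(int(i), int(j))] = data[key]
    out: dict[str, list] = {}
    for gname, entries in groups.items():
        n_entries = max(i for i, _ in entries) + 1
        state = []
        for i in range(n_entries):
            parts = [j for k, j in entries if k == i]
            # parameter-free layers (activations) save no arrays: empty entry
            state.append([entries[(i, j)] for j in range(max(parts) + 1)] if parts else [])
        out[gname] = state
    return out, meta


@dataclass
class FitResult:
    history: list[tuple[int, float, float]] = field(default_factory=list)  # (epoch, mse, r2)
    best_r2: float = -np.inf
    best_epoch: int = -1


def fit_mse(
    model: Sequential,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    lr: float = 1e-3,
    eval_every: int = 100,
    early_stop_mse: float | None = None,
    eval_weights: np.ndarray | None = None,
) -> FitResult:
    """Mini-batch MSE training with periodic pooled-R² checkpointing.

    Every ``eval_every`` epochs the full-data pooled R² is logged and the
    best-scoring parameter snapshot is kept; the model is restored to
    that snapshot before returning.  ``early_stop_mse`` stops once the
    full-data MSE drops below the threshold (checked at the same
    cadence).
    """
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    batch_size = min(batch_size, n)
    opt = Adam(model.params(), lr=lr)
    result = FitResult()
    best_state = model.state_dict()

    def evaluate(epoch: int) -> float:
        pred = model.forward(X, training=False)
        mse = float(np.mean((pred - Y) ** 2))
        if not np.isfinite(mse):
            raise TrainingDivergence(f"non-finite loss at epoch {epoch}")
        r2 = pooled_r_squared(Y, pred, weights=eval_weights)
        result.history.append((epoch, mse, r2))
        return mse

    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], Y[idx]
            pred = model.forward(xb, training=True)
            grad = 2.0 * (pred - yb) / pred.size
            model.backward(grad)
            opt.step(model.grads())
        if epoch % eval_every == 0 or epoch == epochs:
            mse = evaluate(epoch)
            if result.history[-1][2] > result.best_r2:
                result.best_r2 = result.history[-1][2]
                result.best_epoch = epoch
                best_state = model.state_dict()
            if early_stop_mse is not None and mse < early_stop_mse:
                break

    model.load_state_dict(best_state)
    return result
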