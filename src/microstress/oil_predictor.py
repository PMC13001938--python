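"""Prediction network for encoded oil type from environment + taxa.

A (4+N)-input regression network — encoded location, incubation time,
temperature, encoded month, plus the N selected taxa abundances; the
oil type itself is excluded from the inputs and is the single-output
regression target.  Hidden stack 32-64-128-64-32 with ReLU throughout;
the fifth hidden layer optionally adds batch normalization (the
overfitting control evaluated in the with/without-BN comparison).
Trained with Adam on MSE at batch size 16, keeping the checkpoint with
the best training R².
"""

from __future__ import annotations

import numpy as np

from . import _nn
from ._nn import Sequential, fit_mse
from .adnn_augment import AugmentedSet
from .categorical_codec import EncoderBundle, code_to_oil_label
from .data_model import ENV_COLUMNS

__all__ = [
    "PredictorModel",
    "train_predictor",
    "predict_oil",
    "decode_predictions",
    "labels_from_encoding",
    "predictor_inputs",
]

#: environmental inputs of the predictor (oil type excluded)
PREDICTOR_ENV = [c for c in ENV_COLUMNS if c != "oil_enc"]
_ENV_IDX = [ENV_COLUMNS.index(c) for c in PREDICTOR_ENV]


def predictor_inputs(env: np.ndarray, taxa: np.ndarray) -> np.ndarray:
    """Assemble the (4+N) input matrix from canonical env + taxa blocks."""
    env = np.atleast_2d(np.asarray(env, dtype=float))
    taxa = np.atleast_2d(np.asarray(taxa, dtype=float))
    return np.hstack([env[:, _ENV_IDX], taxa])


class PredictorModel:
    """Trained oil-type regressor with input/target standardizers."""

    def __init__(self, net: Sequential, use_bn: bool, x_stats, y_stats,
                 r2: float, history: list, n_taxa_features: int):
        self.net = net
        self.use_bn = use_bn
        self.x_stats = x_stats
        self.y_stats = y_stats
        self.r2 = r2
        self.history = history
        self.n_taxa_features = n_taxa_features

    @property
    def n_inputs(self) -> int:
        return 4 + self.n_taxa_features

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Encoded oil values, one per row (inference mode: BN uses running stats)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} input columns, got {X.shape[1]}")
        xm, xs = self.x_stats
        ym, ys = self.y_stats
        return self.net.forward((X - xm) / xs, training=False)[:, 0] * ys + ym

    def save(self, path) -> None:
        _nn.save_checkpoint(
            path,
            {
                "net": self.net.state_dict(),
                "xstats": [list(self.x_stats)],
                "ystats": [[np.asarray([v]) for v in self.y_stats]],
            },
            {"use_bn": self.use_bn, "r2": self.r2, "history": self.history,
             "n_taxa_features": self.n_taxa_features},
        )

    @classmethod
    def load(cls, path) -> "PredictorModel":
        groups, meta = _nn.load_checkpoint(path)
        net = _build_net(4 + meta["n_taxa_features"], meta["use_bn"],
                         np.random.default_rng(0))
        net.load_state_dict(groups["net"])
        xm, xs = groups["xstats"][0]
        ym, ys = (float(a[0]) for a in groups["ystats"][0])
        return cls(net, meta["use_bn"], (xm, xs), (ym, ys), meta["r2"],
                   [tuple(h) for h in meta["history"]], meta["n_taxa_features"])


def _build_net(n_in: int, use_bn: bool, rng: np.random.Generator,
               bn_all: bool = False) -> Sequential:
    hidden = [32, 64, 128, 64, 32]
    if bn_all:
        bn_layers = set(range(len(hidden)))
    elif use_bn:
        bn_layers = {4}  # fifth hidden layer only
    else:
        bn_layers = set()
    return _nn.mlp(
        [n_in] + hidden + [1],
        ["relu"] * 5 + ["linear"],
        rng,
        bn_layers=bn_layers,
    )


def train_predictor(
    augmented: AugmentedSet,
    use_bn: bool = True,
    epochs: int = 1500,
    batch_size: int = 16,
    lr: float = 1e-3,
    seed: int = 0,
    bn_all: bool = False,
) -> PredictorModel:
    """Fit the oil-type prediction network on an augmented training set.

    Inputs and the encoded-oil target are z-scored internally (R² is
    affine-invariant, so reported values are unchanged); the training-R²
    log is kept at a 100-epoch cadence and the best checkpoint retained.
    """
    X = predictor_inputs(augmented.env, augmented.taxa)
    y = augmented.oil_enc
    xm = X.mean(axis=0)
    xs = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    ym = float(y.mean())
    ys = float(y.std()) or 1.0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x011]))
    net = _build_net(X.shape[1], use_bn, rng, bn_all=bn_all)
    result = fit_mse(net, (X - xm) / xs, (y - ym) / ys,
                     epochs=epochs, batch_size=batch_size, rng=rng, lr=lr)
    return PredictorModel(net, use_bn, (xm, xs), (ym, ys),
                          float(result.best_r2), result.history, augmented.taxa.shape[1])


def predict_oil(model: PredictorModel, samples: np.ndarray) -> np.ndarray:
    """Deterministic forward pass: one encoded oil value per sample row."""
    return model.predict(samples)


def decode_predictions(values: np.ndarray, oil_bundle: EncoderBundle) -> list[str]:
    """Translate predicted encoded-oil scalars into oil labels.

    Each scalar runs through the oil codec's decoder to a raw sigmoid
    pair, then through the rounded/nearest-code label map — total on any
    real input.
    """
    raw = oil_bundle.decode(np.asarray(values, dtype=float))
    return [code_to_oil_label(tuple(pair)) for pair in raw]


def labels_from_encoding(values: np.ndarray, encoding: dict[str, float]) -> list[str]:
    """Nearest-value label decoding for tables with a fixed oil encoding.

    For cohorts whose ``oil_enc`` column carries known per-label scalars
    (e.g. generator output) rather than codec bottleneck values.
    """
    labels = list(encoding)
    centers = np.array([encoding[l] for l in labels], dtype=float)
    values = np.asarray(values, dtype=float)
    nearest = np.abs(values[:, None] - centers[None, :]).argmin(axis=1)
    return [labels[i] for i in nearest]
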