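"""Noise-injected data augmentation around a small regression network.

The augmentation network (ADNN) learns the map from the five
environmental features (encoded location, incubation time, encoded oil
type, temperature, encoded month) to the abundances of the N
top-ranked taxa, through a 5→32→64→128→64→32→N stack whose central
hidden layer uses the radial Gaussian activation exp(−x²) and whose
output is linear.  Synthetic inputs are manufactured by adding
zero-mean Gaussian noise with standard deviation ``c·σᵢ`` (default
c = 0.01, σᵢ the per-feature sd of the real inputs) to the full real
input matrix, once per round; the network's predictions at those noisy
inputs become synthetic samples.  Four rounds on 404 real samples give
1,616 synthetic rows and a 2,020-row augmented training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from ._nn import Sequential, fit_mse
from .data_model import ENV_COLUMNS, SampleTable

__all__ = [
    "NoiseSpec",
    "AdnnModel",
    "AugmentedSet",
    "ReliabilityWarning",
    "train_adnn",
    "inject_noise",
    "build_augmented_set",
]

#: training R² below which ADNN-generated samples are flagged unreliable
ADNN_RELIABILITY_THRESHOLD = 0.75


class ReliabilityWarning(UserWarning):
    """Synthetic data may be unreliable (generator fit below threshold)."""


@dataclass
class NoiseSpec:
    """Per-feature noise scale for input perturbation."""

    sigma: np.ndarray            # per-feature standard deviations (σ1..σ5)
    scale: float = 0.01          # c: injected sd is c·σᵢ
    rounds: int = 4              # synthetic copies of the real matrix
    seed: int = 0

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if (self.sigma < 0).any():
            raise ValueError("sigma must be non-negative")
        if self.scale < 0 or self.rounds < 0:
            raise ValueError("scale and rounds must be non-negative")

    @classmethod
    def from_matrix(cls, env: np.ndarray, scale: float = 0.01, rounds: int = 4,
                    seed: int = 0) -> "NoiseSpec":
        """Compute σᵢ as the sample sd (ddof=1) of each input column."""
        env = np.asarray(env, dtype=float)
        return cls(sigma=env.std(axis=0, ddof=1), scale=scale, rounds=rounds, seed=seed)


def inject_noise(env_matrix: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Perturb the full input matrix once per round; concatenate rounds.

    Each round draws an independent Gaussian matrix of the input's shape
    with column sd ``scale·σᵢ`` and adds it to the originals, so the
    output has ``n·rounds`` rows in round-major order.
    """
    env = np.asarray(env_matrix, dtype=float)
    if env.ndim != 2 or env.shape[1] != len(spec.sigma):
        raise ValueError(f"env matrix shape {env.shape} does not match spec ({len(spec.sigma)} features)")
    rng = np.random.default_rng(spec.seed)
    blocks = []
    for _ in range(spec.rounds):
        noise = rng.normal(0.0, 1.0, size=env.shape) * (spec.scale * spec.sigma)
        blocks.append(env + noise)
    if not blocks:
        return np.empty((0, env.shape[1]))
    return np.vstack(blocks)


class AdnnModel:
    """Trained augmentation network with its input/output standardizers."""

    def __init__(self, net: Sequential, selected_taxa: list[int],
                 x_stats, y_stats, r2: float, history: list):
        self.net = net
        self.selected_taxa = list(selected_taxa)
        self.x_stats = x_stats  # (mean, sd) of the 5 env features
        self.y_stats = y_stats  # (mean, sd) of the N taxa outputs
        self.r2 = r2
        self.history = history

    def predict(self, env: np.ndarray) -> np.ndarray:
        """Taxa abundances at raw env inputs (de-standardized, clipped ≥ 0)."""
        env = np.atleast_2d(np.asarray(env, dtype=float))
        xm, xs = self.x_stats
        ym, ys = self.y_stats
        z = self.net.forward((env - xm) / xs, training=False)
        return np.clip(z * ys + ym, 0.0, None)

    def save(self, path) -> None:
        _nn.save_checkpoint(
            path,
            {
                "net": self.net.state_dict(),
                "stats": [[*self.x_stats], [*self.y_stats]],
            },
            {"selected_taxa": self.selected_taxa, "r2": self.r2, "history": self.history},
        )

    @classmethod
    def load(cls, path) -> "AdnnModel":
        groups, meta = _nn.load_checkpoint(path)
        taxa = meta["selected_taxa"]
        net = _nn.mlp(
            [5, 32, 64, 128, 64, 32, len(taxa)],
            ["relu", "relu", "gaussian", "relu", "relu", "linear"],
            np.random.default_rng(0),
        )
        net.load_state_dict(groups["net"])
        (xm, xs), (ym, ys) = groups["stats"]
        return cls(net, taxa, (xm, xs), (ym, ys), meta["r2"],
                   [tuple(h) for h in meta["history"]])


def _standardize_stats(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def train_adnn(
    table: SampleTable,
    selected_taxa: list[int],
    epochs: int = 3000,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> AdnnModel:
    """Fit the 5→32→64→128(Gaussian)→64→32→N augmentation network.

    All samples are used; the training R² (pooled over the N outputs) is
    evaluated every 100 epochs and the best-scoring checkpoint is kept.
    Inputs and outputs are z-scored internally; predictions are returned
    in raw abundance units.
    """
    N = len(selected_taxa)
    if N < 1:
        raise ValueError("need at least one selected taxon")
    X = table.env_matrix
    Y = table.taxa_matrix(selected_taxa)
    x_stats = _standardize_stats(X)
    y_stats = _standardize_stats(Y)
    Xz = (X - x_stats[0]) / x_stats[1]
    Yz = (Y - y_stats[0]) / y_stats[1]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xADF]))
    net = _nn.mlp(
        [5, 32, 64, 128, 64, 32, N],
        ["relu", "relu", "gaussian", "relu", "relu", "linear"],
        rng,
    )
    # R² monitored in raw abundance units: pooled over outputs with each
    # column weighted by its raw variance (standardized fit, raw metric)
    result = fit_mse(net, Xz, Yz, epochs=epochs, batch_size=batch_size, rng=rng,
                     lr=lr, eval_weights=y_stats[1] ** 2)
    model = AdnnModel(net, selected_taxa, x_stats, y_stats,
                      float(result.best_r2), result.history)
    return model


@dataclass
class AugmentedSet:
    """Union of real and ADNN-synthesized samples.

    ``env`` is (m, 5) in canonical environmental column order, ``taxa``
    (m, N) for the selected taxa; ``provenance`` labels each row
    ``"real"`` or ``"synthetic"``.  Real rows are the untouched
    projection of the source table.
    """

    env: np.ndarray
    taxa: np.ndarray
    provenance: np.ndarray
    selected_taxa: list[int]
    adnn_r2: float = float("nan")

    @property
    def n_real(self) -> int:
        return int((self.provenance == "real").sum())

    @property
    def n_synthetic(self) -> int:
        return int((self.provenance == "synthetic").sum())

    def __len__(self) -> int:
        return self.env.shape[0]

    @property
    def features(self) -> np.ndarray:
        """(m, 5+N) combined feature matrix — VAE training input."""
        return np.hstack([self.env, self.taxa])

    @property
    def oil_enc(self) -> np.ndarray:
        return self.env[:, ENV_COLUMNS.index("oil_enc")]

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.env, columns=ENV_COLUMNS)
        for j, t in enumerate(self.selected_taxa):
            df[f"Bac_{t}"] = self.taxa[:, j]
        df["provenance"] = self.provenance
        return df

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AugmentedSet":
        df = pd.read_csv(path)
        taxa_cols = [c for c in df.columns if c.startswith("Bac_")]
        missing = [c for c in ENV_COLUMNS + ["provenance"] if c not in df.columns]
        if missing:
            raise ValueError(f"augmented CSV missing columns: {missing}")
        return cls(
            env=df[ENV_COLUMNS].to_numpy(dtype=float),
            taxa=df[taxa_cols].to_numpy(dtype=float),
            provenance=df["provenance"].to_numpy(dtype=str),
            selected_taxa=[int(c.split("_", 1)[1]) for c in taxa_cols],
        )


def build_augmented_set(
    table: SampleTable,
    model: AdnnModel,
    spec: NoiseSpec,
    selected_taxa: list[int] | None = None,
) -> AugmentedSet:
    """Assemble real + synthetic rows: n·(1+rounds) samples total.

    Synthetic rows pair each noise-injected input with the ADNN's
    prediction at that input.  Emits a :class:`ReliabilityWarning` when
    the generator's training R² is below 0.75 — downstream stress tests
    built on such data are less trustworthy.
    """
    selected_taxa = list(selected_taxa) if selected_taxa is not None else model.selected_taxa
    if selected_taxa != model.selected_taxa:
        raise ValueError("selected taxa do not match the trained model's outputs")
    if model.r2 < ADNN_RELIABILITY_THRESHOLD:
        warnings.warn(
            f"ADNN training R² {model.r2:.3f} < {ADNN_RELIABILITY_THRESHOLD}; "
            "synthetic samples may be unreliable",
            ReliabilityWarning,
        )
    env_real = table.env_matrix
    taxa_real = table.taxa_matrix(selected_taxa)
    env_syn = inject_noise(env_real, spec)
    taxa_syn = model.predict(env_syn) if len(env_syn) else np.empty((0, len(selected_taxa)))
    env = np.vstack([env_real, env_syn])
    taxa = np.vstack([taxa_real, taxa_syn])
    provenance = np.array(["real"] * len(env_real) + ["synthetic"] * len(env_syn))
    return AugmentedSet(env=env, taxa=taxa, provenance=provenance,
                        selected_taxa=selected_taxa, adnn_r2=model.r2)
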