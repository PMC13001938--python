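"""Variational autoencoder over augmented samples; in-distribution stress sets.

The VAE learns a smooth 3-D latent representation of the (5+N)-feature
augmented training distribution: encoder trunk 256-128-64 (ReLU) with
linear μ and log-σ² heads, latent z = μ + σ·ε with ε ~ N(0, I), mirrored
decoder with linear output.  The loss is per-sample reconstruction
squared error plus the closed-form KL divergence of the Gaussian
posterior from the standard normal prior, optimized with Adam.

Decoding latent draws yields a *stress set*: perturbed but in-manifold
samples used to probe the prediction network's internal consistency —
not independent validation data.  The default draws one z from each
training row's posterior N(μᵢ, σᵢ²), generating samples similar to but
not identical to the originals; drawing from the N(0, I) prior instead
is available for global latent-space probing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nn
from ._nn import Adam, Dense, Sequential, TrainingDivergence, pooled_r_squared
from .adnn_augment import ADNN_RELIABILITY_THRESHOLD, AugmentedSet, ReliabilityWarning
from .data_model import ENV_COLUMNS

__all__ = ["VaeModel", "StressSet", "kl_divergence", "train_vae", "sample_stress_set"]

LATENT_DIM = 3


def kl_divergence(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Per-sample KL(N(μ, σ²) ‖ N(0, I)) = ½ Σ(μ² + σ² − 1 − ln σ²)."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    return 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=1)


class VaeModel:
    """Trained VAE with its feature standardizer and training log."""

    def __init__(self, trunk: Sequential, head_mu: Dense, head_logvar: Dense,
                 decoder: Sequential, stats, selected_taxa: list[int],
                 r2: float, history: list):
        self.trunk = trunk
        self.head_mu = head_mu
        self.head_logvar = head_logvar
        self.decoder = decoder
        self.stats = stats  # (mean, sd) over the 5+N features
        self.selected_taxa = list(selected_taxa)
        self.r2 = r2
        self.history = history

    # -- forward passes ------------------------------------------------
    def encode(self, X: np.ndarray, eps: np.ndarray | None = None) -> tuple[np.ndarray, ...]:
        """Return (z, μ, log σ²); ε defaults to 0 (deterministic z = μ)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mean, sd = self.stats
        h = self.trunk.forward((X - mean) / sd, training=False)
        mu = self.head_mu.forward(h, False)
        logvar = self.head_logvar.forward(h, False)
        if eps is None:
            z = mu
        else:
            z = mu + np.exp(0.5 * logvar) * eps
        return z, mu, logvar

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode latent vectors back to raw feature units."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        mean, sd = self.stats
        return self.decoder.forward(z, training=False) * sd + mean

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        z, _, _ = self.encode(X)
        return self.decode(z)

    def save(self, path) -> None:
        _nn.save_checkpoint(
            path,
            {
                "trunk": self.trunk.state_dict(),
                "mu": [[p.copy() for p in self.head_mu.params()]],
                "logvar": [[p.copy() for p in self.head_logvar.params()]],
                "decoder": self.decoder.state_dict(),
                "stats": [list(self.stats)],
            },
            {"selected_taxa": self.selected_taxa, "r2": self.r2, "history": self.history},
        )

    @classmethod
    def load(cls, path) -> "VaeModel":
        groups, meta = _nn.load_checkpoint(path)
        mean, sd = groups["stats"][0]
        d = len(mean)
        rng = np.random.default_rng(0)
        trunk = _nn.mlp([d, 256, 128, 64], ["relu", "relu", "relu"], rng)
        head_mu = Dense(64, LATENT_DIM, rng)
        head_logvar = Dense(64, LATENT_DIM, rng)
        decoder = _nn.mlp([LATENT_DIM, 64, 128, 256, d], ["relu", "relu", "relu", "linear"], rng)
        trunk.load_state_dict(groups["trunk"])
        for p, v in zip(head_mu.params(), groups["mu"][0]):
            p[...] = v
        for p, v in zip(head_logvar.params(), groups["logvar"][0]):
            p[...] = v
        decoder.load_state_dict(groups["decoder"])
        return cls(trunk, head_mu, head_logvar, decoder, (mean, sd),
                   meta["selected_taxa"], meta["r2"], [tuple(h) for h in meta["history"]])


def train_vae(
    augmented: AugmentedSet,
    epochs: int = 3000,
    batch_size: int = 32,
    lr: float = 1e-3,
    beta: float = 1.0,
    lr_decay: float = 0.999,
    seed: int = 0,
) -> VaeModel:
    """Fit the (5+N)-256-128-64-(3)-64-128-256-(5+N) VAE.

    Reconstruction R² (deterministic, z = μ) is evaluated every 100
    epochs and the best checkpoint kept.  Posterior collapse (μ→0, σ→1,
    negative reconstruction R²) produces a warning, not a failure.
    """
    X = augmented.features
    n, d = X.shape
    if n < batch_size:
        raise ValueError(f"augmented set ({n} rows) smaller than batch size {batch_size}")
    if np.isfinite(augmented.adnn_r2) and augmented.adnn_r2 < ADNN_RELIABILITY_THRESHOLD:
        warnings.warn(
            f"training VAE on augmented data from a weak generator "
            f"(ADNN R² {augmented.adnn_r2:.3f} < {ADNN_RELIABILITY_THRESHOLD})",
            ReliabilityWarning,
        )
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xz = (X - mean) / sd

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7AE]))
    trunk = _nn.mlp([d, 256, 128, 64], ["relu", "relu", "relu"], rng)
    head_mu = Dense(64, LATENT_DIM, rng, init="glorot")
    head_logvar = Dense(64, LATENT_DIM, rng, init="glorot")
    decoder = _nn.mlp([LATENT_DIM, 64, 128, 256, d], ["relu", "relu", "relu", "linear"], rng)

    params = trunk.params() + head_mu.params() + head_logvar.params() + decoder.params()
    opt = Adam(params, lr=lr)

    def snapshot():
        return (trunk.state_dict(), [p.copy() for p in head_mu.params()],
                [p.copy() for p in head_logvar.params()], decoder.state_dict())

    def restore(s):
        trunk.load_state_dict(s[0])
        for p, v in zip(head_mu.params(), s[1]):
            p[...] = v
        for p, v in zip(head_logvar.params(), s[2]):
            p[...] = v
        decoder.load_state_dict(s[3])

    history: list[tuple[int, float, float]] = []
    best_r2, best_state = -np.inf, snapshot()

    for epoch in range(1, epochs + 1):
        opt.lr = lr * lr_decay ** (epoch - 1)
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = Xz[idx]
            B = xb.shape[0]
            h = trunk.forward(xb, training=True)
            mu = head_mu.forward(h, True)
            logvar = np.clip(head_logvar.forward(h, True), -10.0, 10.0)
            eps = rng.standard_normal(mu.shape)
            std = np.exp(0.5 * logvar)
            z = mu + std * eps
            xhat = decoder.forward(z, training=True)

            # d/dxhat of mean-over-batch per-sample squared error
            dxhat = 2.0 * (xhat - xb) / B
            dz = decoder.backward(dxhat)
            dmu = dz + (beta / B) * mu
            dlogvar = dz * eps * 0.5 * std + (beta / B) * 0.5 * (np.exp(logvar) - 1.0)
            dh = head_mu.backward(dmu) + head_logvar.backward(dlogvar)
            trunk.backward(dh)
            grads = trunk.grads() + head_mu.grads() + head_logvar.grads() + decoder.grads()
            opt.step(grads)

        if epoch % 100 == 0 or epoch == epochs:
            h = trunk.forward(Xz, training=False)
            mu = head_mu.forward(h, False)
            recon = decoder.forward(mu, training=False)
            mse = float(np.mean((recon - Xz) ** 2))
            if not np.isfinite(mse):
                raise TrainingDivergence(f"non-finite VAE loss at epoch {epoch}")
            r2 = pooled_r_squared(Xz, recon, weights=sd**2)
            history.append((epoch, mse, r2))
            if r2 > best_r2:
                best_r2, best_state = r2, snapshot()

    restore(best_state)
    model = VaeModel(trunk, head_mu, head_logvar, decoder, (mean, sd),
                     augmented.selected_taxa, float(best_r2), history)
    # posterior-collapse diagnostic on the final checkpoint
    _, mu, logvar = model.encode(X)
    sigma = np.exp(0.5 * logvar)
    if best_r2 < 0 and np.abs(mu).mean() < 0.05 and np.abs(sigma - 1).mean() < 0.05:
        warnings.warn("posterior collapse suspected (μ≈0, σ≈1, reconstruction R² < 0)")
    return model


@dataclass
class StressSet:
    """Decoded prior samples: (n, 5) env block + (n, N) taxa block."""

    env: np.ndarray
    taxa: np.ndarray
    selected_taxa: list[int]
    seed: int

    def __len__(self) -> int:
        return self.env.shape[0]

    @property
    def features(self) -> np.ndarray:
        return np.hstack([self.env, self.taxa])

    @property
    def oil_enc(self) -> np.ndarray:
        return self.env[:, ENV_COLUMNS.index("oil_enc")]

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.env, columns=ENV_COLUMNS)
        for j, t in enumerate(self.selected_taxa):
            df[f"Bac_{t}"] = self.taxa[:, j]
        df.insert(0, "sample_id", [f"VAE{i + 1:05d}" for i in range(len(df))])
        return df

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False)


def sample_stress_set(
    model: VaeModel,
    n: int = 2020,
    seed: int = 0,
    source: np.ndarray | None = None,
    mode: str = "posterior",
) -> StressSet:
    """Decode n latent draws into perturbed in-manifold samples.

    ``mode="posterior"`` (default) draws one z ~ N(μᵢ, σᵢ²) per row of
    ``source`` — the training features the model was fit on — producing
    samples similar to, but not identical to, the originals; rows are
    resampled with replacement when n differs from ``len(source)``.
    ``mode="prior"`` draws z ~ N(0, I₃) instead, probing the latent
    space globally at the cost of less coherent samples.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    if mode == "posterior":
        if source is None:
            raise ValueError("posterior sampling needs the training features (source=...)")
        source = np.atleast_2d(np.asarray(source, dtype=float))
        idx = (np.arange(n) if n == len(source)
               else rng.integers(0, len(source), size=n))
        _, mu, logvar = model.encode(source[idx])
        z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
    elif mode == "prior":
        z = rng.standard_normal((n, LATENT_DIM))
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    decoded = model.decode(z)
    if not np.all(np.isfinite(decoded)):
        raise TrainingDivergence("decoder produced non-finite stress samples")
    env = decoded[:, :5]
    taxa = np.clip(decoded[:, 5:], 0.0, None)
    return StressSet(env=env, taxa=taxa, selected_taxa=model.selected_taxa, seed=seed)
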