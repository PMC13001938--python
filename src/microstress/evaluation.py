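"""Metrics, feature-count sweeps, stress tests, and grouped hold-out.

The hold-out protocol partitions *bottles* — independent physical
microcosms — rather than samples, so no microcosm contributes rows to
both sides of a split.  Everything fitted (feature ranking, the
augmentation network, noise statistics, the predictor and its
standardizers) sees only training-split samples; augmentation is never
applied to held-out data.  Test R² on held-out real samples can be
negative when predictions are worse than the held-out mean — grouped
evaluation of a small, heterogeneous cohort routinely is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adnn_augment import NoiseSpec, build_augmented_set, train_adnn
from .data_model import SampleTable
from .feature_selection import rank_features_rfr, select_top_k
from .oil_predictor import PredictorModel, predict_oil, predictor_inputs, train_predictor
from .vae_stress import StressSet, sample_stress_set, train_vae

__all__ = [
    "r_squared",
    "snap_to_legal",
    "stress_test",
    "HoldoutResult",
    "SweepResult",
    "bottle_holdout",
    "feature_sweep",
    "PipelineSizes",
]


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 − Σ(y−ŷ)²/Σ(y−ȳ)².

    Negative values mean the predictions are worse than the mean of
    ``y`` — expected on hard held-out data, not an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("target has zero variance; R² undefined")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def snap_to_legal(values: np.ndarray, legal_values: np.ndarray) -> np.ndarray:
    """Map each value to the nearest member of a legal encoded-value set."""
    legal = np.asarray(legal_values, dtype=float)
    values = np.asarray(values, dtype=float)
    return legal[np.abs(values[:, None] - legal[None, :]).argmin(axis=1)]


def stress_test(
    model: PredictorModel,
    stress: StressSet,
    legal_oil_values: np.ndarray | None = None,
) -> float:
    """R² of the predictor on a VAE-generated stress set.

    The generated ``oil_enc`` column is the target; when the legal
    encoded oil values are supplied each generated value is first
    snapped to its nearest legal code (generated targets are continuous,
    but oil type is categorical underneath).
    """
    X = predictor_inputs(stress.env, stress.taxa)
    target = stress.oil_enc
    if legal_oil_values is not None:
        target = snap_to_legal(target, legal_oil_values)
    return r_squared(target, predict_oil(model, X))


@dataclass
class PipelineSizes:
    """Per-stage training sizes shared by the sweep and hold-out drivers.

    Defaults are the pipeline's full training schedule (augmentation
    network 3000 epochs at batch 32, VAE 3000 at 32, predictor 1500 at
    16, forest of 2500 trees); the drivers accept smaller values for
    quick studies.
    """

    adnn_epochs: int = 3000
    vae_epochs: int = 3000
    predictor_epochs: int = 1500
    adnn_batch: int = 32
    vae_batch: int = 32
    predictor_batch: int = 16
    rf_trees: int = 2500
    rf_depth: int = 25
    noise_scale: float = 0.01
    noise_rounds: int = 4
    stress_n: int = 2020


@dataclass
class HoldoutResult:
    """Per-split and summary R² of repeated grouped hold-out."""

    splits: list[dict] = field(default_factory=list)
    n_splits: int = 0
    test_fraction: float = 0.2

    @property
    def test_r2(self) -> np.ndarray:
        return np.array([s["test_r2"] for s in self.splits])

    @property
    def train_r2(self) -> np.ndarray:
        return np.array([s["train_r2"] for s in self.splits])

    def summary(self) -> dict:
        t = self.test_r2
        return {
            "mean_test_r2": float(t.mean()),
            "sd_test_r2": float(t.std(ddof=1)) if len(t) > 1 else 0.0,
            "min_test_r2": float(t.min()),
            "max_test_r2": float(t.max()),
            "mean_train_r2": float(self.train_r2.mean()),
            "n_splits": self.n_splits,
            "test_fraction": self.test_fraction,
        }

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "split": i,
                    "train_r2": s["train_r2"],
                    "test_r2": s["test_r2"],
                    "n_test_bottles": len(s["test_bottles"]),
                    "n_test_samples": s["n_test_samples"],
                }
                for i, s in enumerate(self.splits)
            ]
        )


def _split_bottle_counts(n_bottles: int, test_frac: float, n_splits: int) -> list[int]:
    """Held-out bottle count per split: alternate floor/ceil of frac·n.

    At 172 bottles and an 80/20 ratio this alternates 34 and 35.
    """
    exact = test_frac * n_bottles
    lo, hi = int(np.floor(exact)), int(np.ceil(exact))
    return [lo if i % 2 == 0 else hi for i in range(n_splits)]


def _fit_and_score_split(
    train: SampleTable,
    test: SampleTable,
    k: int,
    sizes: PipelineSizes,
    seed: int,
    use_bn: bool,
) -> dict:
    """Train the pipeline on training-split samples only; score on test."""
    ranking = rank_features_rfr(train, seed=seed, n_estimators=sizes.rf_trees,
                                max_depth=sizes.rf_depth)
    taxa = select_top_k(ranking, k)
    adnn = train_adnn(train, taxa, epochs=sizes.adnn_epochs,
                      batch_size=sizes.adnn_batch, seed=seed)
    spec = NoiseSpec.from_matrix(train.env_matrix, scale=sizes.noise_scale,
                                 rounds=sizes.noise_rounds, seed=seed)
    augmented = build_augmented_set(train, adnn, spec)
    model = train_predictor(augmented, use_bn=use_bn, epochs=sizes.predictor_epochs,
                            batch_size=sizes.predictor_batch, seed=seed)
    X_test = predictor_inputs(test.env_matrix, test.taxa_matrix(taxa))
    test_r2 = r_squared(test.oil_enc, predict_oil(model, X_test))
    return {
        "train_r2": model.r2,
        "test_r2": test_r2,
        "selected_taxa": taxa,
        "n_test_samples": test.n_samples,
        "n_train_samples": train.n_samples,
        "n_augmented": len(augmented),
        "n_augmented_synthetic": augmented.n_synthetic,
    }


def bottle_holdout(
    table: SampleTable,
    k: int = 5,
    n_splits: int = 22,
    test_frac: float = 0.2,
    seed: int = 0,
    use_bn: bool = True,
    sizes: PipelineSizes | None = None,
    group: str = "bottle",
    max_resample: int = 20,
) -> HoldoutResult:
    """Repeated random grouped hold-out with leakage guards.

    Per split, bottles (``group="bottle"``) or individual samples
    (``group="sample"``, for the grouping-matters comparison) are
    partitioned at the requested ratio; the full pipeline is refit on
    the training side only.  Splits whose test side has no target
    variance are resampled (bounded, with a note in the split record).
    """
    sizes = sizes or PipelineSizes()
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    if group not in ("bottle", "sample"):
        raise ValueError("group must be 'bottle' or 'sample'")
    units = np.unique(table.bottle_ids) if group == "bottle" else table.sample_ids
    if group == "bottle" and len(units) < 5:
        raise ValueError("need at least 5 bottles for grouped hold-out")
    n_test_per_split = _split_bottle_counts(len(units), test_frac, n_splits)
    master = np.random.SeedSequence(seed)
    split_seeds = [int(s.generate_state(1)[0] % 2**31) for s in master.spawn(n_splits)]

    result = HoldoutResult(n_splits=n_splits, test_fraction=test_frac)
    key = table.bottle_ids if group == "bottle" else table.sample_ids
    for i, (split_seed, n_test) in enumerate(zip(split_seeds, n_test_per_split)):
        rng = np.random.default_rng(split_seed)
        resampled = 0
        while True:
            test_units = set(rng.choice(units, size=n_test, replace=False).tolist())
            test_mask = np.array([u in test_units for u in key])
            test = table.subset(test_mask)
            train = table.subset(~test_mask)
            ok = test.n_samples >= 2 and np.var(test.oil_enc) > 0 and np.var(train.oil_enc) > 0
            if ok or resampled >= max_resample:
                break
            resampled += 1
        if not ok:
            raise RuntimeError(f"split {i}: could not draw a usable test split")
        # leakage guard: the grouped train/test unit sets must be disjoint
        train_units = set(train.bottle_ids if group == "bottle" else train.sample_ids)
        assert not (train_units & set(test.bottle_ids if group == "bottle" else test.sample_ids))
        record = _fit_and_score_split(train, test, k, sizes, split_seed, use_bn)
        record["test_bottles"] = sorted(set(test.bottle_ids))
        record["train_bottles"] = sorted(set(train.bottle_ids))
        record["resampled"] = resampled
        result.splits.append(record)
    return result


@dataclass
class SweepResult:
    """Per-k pipeline R² values (the feature-count comparison table)."""

    rows: list[dict] = field(default_factory=list)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def feature_sweep(
    table: SampleTable,
    k_list: list[int],
    seed: int = 0,
    use_bn: bool = True,
    sizes: PipelineSizes | None = None,
    legal_oil_values: np.ndarray | None = None,
) -> SweepResult:
    """Run the full train-on-everything pipeline at each feature count k.

    Reports, per k: augmentation-network training R², VAE reconstruction
    R², predictor training R², and predictor stress-test R² on a fresh
    VAE-generated set.  This is the internal-fit regime (no hold-out).
    """
    sizes = sizes or PipelineSizes()
    if sorted(k_list) != list(k_list) or len(set(k_list)) != len(k_list):
        raise ValueError("k_list must be strictly increasing")
    ranking = rank_features_rfr(table, seed=seed, n_estimators=sizes.rf_trees,
                                max_depth=sizes.rf_depth)
    if legal_oil_values is None:
        legal_oil_values = np.unique(table.oil_enc)
    result = SweepResult()
    for k in k_list:
        taxa = select_top_k(ranking, k)
        adnn = train_adnn(table, taxa, epochs=sizes.adnn_epochs,
                          batch_size=sizes.adnn_batch, seed=seed)
        spec = NoiseSpec.from_matrix(table.env_matrix, scale=sizes.noise_scale,
                                     rounds=sizes.noise_rounds, seed=seed)
        augmented = build_augmented_set(table, adnn, spec)
        vae = train_vae(augmented, epochs=sizes.vae_epochs,
                        batch_size=sizes.vae_batch, seed=seed)
        stress = sample_stress_set(vae, n=sizes.stress_n, seed=seed,
                                   source=augmented.features)
        model = train_predictor(augmented, use_bn=use_bn, epochs=sizes.predictor_epochs,
                                batch_size=sizes.predictor_batch, seed=seed)
        result.rows.append(
            {
                "k": k,
                "adnn_train_r2": adnn.r2,
                "vae_train_r2": vae.r2,
                "predictor_train_r2": model.r2,
                "predictor_stress_r2": stress_test(model, stress, legal_oil_values),
                "rfr_train_r2": ranking.train_r2,
            }
        )
    return result
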