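"""Config-driven end-to-end pipeline runs.

A :class:`PipelineConfig` captures every knob of the full chain —
cohort simulation (or an input table), feature ranking, augmentation,
VAE stress generation, predictor training and evaluation — plus a
single master seed fanned out to per-stage seeds through a splittable
seed sequence, so each stage is individually reproducible.  The runner
writes every artifact (tables, models, metrics, log) into one run
directory stamped with the config hash and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .adnn_augment import NoiseSpec, build_augmented_set, train_adnn
from .data_model import SampleTable, read_sample_table, write_sample_table
from .evaluation import PipelineSizes, r_squared, stress_test
from .feature_selection import rank_features_rfr, select_top_k
from .oil_predictor import predict_oil, predictor_inputs, train_predictor
from .synthetic_community import CohortConfig, generate_cohort
from .vae_stress import sample_stress_set, train_vae

log = logging.getLogger("microstress")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

STAGES = ("simulate", "rank", "adnn", "inject", "vae", "stress", "predictor")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Fan one master seed out to independent per-stage seeds (< 2³¹)."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31) for name, c in zip(STAGES, children)}


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults are the full study-shaped schedule."""

    input_table: str | None = None      # CSV path; None → simulate a cohort
    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    k: int = 5                          # selected taxa features
    use_bn: bool = True
    noise_scale: float = 0.01
    noise_rounds: int = 4
    adnn_epochs: int = 3000
    vae_epochs: int = 3000
    predictor_epochs: int = 1500
    adnn_batch: int = 32
    vae_batch: int = 32
    predictor_batch: int = 16
    rf_trees: int = 2500
    rf_depth: int = 25
    stress_n: int = 2020
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not self.synthetic and not self.input_table:
            raise ValueError("need input_table when synthetic is false")
        for name in ("adnn_epochs", "vae_epochs", "predictor_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def sizes(self) -> PipelineSizes:
        return PipelineSizes(
            adnn_epochs=self.adnn_epochs, vae_epochs=self.vae_epochs,
            predictor_epochs=self.predictor_epochs, adnn_batch=self.adnn_batch,
            vae_batch=self.vae_batch, predictor_batch=self.predictor_batch,
            rf_trees=self.rf_trees, rf_depth=self.rf_depth,
            noise_scale=self.noise_scale, noise_rounds=self.noise_rounds,
            stress_n=self.stress_n,
        )

    # -- round-trippable flat serialization ----------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["effect_log2fc"] = (
            None if self.cohort.effect_log2fc is None
            else np.asarray(self.cohort.effect_log2fc).tolist()
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if cohort.get("effect_log2fc") is not None:
            cohort["effect_log2fc"] = np.asarray(cohort["effect_log2fc"], dtype=float)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=CohortConfig(**cohort), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:10]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute rank → augment → VAE → stress → predict → evaluate.

    Returns the metrics dict; all artifacts land in ``out_dir`` with the
    config and seed embedded.  Reruns with the same config are
    bit-reproducible.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    tag = f"{config.digest()}-seed{config.seed}"
    config.to_yaml(out / f"config-{tag}.yaml")

    if config.synthetic:
        cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["simulate"])
        table, truth = generate_cohort(cohort_cfg)
        write_sample_table(table, out / f"cohort-{tag}.csv")
        truth.to_json(out / f"ground_truth-{tag}.json")
        log.info("simulated cohort: %d samples, %d bottles",
                 table.n_samples, len(set(table.bottle_ids)))
    else:
        table = read_sample_table(config.input_table)

    ranking = rank_features_rfr(table, seed=seeds["rank"],
                                n_estimators=config.rf_trees, max_depth=config.rf_depth)
    ranking.to_tsv(out / f"ranking-{tag}.tsv")
    taxa = select_top_k(ranking, config.k)
    log.info("rank: RFR training R²=%.3f, top-%d taxa=%s", ranking.train_r2, config.k, taxa)

    adnn = train_adnn(table, taxa, epochs=config.adnn_epochs,
                      batch_size=config.adnn_batch, seed=seeds["adnn"])
    log.info("adnn: training R²=%.3f (best epoch of %d)", adnn.r2, config.adnn_epochs)

    spec = NoiseSpec.from_matrix(table.env_matrix, scale=config.noise_scale,
                                 rounds=config.noise_rounds, seed=seeds["inject"])
    augmented = build_augmented_set(table, adnn, spec)
    augmented.to_csv(out / f"augmented-{tag}.csv")
    log.info("augment: %d real + %d synthetic = %d rows",
             augmented.n_real, augmented.n_synthetic, len(augmented))

    vae = train_vae(augmented, epochs=config.vae_epochs,
                    batch_size=config.vae_batch, seed=seeds["vae"])
    log.info("vae: reconstruction R²=%.3f", vae.r2)
    stress = sample_stress_set(vae, n=config.stress_n, seed=seeds["stress"],
                               source=augmented.features)
    stress.to_csv(out / f"stress-{tag}.csv")

    model = train_predictor(augmented, use_bn=config.use_bn,
                            epochs=config.predictor_epochs,
                            batch_size=config.predictor_batch, seed=seeds["predictor"])
    log.info("predictor: training R²=%.3f (BN=%s)", model.r2, config.use_bn)

    legal = np.unique(table.oil_enc)
    stress_r2 = stress_test(model, stress, legal)
    real_r2 = r_squared(
        table.oil_enc,
        predict_oil(model, predictor_inputs(table.env_matrix, table.taxa_matrix(taxa))),
    )
    metrics = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_samples": table.n_samples,
        "n_augmented": len(augmented),
        "k": config.k,
        "selected_taxa": taxa,
        "rfr_train_r2": ranking.train_r2,
        "adnn_train_r2": adnn.r2,
        "vae_train_r2": vae.r2,
        "predictor_train_r2": model.r2,
        "predictor_real_r2": real_r2,
        "predictor_stress_r2": stress_r2,
        "history": {
            "adnn": adnn.history,
            "vae": vae.history,
            "predictor": model.history,
        },
    }
    with open(out / f"metrics-{tag}.json", "w") as fh:
        json.dump(metrics, fh, indent=1)
    return metrics
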