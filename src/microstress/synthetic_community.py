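"""Seeded generator of study-shaped microcosm cohorts.

Emulates the structure of the training cohort the pipeline was designed
for: ~172 oil-amended bottles of lake surface water from 4 sites,
sampled over incubation weeks 0–7, with sparse counts over ~503 taxa of
which a small planted subset responds to oil exposure.  Counts follow a
zero-inflated negative binomial; oil-responsive taxa have their mean
abundance multiplied by ``2**(log2fc · ramp(week))`` when the bottle's
oil treatment matches, where ``ramp`` saturates at week 3 — blooms of
hydrocarbon degraders grow in over the first weeks of incubation.

The generator also returns the ground truth (which taxa were planted,
with what effects, and each bottle's treatment) so that recovery tests
can score the downstream feature-selection and prediction stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import ENV_COLUMNS, META_COLUMNS, SampleTable, scale_temporal, taxa_columns

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "DEFAULT_OIL_ENCODING"]


class ConfigError(ValueError):
    """Cohort configuration violates an invariant."""


#: stand-in encoded oil-type scalars used by the generator (the real
#: pipeline derives these from a trained categorical codec; any three
#: distinct values work — downstream ranking is affine-invariant).
DEFAULT_OIL_ENCODING = {"no_oil": 0.0, "crude": 45.11, "diesel": 146.27}

#: four Great-Lakes-like site coordinates (lat, lon); arbitrary but distinct
_DEFAULT_SITES = [
    (47.12, -88.55),  # Keweenaw / Superior shoreline
    (45.78, -84.73),  # Straits of Mackinac
    (44.76, -86.06),  # Lake Michigan
    (47.12, -88.54),  # harbor research station
]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults mirror the study shape."""

    n_bottles: int = 172
    samples_per_bottle_mean: float = 2.35  # 172 bottles × 2.35 ≈ 404 samples
    n_taxa: int = 503
    n_sites: int = 4
    n_responsive: int = 10
    effect_log2fc: np.ndarray | None = None  # (n_responsive, 2): per-taxon effect under crude / diesel
    effect_magnitude: float = 4.0
    sparsity: float = 0.7        # target overall zero-cell fraction
    dispersion: float = 0.05     # NB overdispersion α, var = μ + α·μ²
    baseline_log_mean: float = 1.6
    baseline_log_sd: float = 1.5
    bottle_effect_sd: float = 0.15  # shared per-bottle random effect, log2 scale
    taxon_bottle_sd: float = 0.5    # per-taxon-per-bottle dispersion, log2 scale
    ramp_saturation_week: int = 3
    oil_encoding: dict = field(default_factory=lambda: dict(DEFAULT_OIL_ENCODING))
    seed: int = 0

    def validate(self) -> None:
        if self.n_bottles < 1 or self.n_taxa < 0 or self.n_sites < 1:
            raise ConfigError("n_bottles, n_sites must be >= 1 and n_taxa >= 0")
        if self.n_responsive > self.n_taxa or self.n_responsive < 0:
            raise ConfigError("need 0 <= n_responsive <= n_taxa")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ConfigError("sparsity must be a probability")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.samples_per_bottle_mean < 1:
            raise ConfigError("samples_per_bottle_mean must be >= 1")
        if self.effect_log2fc is not None:
            eff = np.asarray(self.effect_log2fc, dtype=float)
            if eff.shape != (self.n_responsive, 2):
                raise ConfigError("effect_log2fc must have shape (n_responsive, 2)")


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery tests."""

    responsive_taxa: list[int]               # 1-based taxon indices
    effect_log2fc: np.ndarray                # (n_responsive, 2) for (crude, diesel)
    bottle_oil: dict[str, str]               # bottle_id -> oil label
    site_coords: list[tuple[float, float]]   # (lat, lon) per site
    bottle_site: dict[str, int]              # bottle_id -> site index
    oil_encoding: dict[str, float]

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["effect_log2fc"] = np.asarray(self.effect_log2fc).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["effect_log2fc"] = np.asarray(payload["effect_log2fc"], dtype=float)
        payload["site_coords"] = [tuple(c) for c in payload["site_coords"]]
        return cls(**payload)


def _calibrate_dropout(mu: np.ndarray, r: float, target: float) -> float:
    """Scale μ₀ of the abundance-dependent dropout π = exp(−μ/μ₀).

    Dropout in sparse count data hits low-abundance taxa hardest while
    blooming taxa are reliably detected, so structural zeros are modeled
    as ``exp(−μ/μ₀)`` per cell.  μ₀ is bisected so the *expected* total
    zero fraction (structural + negative-binomial zeros) equals the
    configured ``sparsity`` target; returns 0.0 when NB zeros alone
    already exceed it.
    """
    p0_nb = (r / (r + mu)) ** r

    def frac(mu0: float) -> float:
        drop = np.exp(-mu / mu0)
        return float((drop + (1.0 - drop) * p0_nb).mean())

    if p0_nb.mean() >= target:
        return 0.0
    lo, hi = 1e-6, 1e9
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _default_effects(n_responsive: int, magnitude: float) -> np.ndarray:
    """Cycle taxa through crude-only / diesel-only / both-oils response."""
    eff = np.zeros((n_responsive, 2))
    for j in range(n_responsive):
        pattern = j % 3
        if pattern == 0:
            eff[j] = (magnitude, 0.0)
        elif pattern == 1:
            eff[j] = (0.0, magnitude)
        else:
            eff[j] = (magnitude, magnitude)
    return eff


def generate_cohort(config: CohortConfig) -> tuple[SampleTable, GroundTruth]:
    """Draw one seeded cohort; identical config (incl. seed) ⇒ identical table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    oil_labels = list(config.oil_encoding)

    sites = _DEFAULT_SITES[: config.n_sites]
    while len(sites) < config.n_sites:  # beyond 4: jitter around the defaults
        base = _DEFAULT_SITES[len(sites) % 4]
        sites.append((base[0] + 0.5 * len(sites) / 4, base[1] - 0.3))
    # evenly spaced stand-in encoded-location scalars, one per site
    site_enc = np.linspace(0.1, 0.9, config.n_sites)

    if config.effect_log2fc is not None:
        effects = np.asarray(config.effect_log2fc, dtype=float)
    else:
        effects = _default_effects(config.n_responsive, config.effect_magnitude)
    responsive = (
        rng.choice(config.n_taxa, size=config.n_responsive, replace=False) + 1
        if config.n_responsive
        else np.array([], dtype=int)
    )
    responsive = np.sort(responsive)

    baseline = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_taxa))

    # month and incubation temperature are campaign-level attributes: each
    # site was sampled in one campaign with one lab incubation setting, so
    # location, month and temperature are collinear at the site level —
    # mirroring the multi-experiment provenance of real cohorts.
    site_month = rng.integers(5, 11, size=config.n_sites)      # open-water season
    site_temp = np.round(rng.normal(22.0, 2.0, config.n_sites), 1)

    rows = []
    bottle_oil: dict[str, str] = {}
    bottle_site: dict[str, int] = {}
    sample_counter = 0
    for b in range(config.n_bottles):
        bottle_id = f"B{b + 1:04d}"
        site = int(rng.integers(config.n_sites))
        oil = oil_labels[b % len(oil_labels)]  # balanced treatment assignment
        bottle_oil[bottle_id] = oil
        bottle_site[bottle_id] = site
        month = int(site_month[site])
        temperature = float(site_temp[site])
        lat_jit, lon_jit = rng.normal(0.0, 0.01, 2)
        loc_enc = float(site_enc[site] + 0.02 * lat_jit)
        bottle_effect = rng.normal(0.0, config.bottle_effect_sd)  # log2 scale
        # taxon-specific bottle effects: between-bottle community variability
        # that environmental covariates cannot explain
        taxon_effects = rng.normal(0.0, config.taxon_bottle_sd, config.n_taxa)

        n_obs = 1 + int(rng.poisson(config.samples_per_bottle_mean - 1.0))
        n_obs = min(n_obs, 8)
        weeks = np.sort(rng.choice(8, size=n_obs, replace=False))
        for week in weeks:
            time_enc, month_enc = scale_temporal(int(week), month)
            mu = baseline.copy()
            ramp = min(week / config.ramp_saturation_week, 1.0) if config.ramp_saturation_week else 1.0
            if oil == "crude":
                mu[responsive - 1] *= 2.0 ** (effects[:, 0] * ramp)
            elif oil == "diesel":
                mu[responsive - 1] *= 2.0 ** (effects[:, 1] * ramp)
            mu = mu * 2.0 ** (bottle_effect + taxon_effects)
            sample_counter += 1
            rows.append(
                {
                    "sample_id": f"S{sample_counter:05d}",
                    "bottle_id": bottle_id,
                    "location_enc": loc_enc,
                    "time_enc": float(time_enc),
                    "oil_enc": float(config.oil_encoding[oil]),
                    "temperature": temperature,
                    "month_enc": float(month_enc),
                    "_mu": mu,
                }
            )

    # counts: abundance-dependent structural zeros over a negative binomial,
    # with the dropout scale calibrated to the configured overall sparsity
    mu_matrix = np.vstack([row.pop("_mu") for row in rows]) if config.n_taxa else np.empty((len(rows), 0))
    r = 1.0 / config.dispersion
    if config.n_taxa:
        mu0 = _calibrate_dropout(mu_matrix, r, config.sparsity)
        counts = rng.negative_binomial(r, r / (r + mu_matrix))
        if mu0 > 0:
            counts[rng.random(mu_matrix.shape) < np.exp(-mu_matrix / mu0)] = 0
    else:
        counts = np.empty((len(rows), 0), dtype=np.int64)

    df = pd.DataFrame(rows, columns=META_COLUMNS + ENV_COLUMNS)
    df = pd.concat(
        [df, pd.DataFrame(counts.astype(np.int64), columns=taxa_columns(config.n_taxa))],
        axis=1,
    )
    truth = GroundTruth(
        responsive_taxa=[int(i) for i in responsive],
        effect_log2fc=effects,
        bottle_oil=bottle_oil,
        site_coords=[tuple(s) for s in sites],
        bottle_site=bottle_site,
        oil_encoding=dict(config.oil_encoding),
    )
    return SampleTable(df), truth
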