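"""KL closed forms, reparameterization, stress-set sampling and moments."""

import numpy as np
import pytest

from microstress.vae_stress import (
    VaeModel,
    kl_divergence,
    sample_stress_set,
    train_vae,
)


class TestKlDivergence:
    def test_unit_gaussian_is_zero(self):
        assert np.allclose(kl_divergence(np.zeros(3), np.ones(3)), 0.0)

    def test_unit_mean_shift_is_half(self):
        # ½(μ² + σ² − 1 − ln σ²) summed: μ=(1,0,0), σ=1 → 0.5
        assert np.allclose(kl_divergence([1.0, 0.0, 0.0], [1.0, 1.0, 1.0]), 0.5)

    def test_closed_form_general(self):
        mu = np.array([0.5, -1.0, 2.0])
        sigma = np.array([0.5, 2.0, 1.0])
        expected = 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - np.log(sigma**2))
        assert np.allclose(kl_divergence(mu, sigma), expected)

    def test_nonnegative_property(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(50, 3))
        sigma = np.exp(rng.normal(size=(50, 3)))
        assert (kl_divergence(mu, sigma) >= -1e-12).all()


@pytest.fixture(scope="module")
def small_vae(small_augmented):
    return train_vae(small_augmented, epochs=300, seed=0)


class TestTrainVae:
    def test_latent_dimension_is_three(self, small_vae, small_augmented):
        _, mu, logvar = small_vae.encode(small_augmented.features[:4])
        assert mu.shape == (4, 3)
        assert logvar.shape == (4, 3)

    def test_reconstruction_quality(self, small_vae, small_augmented):
        assert small_vae.r2 > 0.7

    def test_deterministic_encode_returns_mu(self, small_vae, small_augmented):
        """With ε fixed at zero, repeated encodes give identical z = μ."""
        X = small_augmented.features[:6]
        z1, mu, _ = small_vae.encode(X)
        z2, _, _ = small_vae.encode(X)
        assert np.array_equal(z1, z2)
        assert np.array_equal(z1, mu)

    def test_reparameterization_shifts_by_sigma_eps(self, small_vae, small_augmented):
        X = small_augmented.features[:3]
        eps = np.ones((3, 3))
        z, mu, logvar = small_vae.encode(X, eps=eps)
        assert np.allclose(z, mu + np.exp(0.5 * logvar))

    def test_same_seed_identical_model(self, small_augmented):
        m1 = train_vae(small_augmented, epochs=100, seed=9)
        m2 = train_vae(small_augmented, epochs=100, seed=9)
        X = small_augmented.features[:5]
        assert np.array_equal(m1.reconstruct(X), m2.reconstruct(X))

    def test_too_small_set_rejected(self, small_augmented):
        import dataclasses

        tiny = dataclasses.replace(
            small_augmented,
            env=small_augmented.env[:8],
            taxa=small_augmented.taxa[:8],
            provenance=small_augmented.provenance[:8],
        )
        with pytest.raises(ValueError):
            train_vae(tiny, epochs=10, batch_size=32)

    def test_checkpoint_roundtrip(self, tmp_path, small_vae, small_augmented):
        path = tmp_path / "vae.npz"
        small_vae.save(path)
        back = VaeModel.load(path)
        X = small_augmented.features[:5]
        assert np.array_equal(back.reconstruct(X), small_vae.reconstruct(X))


class TestStressSet:
    def test_requested_size_and_shape(self, small_vae, small_augmented):
        s = sample_stress_set(small_vae, n=2020, seed=1,
                              source=small_augmented.features)
        assert len(s) == 2020
        assert s.features.shape == (2020, 5 + len(small_vae.selected_taxa))
        assert np.isfinite(s.features).all()

    def test_seeded_determinism(self, small_vae, small_augmented):
        src = small_augmented.features
        s1 = sample_stress_set(small_vae, n=50, seed=4, source=src)
        s2 = sample_stress_set(small_vae, n=50, seed=4, source=src)
        assert np.array_equal(s1.features, s2.features)
        assert not np.array_equal(
            s1.features, sample_stress_set(small_vae, n=50, seed=5, source=src).features
        )

    def test_prior_mode_needs_no_source(self, small_vae):
        s = sample_stress_set(small_vae, n=40, seed=0, mode="prior")
        assert len(s) == 40

    def test_posterior_mode_requires_source(self, small_vae):
        with pytest.raises(ValueError, match="source"):
            sample_stress_set(small_vae, n=10, mode="posterior")

    def test_posterior_samples_stay_near_their_sources(self, small_vae, small_augmented):
        """One posterior draw per training row lands near that row."""
        src = small_augmented.features
        s = sample_stress_set(small_vae, n=len(src), seed=3, source=src)
        sd = src.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        per_row = np.abs((s.features - np.clip(src, [-np.inf]*5 + [0]*(src.shape[1]-5), None)) / sd).mean()
        shuffled = np.abs((s.features - src[::-1]) / sd).mean()
        assert per_row < shuffled  # aligned rows are closer than misaligned

    def test_nonpositive_n_rejected(self, small_vae):
        with pytest.raises(ValueError):
            sample_stress_set(small_vae, n=0)

    def test_in_manifold_moments(self, small_vae, small_augmented):
        """Large stress sets stay near the training distribution: feature
        means and sds within 20% of the augmented set's (sd-scaled)."""
        s = sample_stress_set(small_vae, n=10_000, seed=2,
                              source=small_augmented.features)
        train_mean = small_augmented.features.mean(axis=0)
        train_sd = small_augmented.features.std(axis=0)
        gen_mean = s.features.mean(axis=0)
        gen_sd = s.features.std(axis=0)
        assert np.all(np.abs(gen_mean - train_mean) <= 0.2 * train_sd + 1e-9)
        assert np.all(np.abs(gen_sd - train_sd) <= 0.35 * train_sd + 1e-9)

    def test_csv_export(self, tmp_path, small_vae, small_augmented):
        s = sample_stress_set(small_vae, n=10, seed=0,
                              source=small_augmented.features)
        path = tmp_path / "stress.csv"
        s.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == 10
        assert "oil_enc" in df.columns and "sample_id" in df.columns
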