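"""Noise injection bookkeeping, moment checks, ADNN fit, augmented sets."""

import numpy as np
import pytest

from microstress.adnn_augment import (
    AdnnModel,
    AugmentedSet,
    NoiseSpec,
    ReliabilityWarning,
    build_augmented_set,
    inject_noise,
    train_adnn,
)


class TestNoiseSpec:
    def test_from_matrix_uses_sample_sd(self):
        rng = np.random.default_rng(0)
        env = rng.normal(size=(50, 5))
        spec = NoiseSpec.from_matrix(env)
        assert np.allclose(spec.sigma, env.std(axis=0, ddof=1))

    @pytest.mark.parametrize("kwargs", [
        {"sigma": [-1.0] * 5}, {"sigma": [1.0] * 5, "scale": -0.1},
        {"sigma": [1.0] * 5, "rounds": -1},
    ])
    def test_invariants(self, kwargs):
        with pytest.raises(ValueError):
            NoiseSpec(**kwargs)


class TestInjectNoise:
    def test_study_bookkeeping_404_to_1616(self):
        rng = np.random.default_rng(1)
        env = rng.normal(size=(404, 5))
        out = inject_noise(env, NoiseSpec.from_matrix(env, rounds=4, seed=0))
        assert out.shape == (1616, 5)

    def test_zero_noise_gives_exact_copies(self):
        rng = np.random.default_rng(2)
        env = rng.normal(size=(10, 5))
        out = inject_noise(env, NoiseSpec.from_matrix(env, scale=0.0, rounds=4))
        assert np.array_equal(out, np.tile(env, (4, 1)))

    def test_zero_rounds_empty(self):
        env = np.ones((5, 5))
        out = inject_noise(env, NoiseSpec(sigma=np.ones(5), rounds=0))
        assert out.shape == (0, 5)

    def test_perturbation_sd_matches_spec(self):
        """Per-column sd of (synthetic − tiled original) ≈ 0.01·σᵢ."""
        rng = np.random.default_rng(3)
        env = rng.normal(scale=[1, 5, 10, 0.5, 2], size=(404, 5))
        spec = NoiseSpec.from_matrix(env, scale=0.01, rounds=4, seed=7)
        delta = inject_noise(env, spec) - np.tile(env, (4, 1))
        sd = delta.std(axis=0)
        assert np.all(np.abs(sd - 0.01 * spec.sigma) / (0.01 * spec.sigma) < 0.10)

    def test_rounds_draw_independent_noise(self):
        rng = np.random.default_rng(4)
        env = rng.normal(size=(20, 5))
        out = inject_noise(env, NoiseSpec.from_matrix(env, rounds=2, seed=1))
        assert not np.array_equal(out[:20] - env, out[20:] - env)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inject_noise(np.ones((5, 3)), NoiseSpec(sigma=np.ones(5)))


class TestTrainAdnn:
    def test_architecture_and_fit(self, small_adnn, small_table, small_taxa):
        widths = [p.shape for layer in small_adnn.net.layers
                  for p in layer.params()[:1] if p.ndim == 2]
        assert widths == [(5, 32), (32, 64), (64, 128), (128, 64), (64, 32),
                          (32, len(small_taxa))]
        assert small_adnn.r2 > 0.5
        # history logged at the 100-epoch cadence
        assert [e for e, _, _ in small_adnn.history][:3] == [100, 200, 300]

    def test_same_seed_identical_checkpoint(self, small_table, small_taxa):
        m1 = train_adnn(small_table, small_taxa, epochs=150, seed=5)
        m2 = train_adnn(small_table, small_taxa, epochs=150, seed=5)
        env = small_table.env_matrix[:10]
        assert np.array_equal(m1.predict(env), m2.predict(env))

    def test_predictions_nonnegative(self, small_adnn, small_table):
        assert small_adnn.predict(small_table.env_matrix).min() >= 0.0

    def test_empty_selection_rejected(self, small_table):
        with pytest.raises(ValueError):
            train_adnn(small_table, [], epochs=10)

    def test_checkpoint_roundtrip(self, tmp_path, small_adnn, small_table):
        path = tmp_path / "adnn.npz"
        small_adnn.save(path)
        back = AdnnModel.load(path)
        env = small_table.env_matrix[:7]
        assert np.array_equal(back.predict(env), small_adnn.predict(env))
        assert back.r2 == small_adnn.r2


class TestAugmentedSet:
    def test_counts_partition(self, small_table, small_augmented):
        n = small_table.n_samples
        assert small_augmented.n_real == n
        assert small_augmented.n_synthetic == 4 * n
        assert len(small_augmented) == 5 * n

    def test_real_rows_bit_identical(self, small_table, small_augmented):
        real = small_augmented.provenance == "real"
        assert np.array_equal(small_augmented.env[real], small_table.env_matrix)
        assert np.array_equal(
            small_augmented.taxa[real],
            small_table.taxa_matrix(small_augmented.selected_taxa),
        )

    def test_zero_rounds_equals_real_projection(self, small_table, small_adnn):
        spec = NoiseSpec.from_matrix(small_table.env_matrix, rounds=0)
        aug = build_augmented_set(small_table, small_adnn, spec)
        assert len(aug) == small_table.n_samples
        assert (aug.provenance == "real").all()

    def test_bookkeeping_any_rounds(self, small_table, small_adnn):
        for rounds in (1, 3):
            spec = NoiseSpec.from_matrix(small_table.env_matrix, rounds=rounds)
            aug = build_augmented_set(small_table, small_adnn, spec)
            assert len(aug) == small_table.n_samples * (1 + rounds)

    def test_weak_generator_warns(self, small_table, small_adnn):
        weak = AdnnModel(small_adnn.net, small_adnn.selected_taxa,
                         small_adnn.x_stats, small_adnn.y_stats, 0.40,
                         small_adnn.history)
        spec = NoiseSpec.from_matrix(small_table.env_matrix, rounds=1)
        with pytest.warns(ReliabilityWarning):
            build_augmented_set(small_table, weak, spec)

    def test_taxa_mismatch_rejected(self, small_table, small_adnn):
        spec = NoiseSpec.from_matrix(small_table.env_matrix)
        with pytest.raises(ValueError):
            build_augmented_set(small_table, small_adnn, spec, selected_taxa=[1, 2])

    def test_csv_roundtrip(self, tmp_path, small_augmented):
        path = tmp_path / "aug.csv"
        small_augmented.to_csv(path)
        back = AugmentedSet.from_csv(path)
        assert back.selected_taxa == small_augmented.selected_taxa
        assert np.allclose(back.env, small_augmented.env)
        assert list(back.provenance) == list(small_augmented.provenance)
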