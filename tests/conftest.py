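"""Shared fixtures: small seeded cohorts and pre-trained small models.

Session-scoped so expensive training happens once per run; every
fixture is fully deterministic.
"""

import numpy as np
import pytest

from microstress.adnn_augment import NoiseSpec, build_augmented_set, train_adnn
from microstress.feature_selection import rank_features_rfr, select_top_k
from microstress.synthetic_community import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_bottles=40, n_taxa=60, n_responsive=6, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[1]


@pytest.fixture(scope="session")
def small_ranking(small_table):
    return rank_features_rfr(small_table, seed=0, n_estimators=200)


@pytest.fixture(scope="session")
def small_taxa(small_ranking):
    return select_top_k(small_ranking, 4)


@pytest.fixture(scope="session")
def small_adnn(small_table, small_taxa):
    return train_adnn(small_table, small_taxa, epochs=400, seed=0)


@pytest.fixture(scope="session")
def small_augmented(small_table, small_adnn):
    spec = NoiseSpec.from_matrix(small_table.env_matrix, seed=0)
    return build_augmented_set(small_table, small_adnn, spec)


@pytest.fixture(scope="session")
def legal_oil_values(small_table):
    return np.unique(small_table.oil_enc)
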