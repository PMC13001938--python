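"""Taxa ranking by random-forest importance, with PCA/t-SNE baselines.

The primary reduction route regresses the full taxa count block onto the
encoded oil type with a random forest (2,500 trees, max depth 25, MSE
split criterion) and ranks taxa by mean decrease in impurity — the
normalized MSE reduction attributable to splits on each taxon, summed
over the forest.  PCA and t-SNE 2-D embeddings are provided for the
conventional ordination comparison; they reduce dimension but lose the
taxon-level interpretability the ranking keeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.manifold import TSNE

from .data_model import SampleTable

__all__ = ["FeatureRanking", "rank_features_rfr", "select_top_k", "pca_2d", "tsne_2d"]


@dataclass
class FeatureRanking:
    """Taxa ordered by non-increasing importance (ties: ascending index).

    ``entries`` holds (1-based taxon index, normalized importance);
    importances are ≥ 0 and sum to 1.  ``train_r2`` is the forest's
    training R² on the full table.
    """

    entries: list[tuple[int, float]]
    train_r2: float

    @property
    def taxa(self) -> list[int]:
        return [t for t, _ in self.entries]

    @property
    def importances(self) -> np.ndarray:
        return np.array([imp for _, imp in self.entries])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "taxon": self.taxa,
                "importance": self.importances,
            }
        )

    def to_tsv(self, path) -> None:
        self.as_dataframe().to_csv(path, sep="\t", index=False)


def rank_features_rfr(
    table: SampleTable,
    seed: int = 0,
    n_estimators: int = 2500,
    max_depth: int = 25,
    importance: str = "mdi",
) -> FeatureRanking:
    """Rank taxa by random-forest importance for the encoded oil type.

    ``importance`` selects mean decrease in impurity (``"mdi"``, the
    default) or seeded permutation importance (``"permutation"``, an
    optional cross-check; its raw scores are renormalized to sum to 1
    after clipping at 0).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to rank features")
    y = table.oil_enc
    if np.var(y) == 0:
        raise ValueError("oil_enc target is constant; ranking undefined")
    X = table.counts.astype(float)
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        max_depth=max_depth,
        criterion="squared_error",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    train_r2 = float(forest.score(X, y))
    if importance == "mdi":
        imp = forest.feature_importances_
    elif importance == "permutation":
        res = permutation_importance(forest, X, y, n_repeats=5, random_state=seed, n_jobs=1)
        imp = np.clip(res.importances_mean, 0.0, None)
    else:
        raise ValueError(f"unknown importance flavor {importance!r}")
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    # non-increasing importance, ties broken by ascending taxon index
    order = np.lexsort((np.arange(len(imp)), -imp))
    entries = [(int(i) + 1, float(imp[i])) for i in order]
    return FeatureRanking(entries=entries, train_r2=train_r2)


def select_top_k(ranking: FeatureRanking, k: int) -> list[int]:
    """First k taxon indices of the ranking (1-based)."""
    if not 1 <= k <= len(ranking.entries):
        raise ValueError(f"k must be in 1..{len(ranking.entries)}, got {k}")
    return ranking.taxa[:k]


def pca_2d(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered projection onto the top-2 principal axes.

    Returns (n×2 coordinates, explained-variance fractions).  Counts are
    centered but not scaled.
    """
    X = np.asarray(counts, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for a 2-D PCA")
    if np.allclose(X - X.mean(axis=0), 0.0):
        raise ValueError("matrix has no variance; PCA degenerate")
    model = PCA(n_components=2)
    coords = model.fit_transform(X)
    return coords, model.explained_variance_ratio_


def tsne_2d(counts: np.ndarray, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Seeded 2-D t-SNE embedding (visualization / comparison only)."""
    X = np.asarray(counts, dtype=float)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for n={X.shape[0]} (need n > 3·perplexity)"
        )
    model = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return model.fit_transform(X)
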