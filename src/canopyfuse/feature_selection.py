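"""Random-forest Gini importance ranking and correlation pruning.

Importance is the random-forest standard: the mean decrease in Gini
impurity a feature contributes across all splits, averaged over trees.
Correlated features are then pruned greedily in importance order — a
feature is dropped when its absolute Pearson correlation with an
already-kept feature reaches the threshold, so within any correlated
group only the most important member survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

DEFAULT_N_TREES = 500
DEFAULT_R_THRESHOLD = 0.90


@dataclass
class ImportanceRanking:
    """Features sorted by non-increasing importance, plus the pruned set."""

    names: list                     # descending importance
    importances: np.ndarray         # raw mean decrease in Gini, same order
    normalized: np.ndarray          # importances / max importance
    kept: list = field(default_factory=list)
    dropped_for: dict = field(default_factory=dict)  # dropped -> kept name
    r_threshold: float = None

    def to_frame(self) -> pd.DataFrame:
        kept = set(self.kept)
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.names) + 1),
                "feature": self.names,
                "importance": self.importances,
                "normalized": self.normalized,
                "kept": [n in kept for n in self.names],
                "dropped_for": [self.dropped_for.get(n, "") for n in self.names],
            }
        )


class GiniImportanceSelector(BaseEstimator):
    """sklearn-style selector: RF Gini importance ranking + pruning.

    Parameters
    ----------
    n_trees : forest size (default 500).
    r_threshold : |Pearson r| at or above which two features count as
        highly correlated (default 0.90).
    random_state : forest seed.

    After ``fit``, ``ranking_`` holds the :class:`ImportanceRanking` and
    ``transform`` selects the pruned columns (in importance order) from a
    feature table.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES,
                 r_threshold: float = DEFAULT_R_THRESHOLD,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.r_threshold = r_threshold
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        ranking = rank_importance(
            X, y, n_trees_rf=self.n_trees, seed=self.random_state
        )
        self.ranking_ = prune_correlated(ranking, X, self.r_threshold)
        return self

    def transform(self, X: pd.DataFrame, k: int = None) -> pd.DataFrame:
        check_is_fitted(self, "ranking_")
        cols = self.ranking_.kept if k is None else self.ranking_.kept[:k]
        return X[cols]


def rank_importance(features: pd.DataFrame, labels,
                    n_trees_rf: int = DEFAULT_N_TREES,
                    seed: int = 0) -> ImportanceRanking:
    """Rank features by mean decrease in Gini impurity.

    Columns are processed in name order internally so the ranking is
    invariant to the column order of the input table; ties in importance
    break by feature name.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 5:
        raise ValueError("every class needs at least 5 samples")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")

    ordered = features[sorted(features.columns)]
    rf = RandomForestClassifier(
        n_estimators=n_trees_rf,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(ordered.to_numpy(float), y)
    imp = rf.feature_importances_
    order = np.lexsort((list(ordered.columns), -imp))
    names = [ordered.columns[i] for i in order]
    imp_sorted = imp[order]
    top = imp_sorted.max() if imp_sorted.max() > 0 else 1.0
    return ImportanceRanking(
        names=names,
        importances=imp_sorted,
        normalized=imp_sorted / top,
    )


def prune_correlated(ranking: ImportanceRanking, features: pd.DataFrame,
                     r_threshold: float = DEFAULT_R_THRESHOLD) -> ImportanceRanking:
    """Greedy sweep in descending importance: drop any feature whose
    |Pearson r| with an already-kept feature is >= the threshold."""
    X = features[ranking.names].to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    kept_idx: list = []
    dropped_for: dict = {}
    for j, name in enumerate(ranking.names):
        drop = None
        for ki in kept_idx:
            if sd[j] == 0 or sd[ki] == 0:
                # constant columns: correlation undefined; a constant never
                # duplicates a varying feature, two constants do duplicate
                if sd[j] == 0 and sd[ki] == 0:
                    drop = ki
                    break
                continue
            r = np.corrcoef(X[:, j], X[:, ki])[0, 1]
            if abs(r) >= r_threshold:
                drop = ki
                break
        if drop is None:
            kept_idx.append(j)
        else:
            dropped_for[name] = ranking.names[drop]
    return ImportanceRanking(
        names=ranking.names,
        importances=ranking.importances,
        normalized=ranking.normalized,
        kept=[ranking.names[i] for i in kept_idx],
        dropped_for=dropped_for,
        r_threshold=r_threshold,
    )
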