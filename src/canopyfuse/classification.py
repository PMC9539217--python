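"""SVM species identification with incremental feature counts.

For each of 120 seeded repetitions a stratified 60/40 train/test split is
drawn; for each feature count k on the grid an RBF-kernel SVM (one-vs-one,
C = 10, gamma scaled by feature variance) is trained on the top-k features
of the importance ranking — standardized with training-set statistics only
— and scored on the held-out 40%.  The mean overall-accuracy curve over
repetitions gives the accuracy-vs-feature-count profile, and the optimal k
is the smallest k whose mean OA is within a stability margin of the
maximum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, cohen_kappa_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .feature_selection import ImportanceRanking

DEFAULT_N_REPETITIONS = 120
DEFAULT_TRAIN_FRACTION = 0.60
DEFAULT_K_MAX = 40
DEFAULT_C = 10.0


class SpeciesSVM(ClassifierMixin, BaseEstimator):
    """Per-feature-standardized RBF SVM (one-vs-one multi-class).

    A thin sklearn estimator so the species classifier composes with
    pipelines and model selection; the incremental-feature experiment
    below builds on it.
    """

    def __init__(self, C: float = DEFAULT_C, kernel: str = "rbf",
                 gamma: str = "scale"):
        self.C = C
        self.kernel = kernel
        self.gamma = gamma

    def fit(self, X, y):
        self.pipeline_ = make_pipeline(
            StandardScaler(),
            SVC(C=self.C, kernel=self.kernel, gamma=self.gamma,
                decision_function_shape="ovo"),
        )
        self.pipeline_.fit(np.asarray(X, float), y)
        self.classes_ = self.pipeline_[-1].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, float))


@dataclass
class IncrementalRun:
    """Results of the repeated incremental-feature SVM experiment."""

    source: str                      # HSI | LiDAR | HSI+LiDAR
    k_grid: np.ndarray
    oa: np.ndarray                   # (n_repetitions, len(k_grid))
    kappa: np.ndarray
    n_repetitions: int
    train_fraction: float
    feature_order: list
    seeds: list = field(default_factory=list)
    optimal_k: int = None

    @property
    def mean_oa(self) -> np.ndarray:
        return self.oa.mean(axis=0)

    @property
    def mean_kappa(self) -> np.ndarray:
        return self.kappa.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_repetitions):
            for j, k in enumerate(self.k_grid):
                rows.append(
                    {
                        "source": self.source,
                        "k": int(k),
                        "repetition": r,
                        "OA": self.oa[r, j],
                        "Kappa": self.kappa[r, j],
                    }
                )
        return pd.DataFrame(rows)


def run_incremental_svm(features: pd.DataFrame, ranking: ImportanceRanking,
                        labels, source: str = "HSI+LiDAR",
                        k_max: int = DEFAULT_K_MAX,
                        n_repetitions: int = DEFAULT_N_REPETITIONS,
                        train_fraction: float = DEFAULT_TRAIN_FRACTION,
                        C: float = DEFAULT_C,
                        seed: int = 0) -> IncrementalRun:
    """Mean OA/Kappa versus number of top-ranked features.

    The k grid runs 1..min(k_max, available pruned features).  Each
    repetition draws an independent stratified split from a child seed of
    ``seed``; a repetition whose training fold misses a class is redrawn
    with a logged replacement seed.
    """
    y = pd.Series(np.asarray(labels), index=features.index)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise ValueError("every class needs at least 5 samples")
    order = [f for f in ranking.kept if f in features.columns]
    if len(order) == 0:
        raise ValueError("ranking shares no features with the table")
    if len(order) < k_max:
        warnings.warn(
            f"only {len(order)} pruned features available; grid truncates"
        )
    k_grid = np.arange(1, min(k_max, len(order)) + 1)
    X_all = features[order[: k_grid[-1]]].to_numpy(float)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(n_repetitions * 2)]
    oa = np.empty((n_repetitions, len(k_grid)))
    kappa = np.empty_like(oa)
    used_seeds = []
    spare = n_repetitions
    for r in range(n_repetitions):
        s = child_seeds[r]
        for _attempt in range(10):
            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=train_fraction, random_state=s
            )
            (tr, te), = splitter.split(X_all, y)
            if len(np.unique(y.iloc[tr])) == len(classes):
                break
            s = child_seeds[spare % len(child_seeds)]  # logged re-seed
            spare += 1
        used_seeds.append(s)
        scaler = StandardScaler().fit(X_all[tr])
        Xtr = scaler.transform(X_all[tr])
        Xte = scaler.transform(X_all[te])
        ytr, yte = y.iloc[tr], y.iloc[te]
        for j, k in enumerate(k_grid):
            svc = SVC(C=C, kernel="rbf", gamma="scale",
                      decision_function_shape="ovo")
            svc.fit(Xtr[:, :k], ytr)
            pred = svc.predict(Xte[:, :k])
            oa[r, j] = accuracy_score(yte, pred)
            kappa[r, j] = cohen_kappa_score(yte, pred)

    return IncrementalRun(
        source=source, k_grid=k_grid, oa=oa, kappa=kappa,
        n_repetitions=n_repetitions, train_fraction=train_fraction,
        feature_order=order[: k_grid[-1]], seeds=used_seeds,
    )


def select_optimal_k(run: IncrementalRun, stability_margin: float = 0.0):
    """Smallest k whose mean OA is within ``stability_margin`` of the
    maximum mean OA.  Sets ``run.optimal_k`` and returns (k, best OA)."""
    mean = run.mean_oa
    target = mean.max() - stability_margin
    idx = int(np.nonzero(mean >= target)[0][0])
    run.optimal_k = int(run.k_grid[idx])
    return run.optimal_k, float(mean[idx])


def classify_and_map(trees, features: pd.DataFrame, labels,
                     run: IncrementalRun, seed: int = 0,
                     C: float = DEFAULT_C, path=None):
    """Train the final model at the optimal k and attribute every crown.

    A single stratified split (seeded) tags each labeled tree as train or
    test in the output properties; trees lacking features are attributed
    ``unclassified``.  Returns the thematic map as a GeoJSON
    FeatureCollection dict (optionally written to ``path``).
    """
    if run.optimal_k is None:
        select_optimal_k(run)
    cols = run.feature_order[: run.optimal_k]
    y = pd.Series(np.asarray(labels), index=features.index)
    X = features[cols]
    splitter = StratifiedShuffleSplit(
        n_splits=1, train_size=run.train_fraction, random_state=seed
    )
    (tr, te), = splitter.split(X, y)
    model = SpeciesSVM(C=C).fit(X.iloc[tr], y.iloc[tr])
    pred = pd.Series(model.predict(X), index=features.index)
    split_tag = pd.Series("train", index=features.index)
    split_tag.iloc[te] = "test"

    feats = []
    for t in trees:
        props = {"tree_id": int(t.tree_id)}
        if t.tree_id in pred.index:
            props["species_pred"] = str(pred.loc[t.tree_id])
            props["split"] = str(split_tag.loc[t.tree_id])
            props["species_ref"] = str(y.loc[t.tree_id])
        else:
            props["species_pred"] = "unclassified"
        geom = mapping(t.crown_polygon) if t.crown_polygon is not None else None
        feats.append({"type": "Feature", "geometry": geom, "properties": props})
    fc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc, model


def plot_accuracy_curves(runs, path):
    """Accuracy-versus-feature-count figure for one or more sources."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for run in runs:
        ax.plot(run.k_grid, 100 * run.mean_oa, marker="o", ms=3,
                label=run.source)
    ax.set_xlabel("Number of features")
    ax.set_ylabel("Mean overall accuracy (%)")
    ax.legend()
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_thematic_map(trees, predictions: dict, path):
    """Render crown polygons coloured by predicted species."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    species = sorted({p for p in predictions.values()})
    cmap = plt.get_cmap("tab10")
    colors = {s: cmap(i % 10) for i, s in enumerate(species)}
    fig, ax = plt.subplots(figsize=(6, 6))
    for t in trees:
        if t.crown_polygon is None:
            continue
        sp = predictions.get(t.tree_id, "unclassified")
        xy = np.asarray(t.crown_polygon.exterior.coords)
        ax.add_patch(MplPolygon(xy, closed=True, facecolor=colors.get(sp, "k"),
                                edgecolor="k", lw=0.3, alpha=0.85))
    ax.autoscale_view()
    ax.set_aspect("equal")
    handles = [plt.Line2D([], [], marker="s", ls="", color=colors[s], label=s)
               for s in species]
    ax.legend(handles=handles, fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
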