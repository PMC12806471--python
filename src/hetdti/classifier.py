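"""Random-forest scoring of fused drug-target pair representations.

The forest grows CART trees on bootstrap resamples, splitting nodes by the
Gini index

    Gini_index(X, f, s) = sum_v |X^v|/|X| * Gini(X^v),   Gini(X) = 1 - sum_i p_i^2

and scores a pair as the mean positive-class leaf probability over trees.
The Gini computations and an exhaustive split search are implemented here
directly; the fitted ensemble itself is backed by scikit-learn's
RandomForestClassifier, which implements the identical bootstrap/CART/Gini
procedure with seeded determinism and mean-decrease-in-impurity feature
importances.
"""

from __future__ import annotations

import pickle
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier


def gini_impurity(labels) -> float:
    """Gini(X) = 1 - sum_i p_i^2 over the class proportions of ``labels``."""
    labels = list(labels)
    if not labels:
        raise ValueError("gini_impurity of an empty label set is undefined")
    n = len(labels)
    return 1.0 - sum((c / n) ** 2 for c in Counter(labels).values())


def gini_index(X: np.ndarray, y, feature: int, threshold: float) -> float:
    """Weighted child impurity of the split ``X[:, feature] <= threshold``.

    Both sides of the split must be nonempty.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    left = X[:, feature] <= threshold
    if not left.any() or left.all():
        raise ValueError("split must partition the samples into two nonempty parts")
    n = len(y)
    return (left.sum() / n) * gini_impurity(y[left]) + \
           ((~left).sum() / n) * gini_impurity(y[~left])


def best_split_exhaustive(X: np.ndarray, y) -> tuple[int, float, float] | None:
    """Exhaustive CART split search: minimal Gini index over all candidates.

    Candidate thresholds are midpoints between consecutive sorted unique
    values of each feature; ties break toward the lowest feature index,
    then the lowest threshold. Returns (feature, threshold, gini_index),
    or None when no feature admits a split.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    best: tuple[int, float, float] | None = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            g = gini_index(X, y, f, thr)
            if best is None or g < best[2] - 1e-15:
                best = (f, thr, g)
    return best


@dataclass
class ForestConfig:
    n_trees: int = 200
    max_features: str | int = "sqrt"  # "sqrt", "all", or an int
    min_leaf: int = 1
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class ForestModel:
    """A fitted ensemble plus the config that produced it."""

    estimator: RandomForestClassifier
    config: ForestConfig
    n_features: int

    @property
    def trees(self) -> list[DecisionTreeClassifier]:
        return list(self.estimator.estimators_)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ForestModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a ForestModel")
        return model


def fit_forest(Z: np.ndarray, y, config: ForestConfig | None = None,
               oob: bool = False) -> ForestModel:
    """Fit the random forest on pair features Z and binary labels y."""
    if config is None:
        config = ForestConfig()
    Z = np.asarray(Z, dtype=np.float64)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels must contain both classes")
    max_features = config.max_features
    if max_features == "all":
        max_features = None
    est = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features=max_features,
        min_samples_leaf=config.min_leaf,
        bootstrap=config.bootstrap,
        oob_score=oob and config.bootstrap,
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(Z, y)
    return ForestModel(estimator=est, config=config, n_features=Z.shape[1])


def predict_scores(model: ForestModel, Z: np.ndarray) -> np.ndarray:
    """Mean positive-class leaf probability over the ensemble, in [0, 1]."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {Z.shape[1]} != training dimension {model.n_features}"
        )
    proba = model.estimator.predict_proba(Z)
    pos_col = list(model.estimator.classes_).index(1)
    return proba[:, pos_col]


def feature_importance(model: ForestModel) -> np.ndarray:
    """Mean decrease in Gini impurity per feature, normalized to sum to 1."""
    imp = model.estimator.feature_importances_
    total = imp.sum()
    return imp / total if total > 0 else imp
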