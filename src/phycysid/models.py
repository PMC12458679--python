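"""The 15-classifier zoo: specs, grid-searched training, feature importance.

Every classifier trains inside a StandardScaler pipeline, with the best
hyperparameter point chosen by mean accuracy over a stratified 20-fold
cross-validation on the training partition, then refit on the full
training partition.  Importances come from impurity for the tree
ensembles, from |coef_| (min–max normalized to [0, 1], averaged over
classes when multiclass) for the linear family, and are unavailable for
the distance/probabilistic models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import (LogisticRegression, Perceptron,
                                  RidgeClassifier, SGDClassifier)
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     train_test_split)
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

MODEL_NAMES = ("RF", "GB", "AdaBoost", "Bagging", "LR", "GNB", "BNB",
               "DecisionT", "QDA", "LDA", "MLPC", "KNN", "RC", "Perceptron",
               "SGDC")

IMPORTANCE_KIND = {
    "RF": "impurity", "GB": "impurity", "AdaBoost": "impurity",
    "DecisionT": "impurity",
    "LR": "coefficient", "RC": "coefficient", "Perceptron": "coefficient",
    "LDA": "coefficient", "SGDC": "coefficient", "MLPC": "coefficient",
    "QDA": "none", "GNB": "none", "BNB": "none", "KNN": "none",
    "Bagging": "none",
}

CV_FOLDS = 20

# small documented default grids; override any of them from a YAML file
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"n_estimators": [100], "max_depth": [None, 10]},
    "GB": {"n_estimators": [100], "learning_rate": [0.1]},
    "AdaBoost": {"n_estimators": [50, 100]},
    "Bagging": {"n_estimators": [10, 30]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "GNB": {"var_smoothing": [1e-9]},
    "BNB": {"alpha": [0.5, 1.0]},
    "DecisionT": {"max_depth": [None, 5, 10]},
    # the unregularized covariance is singular for the nested group-fraction
    # descriptors, so the QDA grid starts at a small positive reg_param
    "QDA": {"reg_param": [0.1, 0.5]},
    "LDA": {"solver": ["svd"]},
    "MLPC": {"hidden_layer_sizes": [(50,)], "alpha": [1e-4, 1e-3]},
    "KNN": {"n_neighbors": [3, 5, 7]},
    "RC": {"alpha": [0.1, 1.0, 10.0]},
    "Perceptron": {"alpha": [1e-4, 1e-3]},
    "SGDC": {"alpha": [1e-4, 1e-3]},
}


# estimator class, fixed constructor kwargs, whether it takes random_state
_ESTIMATORS: dict[str, tuple[type, dict, bool]] = {
    "RF": (RandomForestClassifier, {}, True),
    "GB": (GradientBoostingClassifier, {}, True),
    "AdaBoost": (AdaBoostClassifier, {}, True),
    "Bagging": (BaggingClassifier, {}, True),
    "LR": (LogisticRegression, {"max_iter": 2000}, True),
    "GNB": (GaussianNB, {}, False),
    "BNB": (BernoulliNB, {}, False),
    "DecisionT": (DecisionTreeClassifier, {}, True),
    "QDA": (QuadraticDiscriminantAnalysis, {}, False),
    "LDA": (LinearDiscriminantAnalysis, {}, False),
    "MLPC": (MLPClassifier, {"max_iter": 400}, True),
    "KNN": (KNeighborsClassifier, {}, False),
    "RC": (RidgeClassifier, {}, True),
    "Perceptron": (Perceptron, {}, True),
    "SGDC": (SGDClassifier, {}, True),
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family: name, seed, grid and importance kind."""

    name: str
    seed: int
    grid: Mapping[str, list]
    importance_kind: str

    def make(self) -> BaseEstimator:
        cls, kwargs, takes_seed = _ESTIMATORS[self.name]
        if takes_seed:
            return cls(random_state=self.seed, **kwargs)
        return cls(**kwargs)


def load_grids(path: str | Path) -> dict[str, dict[str, list]]:
    """Merge grid overrides from YAML over the documented defaults."""
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    grids = {k: dict(v) for k, v in DEFAULT_GRIDS.items()}
    for name, grid in overrides.items():
        if name not in grids:
            raise ValueError(f"unknown model name {name!r}")
        grids[name] = {k: [tuple(x) if isinstance(x, list) else x for x in v]
                       for k, v in grid.items()}
    return grids


def build_zoo(seed: int = 42,
              grids: Mapping[str, Mapping[str, list]] | None = None,
              names: Sequence[str] | None = None) -> dict[str, ModelSpec]:
    """The default zoo: all 15 specs (or a named subset), seeded."""
    grids = grids or DEFAULT_GRIDS
    names = tuple(names) if names is not None else MODEL_NAMES
    unknown = set(names) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown model names: {sorted(unknown)}")
    return {name: ModelSpec(name, seed, dict(grids[name]),
                            IMPORTANCE_KIND[name])
            for name in names}


@dataclass
class DatasetSplit:
    """Stratified 70/30 train/test partition of a feature table."""

    train_X: pd.DataFrame
    test_X: pd.DataFrame
    train_y: np.ndarray
    test_y: np.ndarray
    seed: int


def split_dataset(X: pd.DataFrame, y, test_fraction: float = 0.30,
                  seed: int = 42) -> DatasetSplit:
    """Disjoint, exhaustive, stratified split; reproducible for fixed seed."""
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise ValueError(f"classes with a single member cannot be split: {small}")
    train_X, test_X, train_y, test_y = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed)
    return DatasetSplit(train_X, test_X, train_y, test_y, seed)


@dataclass
class TrainedModel:
    """A fitted (scaler + classifier) pipeline with its CV summary."""

    spec: ModelSpec
    pipeline: Pipeline
    best_grid_point: dict[str, Any]
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    cv_fold_accuracies: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def classes_(self) -> np.ndarray:
        return self.pipeline.named_steps["clf"].classes_

    def predict(self, X) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray | None:
        clf = self.pipeline.named_steps["clf"]
        if not hasattr(clf, "predict_proba"):
            return None
        return self.pipeline.predict_proba(np.asarray(X, dtype=float))


def train_with_grid_search(spec: ModelSpec, split: DatasetSplit,
                           cv_folds: int = CV_FOLDS) -> TrainedModel:
    """Grid-search a spec on the training partition and refit the best point.

    Standardization is fitted on training rows only (inside the pipeline,
    so each CV fold re-fits its own scaler).  The best point maximizes the
    mean of the ``cv_folds`` stratified fold accuracies.
    """
    if not spec.grid:
        raise ValueError(f"{spec.name}: empty hyperparameter grid")
    y = np.asarray(split.train_y)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{spec.name}: training labels contain a single class")
    X = np.asarray(split.train_X, dtype=float)
    variances = X.var(axis=0)
    if (variances == 0).any():
        idx = np.flatnonzero(variances == 0).tolist()
        warnings.warn(
            f"{spec.name}: zero-variance feature columns {idx} pass through "
            "standardization unscaled", UserWarning, stacklevel=2)
    pipe = Pipeline([("scale", StandardScaler()), ("clf", spec.make())])
    grid = {f"clf__{k}": v for k, v in spec.grid.items()}
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                         random_state=split.seed)
    search = GridSearchCV(pipe, grid, scoring="accuracy", cv=cv, refit=True,
                          n_jobs=None)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning,
                                module="sklearn")
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        search.fit(X, y)
    best = search.best_index_
    folds = np.array([search.cv_results_[f"split{i}_test_score"][best]
                      for i in range(cv_folds)])
    feature_names = tuple(split.train_X.columns) if isinstance(
        split.train_X, pd.DataFrame) else tuple(
            f"f{i}" for i in range(X.shape[1]))
    return TrainedModel(
        spec=spec,
        pipeline=search.best_estimator_,
        best_grid_point={k.removeprefix("clf__"): v
                         for k, v in search.best_params_.items()},
        cv_accuracy_mean=float(folds.mean()),
        cv_accuracy_sd=float(folds.std(ddof=0)),
        cv_fold_accuracies=folds,
        feature_names=feature_names,
    )


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("degenerate importance vector (all equal); returning zeros",
                      UserWarning, stacklevel=2)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def extract_feature_importance(model: TrainedModel) -> pd.Series | None:
    """Per-descriptor weights in [0, 1], or None for models without them.

    Impurity models report their native (sum-to-one) importances; linear
    models report |coef_| averaged over class rows and min–max normalized,
    so the largest weight is exactly 1 and the smallest exactly 0.  The
    multilayer perceptron uses |first-layer weights| summed over hidden
    units before the same normalization.
    """
    kind = model.spec.importance_kind
    if kind == "none":
        return None
    clf = model.pipeline.named_steps["clf"]
    if kind == "impurity":
        if not hasattr(clf, "feature_importances_"):
            raise ValueError(f"{model.name}: model is not fitted")
        weights = np.asarray(clf.feature_importances_, dtype=float)
    else:
        if isinstance(clf, MLPClassifier):
            weights = np.abs(clf.coefs_[0]).sum(axis=1)
        else:
            if not hasattr(clf, "coef_"):
                raise ValueError(f"{model.name}: model is not fitted")
            coef = np.atleast_2d(clf.coef_)
            weights = np.abs(coef).mean(axis=0)
        weights = _minmax(weights)
    return pd.Series(weights, index=list(model.feature_names),
                     name=model.name)
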