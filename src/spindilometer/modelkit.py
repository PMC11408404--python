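"""Filter feature selection and the five-classifier bank.

Selection is a univariate filter: a one-way ANOVA F statistic per feature
(higher = better class separation), with mutual information available as an
alternative.  The classifier bank is KNN, SVM (RBF), decision tree,
Gaussian naive Bayes, and extremely randomized trees, all trained on
z-scored features where the standardization statistics come from the
training rows only.  Training and prediction are deterministic given the
seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ALGORITHMS",
    "TrainedModel",
    "filter_scores",
    "select_top_k",
    "train",
    "predict",
    "predict_scores",
]

ALGORITHMS = ("KNN", "SVM", "DT", "NB", "ETC")

DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "KNN": {"n_neighbors": 5, "metric": "euclidean"},
    "SVM": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "DT": {"criterion": "gini", "max_depth": None},
    "NB": {},
    "ETC": {"n_estimators": 100, "criterion": "gini"},
}


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce predictions."""

    algorithm: str
    feature_names: list[str]
    selected_features: list[int]
    hyperparameters: dict[str, Any]
    seed: int
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    estimator: Any

    def summary(self) -> dict[str, Any]:
        """JSON-serializable description (fitted state only where small)."""
        return {
            "algorithm": self.algorithm,
            "feature_names": self.feature_names,
            "selected_features": self.selected_features,
            "selected_feature_names": [
                self.feature_names[i] for i in self.selected_features
            ],
            "hyperparameters": {
                k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
                for k, v in self.hyperparameters.items()
            },
            "seed": self.seed,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
        }


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def filter_scores(X, labels, method: str = "anova_f", seed: int = 0) -> np.ndarray:
    """Per-feature class-separation score.

    ``anova_f`` (default): one-way ANOVA F statistic between the two label
    groups; a feature constant across all rows (or with zero between-class
    difference and zero within-class variance) scores 0.  ``mutual_info``:
    estimated mutual information with the label.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("filter scores require both classes present")
    if not np.all(np.isfinite(Xm)):
        raise ValueError("feature matrix must be finite")
    if method == "anova_f":
        # constant features are defined to score 0, so sklearn's warning
        # about them is expected noise here
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Features .* are constant")
            f_stat, _ = f_classif(Xm, y)
        return np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    if method == "mutual_info":
        return mutual_info_classif(Xm, y, random_state=seed)
    raise ValueError(f"unknown filter method {method!r}")


def select_top_k(scores: np.ndarray, k: int = 10) -> list[int]:
    """Indices of the k largest scores; ties broken toward the lower index."""
    scores = np.asarray(scores, dtype=float)
    if not 1 <= k <= scores.size:
        raise ValueError(f"k={k} out of range for {scores.size} features")
    # stable sort on -score keeps lower indices first among ties
    order = np.argsort(-scores, kind="stable")
    return sorted(int(i) for i in order[:k])


def _build_estimator(algorithm: str, hyper: dict[str, Any], seed: int):
    if algorithm == "KNN":
        return KNeighborsClassifier(**hyper)
    if algorithm == "SVM":
        return SVC(**hyper, random_state=seed)
    if algorithm == "DT":
        return DecisionTreeClassifier(**hyper, random_state=seed)
    if algorithm == "NB":
        return GaussianNB(**hyper)
    if algorithm == "ETC":
        return ExtraTreesClassifier(**hyper, random_state=seed)
    raise ValueError(
        f"unknown algorithm {algorithm!r}; valid names: {list(ALGORITHMS)}"
    )


def train(
    algorithm: str,
    X,
    labels,
    hyperparameters: dict[str, Any] | None = None,
    seed: int = 0,
    selected_features: list[int] | None = None,
) -> TrainedModel:
    """Fit one of the five classifiers on (a feature subset of) X.

    Features are z-scored internally using mean/std of the *training* rows
    only; the statistics are stored on the model and reapplied at
    prediction time, so no test-set information leaks into scaling.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(labels).astype(int)
    if Xm.shape[0] != y.size:
        raise ValueError("X rows and labels must align")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires both classes present")
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per class")
    if selected_features is None:
        selected_features = list(range(Xm.shape[1]))
    if not selected_features or max(selected_features) >= Xm.shape[1]:
        raise ValueError("selected_features out of column range")
    hyper = dict(DEFAULT_HYPERPARAMETERS[algorithm.upper()]
                 if algorithm.upper() in DEFAULT_HYPERPARAMETERS else {})
    algorithm = algorithm.upper()
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; valid names: {list(ALGORITHMS)}"
        )
    if hyperparameters:
        hyper.update(hyperparameters)

    sub = Xm[:, selected_features]
    mean = sub.mean(axis=0)
    std = sub.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    est = _build_estimator(algorithm, hyper, seed)
    est.fit((sub - mean) / std, y)
    return TrainedModel(
        algorithm=algorithm,
        feature_names=names,
        selected_features=list(selected_features),
        hyperparameters=hyper,
        seed=seed,
        scaler_mean=mean,
        scaler_std=std,
        estimator=est,
    )


def _transform(model: TrainedModel, X) -> np.ndarray:
    Xm, names = _as_matrix(X)
    if isinstance(X, pd.DataFrame):
        missing = [n for n in model.feature_names if n not in names]
        if missing:
            raise ValueError(f"feature columns missing at prediction: {missing}")
        Xm = X[model.feature_names].to_numpy(dtype=float)
    elif Xm.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, got {Xm.shape[1]}"
        )
    sub = Xm[:, model.selected_features]
    return (sub - model.scaler_mean) / model.scaler_std


def predict_scores(model: TrainedModel, X) -> np.ndarray:
    """Positive-class score in [0, 1] per row.

    KNN: fraction of positive neighbors; SVM: logistic of the decision
    value; tree/forest/NB: positive-class probability.
    """
    Z = _transform(model, X)
    est = model.estimator
    if model.algorithm == "SVM":
        return expit(est.decision_function(Z))
    proba = est.predict_proba(Z)
    pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
    return proba[:, pos_col]


def predict(model: TrainedModel, X) -> np.ndarray:
    """Binary labels: scores thresholded at 0.5."""
    return (predict_scores(model, X) >= 0.5).astype(int)
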