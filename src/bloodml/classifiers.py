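"""The five-model zoo with a uniform train/score interface.

Models: random forest, logistic regression, RBF-kernel SVM, k-nearest
neighbours (k=5, Euclidean) and gradient-boosted trees.  Scores are
oriented so that higher means more case-like; tree ensembles expose
normalized feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "MODEL_IDS",
    "SCALE_SENSITIVE",
    "ModelSpec",
    "FittedModel",
    "make_estimator",
    "train_model",
    "predict_scores",
    "predict_labels",
    "feature_importances",
]

MODEL_IDS = (
    "random_forest",
    "logistic_regression",
    "svm_rbf",
    "knn",
    "gradient_boosting",
)

#: Models whose decision geometry depends on feature scale; they should be
#: fed standardized features.  Tree models take unscaled features.
SCALE_SENSITIVE = frozenset({"logistic_regression", "svm_rbf", "knn"})

#: Models that expose feature importances.
IMPORTANCE_MODELS = frozenset({"random_forest", "gradient_boosting"})

_DEFAULTS: dict[str, dict[str, Any]] = {
    "random_forest": dict(n_estimators=100, criterion="gini", max_features="sqrt"),
    # sklearn's LogisticRegression applies the L2 (ridge) penalty by default
    "logistic_regression": dict(C=1.0, max_iter=2000),
    "svm_rbf": dict(C=1.0, gamma="scale"),
    "knn": dict(n_neighbors=5, metric="euclidean"),
    "gradient_boosting": dict(n_estimators=100, learning_rate=0.3, max_depth=6),
}


@dataclass(frozen=True)
class ModelSpec:
    """A model identifier plus hyperparameter overrides and a seed."""

    model_id: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of {MODEL_IDS}"
            )
        unknown = set(self.hyperparams) - set(_DEFAULTS[self.model_id])
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.model_id}: {sorted(unknown)}"
            )


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: Any
    feature_names: list[str]

    @property
    def is_probabilistic(self) -> bool:
        return self.spec.model_id != "svm_rbf"


def make_estimator(model_id: str, seed: int = 0, hyperparams: dict | None = None):
    """Build an unfitted scikit-learn estimator at the zoo's defaults."""
    params = dict(_DEFAULTS[model_id])
    params.update(hyperparams or {})
    if model_id == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if model_id == "logistic_regression":
        return LogisticRegression(**params)
    if model_id == "svm_rbf":
        return SVC(kernel="rbf", **params)
    if model_id == "knn":
        return KNeighborsClassifier(**params)
    if model_id == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model_id {model_id!r}")


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def train_model(spec: ModelSpec, X, y) -> FittedModel:
    """Fit the spec's estimator.  ``y`` must be binary {0, 1}; KNN clips k to
    ``n_train - 1`` (with a warning) when the fold is smaller than k."""
    matrix, names = _as_matrix(X)
    if matrix.size == 0:
        raise ValueError("empty feature matrix")
    if np.isnan(matrix).any():
        raise ValueError("feature matrix contains missing values; impute first")
    y = np.asarray(y)
    labels = set(np.unique(y))
    if not labels <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(labels)}")

    params = dict(spec.hyperparams)
    if spec.model_id == "knn":
        k = params.get("n_neighbors", _DEFAULTS["knn"]["n_neighbors"])
        if k >= len(y):
            clipped = max(1, len(y) - 1)
            warnings.warn(
                f"KNN k={k} exceeds n_train-1={len(y) - 1}; clipping to {clipped}",
                stacklevel=2,
            )
            params["n_neighbors"] = clipped

    estimator = make_estimator(spec.model_id, seed=spec.seed, hyperparams=params)
    estimator.fit(matrix, y)
    return FittedModel(spec=spec, estimator=estimator, feature_names=names)


def _check_columns(model: FittedModel, X) -> np.ndarray:
    matrix, names = _as_matrix(X)
    if isinstance(X, pd.DataFrame) and names != model.feature_names:
        raise ValueError(
            f"feature columns {names} do not match training columns "
            f"{model.feature_names}"
        )
    if matrix.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} columns, got {matrix.shape[1]}"
        )
    return matrix


def predict_scores(model: FittedModel, X) -> np.ndarray:
    """Continuous case-likeness scores, one per row (higher = more case-like).

    Probability models return P(case); the SVM returns its signed margin.
    """
    matrix = _check_columns(model, X)
    if model.is_probabilistic:
        classes = list(model.estimator.classes_)
        return model.estimator.predict_proba(matrix)[:, classes.index(1)]
    return model.estimator.decision_function(matrix)


def predict_labels(model: FittedModel, X) -> np.ndarray:
    """Hard 0/1 labels: scores thresholded at 0.5 (probabilities) or 0 (margins)."""
    scores = predict_scores(model, X)
    threshold = 0.5 if model.is_probabilistic else 0.0
    return (scores > threshold).astype(int)


def feature_importances(model: FittedModel) -> dict[str, float]:
    """Normalized impurity-decrease importances for the tree ensembles.

    Values are non-negative and sum to 1; a feature never used in a split
    scores 0.  Other model families raise.
    """
    if model.spec.model_id not in IMPORTANCE_MODELS:
        raise ValueError(
            f"feature importances unavailable for {model.spec.model_id}; "
            f"supported: {sorted(IMPORTANCE_MODELS)}"
        )
    raw = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = raw.sum()
    if total > 0:
        raw = raw / total
    return dict(zip(model.feature_names, raw.tolist()))
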