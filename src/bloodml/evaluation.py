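"""Repeated stratified k-fold cross-validation, confusion-matrix metrics,
ROC/AUC, and the before/after-selection comparative experiment.

Metric definitions (case = positive class)::

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    f1          = 2 * precision * recall / (precision + recall)

Undefined ratios (zero denominator) are reported as 0 and flagged.  AUC is
computed by threshold sweeping with tie grouping, which makes the trapezoid
area equal to the normalized Mann-Whitney U statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classifiers, gwo_select, preprocessing
from .preprocessing import design_matrix

__all__ = [
    "FoldPlan",
    "ConfusionCounts",
    "MetricSet",
    "ComparativeReport",
    "make_fold_plan",
    "confusion_counts",
    "compute_metrics",
    "roc_auc",
    "run_experiment",
    "ExperimentConfig",
]

CONDITIONS = ("before_gwo", "after_gwo")


@dataclass(frozen=True)
class FoldPlan:
    """Per-repeat fold assignment: ``assignments[r][i]`` is subject i's fold."""

    k: int
    repeats: int
    seed: int
    assignments: tuple[np.ndarray, ...]

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] == fold)

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[repeat] != fold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float | None = None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
        }


def make_fold_plan(labels, k: int = 10, repeats: int = 5, seed: int = 0) -> FoldPlan:
    """``repeats`` independent stratified k-fold partitions of the subjects.

    Every class must have at least ``k`` members.  Within each repeat, folds
    partition all subjects and per-fold class counts differ by at most one
    from perfect stratification.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(f"class {cls!r} has {cnt} members, fewer than k={k}")

    seed_rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(seed_rng.integers(2**31))
        )
        folds = np.empty(len(y), dtype=int)
        for fold_idx, (_, test_idx) in enumerate(splitter.split(np.zeros_like(y), y)):
            folds[test_idx] = fold_idx
        assignments.append(folds)
    return FoldPlan(k=k, repeats=repeats, seed=seed, assignments=tuple(assignments))


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """TP/TN/FP/FN with case (1) as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.size}, y_pred has {y_pred.size}"
        )
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Apply the metric formulas verbatim; zero denominators yield 0, flagged."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    undefined: set[str] = set()
    accuracy = (counts.tp + counts.tn) / counts.total
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity", undefined)
    specificity = _ratio(counts.tn, counts.tn + counts.fp, "specificity", undefined)
    precision = _ratio(counts.tp, counts.tp + counts.fp, "precision", undefined)
    if precision + sensitivity == 0:
        undefined.add("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        undefined=frozenset(undefined),
    )


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) by threshold sweep and trapezoid AUC.

    Tied scores are grouped into single sweep steps, so the trapezoid area
    equals the normalized Mann-Whitney U statistic (rank-average tie
    handling).  Requires at least one positive and one negative.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]

    # indices where the threshold actually moves (last element of each tie group)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), y_sorted.size - 1]
    tp_cum = np.cumsum(y_sorted)[distinct]
    fp_cum = np.cumsum(1 - y_sorted)[distinct]

    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of the comparative before/after-selection experiment."""

    k: int = 10
    repeats: int = 5
    seed: int = 0
    elimination_threshold: float = preprocessing.DEFAULT_ELIMINATION_THRESHOLD
    models: tuple[str, ...] = classifiers.MODEL_IDS
    model_params: dict = field(default_factory=dict)
    gwo_params: gwo_select.GWOParams = field(default_factory=gwo_select.GWOParams)
    fitness: gwo_select.FitnessSpec = field(default_factory=gwo_select.FitnessSpec)
    gwo_scope: str = "global"  # "global" or "per_fold"

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(classifiers.MODEL_IDS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if self.gwo_scope not in ("global", "per_fold"):
            raise ValueError("gwo_scope must be 'global' or 'per_fold'")


@dataclass
class ComparativeReport:
    """Fold-averaged metrics per model and condition, plus ROC and importances."""

    metrics: dict[tuple[str, str], MetricSet]
    pooled_auc: dict[tuple[str, str], float]
    roc_curves: dict[tuple[str, str], np.ndarray]
    selected_features: list[str]
    convergence_trace: list[float]
    importances: dict[str, dict[str, float]]
    config: ExperimentConfig

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for (model, condition), ms in self.metrics.items():
            row = {"model": model, "condition": condition}
            row.update(ms.as_dict())
            row["pooled_auc"] = self.pooled_auc[(model, condition)]
            rows.append(row)
        return pd.DataFrame(rows)


def _mean_metrics(metric_sets: list[MetricSet], aucs: list[float]) -> MetricSet:
    undefined = frozenset().union(*(ms.undefined for ms in metric_sets))
    return MetricSet(
        accuracy=float(np.mean([ms.accuracy for ms in metric_sets])),
        sensitivity=float(np.mean([ms.sensitivity for ms in metric_sets])),
        specificity=float(np.mean([ms.specificity for ms in metric_sets])),
        precision=float(np.mean([ms.precision for ms in metric_sets])),
        f1=float(np.mean([ms.f1 for ms in metric_sets])),
        auc=float(np.mean(aucs)) if aucs else None,
        undefined=undefined,
    )


def preprocess_full(
    cohort: pd.DataFrame, elimination_threshold: float
) -> tuple[pd.DataFrame, list[str]]:
    """Whole-table eliminate + impute + encode (used for global selection)."""
    reduced, dropped = preprocessing.eliminate_features(cohort, elimination_threshold)
    imputer = preprocessing.fit_imputer(reduced)
    complete = preprocessing.apply_imputer(imputer, reduced)
    return preprocessing.encode_sex(complete), dropped


def run_experiment(cohort: pd.DataFrame, config: ExperimentConfig) -> ComparativeReport:
    """Run the full comparative evaluation.

    Per repeat x fold: features are eliminated using train-fold missingness,
    imputer/scaler fit on the train fold only and applied to both sides,
    every enabled model is trained on (a) all surviving features and (b) the
    selected subset, and the test fold is scored.  Metrics are unweighted
    means over all k*repeats folds; ROC curves pool the out-of-fold scores
    of the last repeat.  With ``gwo_scope='global'`` the selection runs once
    on the fully preprocessed table before cross-validation; ``'per_fold'``
    nests it inside each training fold.
    """
    y_all = (cohort["group"] == "case").to_numpy(dtype=int)
    plan = make_fold_plan(y_all, k=config.k, repeats=config.repeats, seed=config.seed)

    selected: list[str] = []
    trace: list[float] = []
    if config.gwo_scope == "global":
        full_table, _ = preprocess_full(cohort, config.elimination_threshold)
        selection = gwo_select.run_gwo(full_table, config.gwo_params, config.fitness)
        selected = selection.selected_features
        trace = selection.trace

    per_fold_metrics: dict[tuple[str, str], list[MetricSet]] = {}
    per_fold_aucs: dict[tuple[str, str], list[float]] = {}
    last_repeat_scores: dict[tuple[str, str], np.ndarray] = {}

    for key in ((m, c) for m in config.models for c in CONDITIONS):
        per_fold_metrics[key] = []
        per_fold_aucs[key] = []
        last_repeat_scores[key] = np.full(len(cohort), np.nan)

    for repeat in range(plan.repeats):
        for fold in range(plan.k):
            train_idx = plan.train_indices(repeat, fold)
            test_idx = plan.test_indices(repeat, fold)
            train_raw = cohort.iloc[train_idx]
            test_raw = cohort.iloc[test_idx]

            train_red, dropped = preprocessing.eliminate_features(
                train_raw, config.elimination_threshold
            )
            test_red = test_raw.drop(columns=dropped)
            imputer = preprocessing.fit_imputer(train_red)
            train_tab = preprocessing.encode_sex(
                preprocessing.apply_imputer(imputer, train_red)
            )
            test_tab = preprocessing.encode_sex(
                preprocessing.apply_imputer(imputer, test_red)
            )

            X_train, y_train = design_matrix(train_tab)
            X_test, y_test = design_matrix(test_tab)

            scale_cols = list(X_train.columns)
            scaler = preprocessing.fit_scaler(X_train, columns=scale_cols)
            X_train_sc = X_train.copy()
            X_test_sc = X_test.copy()
            for col in scale_cols:
                mu, sd = scaler.means[col], scaler.sds[col]
                X_train_sc[col] = (X_train[col] - mu) / sd
                X_test_sc[col] = (X_test[col] - mu) / sd

            fold_selected = selected
            if config.gwo_scope == "per_fold":
                selection = gwo_select.run_gwo(
                    train_tab, config.gwo_params, config.fitness
                )
                fold_selected = selection.selected_features

            for model_id in config.models:
                scaled = model_id in classifiers.SCALE_SENSITIVE
                Xtr = X_train_sc if scaled else X_train
                Xte = X_test_sc if scaled else X_test
                for condition in CONDITIONS:
                    if condition == "after_gwo":
                        keep = [c for c in Xtr.columns if c in fold_selected]
                        if not keep:  # selection eliminated everything surviving
                            keep = list(Xtr.columns)
                        Xtr_c, Xte_c = Xtr[keep], Xte[keep]
                    else:
                        Xtr_c, Xte_c = Xtr, Xte

                    spec = classifiers.ModelSpec(
                        model_id,
                        hyperparams=config.model_params.get(model_id, {}),
                        seed=config.seed,
                    )
                    model = classifiers.train_model(spec, Xtr_c, y_train)
                    scores = classifiers.predict_scores(model, Xte_c)
                    preds = classifiers.predict_labels(model, Xte_c)

                    key = (model_id, condition)
                    per_fold_metrics[key].append(
                        compute_metrics(confusion_counts(y_test, preds))
                    )
                    if len(set(y_test)) == 2:
                        _, fold_auc = roc_auc(y_test, scores)
                        per_fold_aucs[key].append(fold_auc)
                    if repeat == plan.repeats - 1:
                        last_repeat_scores[key][test_idx] = scores

    metrics = {
        key: _mean_metrics(per_fold_metrics[key], per_fold_aucs[key])
        for key in per_fold_metrics
    }
    pooled_auc = {}
    roc_curves = {}
    for key, scores in last_repeat_scores.items():
        curve, auc = roc_auc(y_all, scores)
        pooled_auc[key] = auc
        roc_curves[key] = curve

    importances = _full_data_importances(cohort, config)

    return ComparativeReport(
        metrics=metrics,
        pooled_auc=pooled_auc,
        roc_curves=roc_curves,
        selected_features=selected,
        convergence_trace=trace,
        importances=importances,
        config=config,
    )


def _full_data_importances(
    cohort: pd.DataFrame, config: ExperimentConfig
) -> dict[str, dict[str, float]]:
    """Tree-ensemble importances fit on the fully preprocessed table."""
    table, _ = preprocess_full(cohort, config.elimination_threshold)
    X, y = design_matrix(table)
    out: dict[str, dict[str, float]] = {}
    for model_id in config.models:
        if model_id not in classifiers.IMPORTANCE_MODELS:
            continue
        spec = classifiers.ModelSpec(
            model_id,
            hyperparams=config.model_params.get(model_id, {}),
            seed=config.seed,
        )
        model = classifiers.train_model(spec, X, y)
        ranked = sorted(
            classifiers.feature_importances(model).items(), key=lambda kv: -kv[1]
        )
        out[model_id] = dict(ranked)
    return out
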