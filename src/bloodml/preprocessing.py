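"""Missingness-aware preprocessing: feature elimination, fold-safe
median/mode imputation, sex encoding and z-score standardization.

All fitting operations (:func:`fit_imputer`, :func:`fit_scaler`) learn their
statistics from a training table only, so they can be applied to held-out
folds without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import META_COLUMNS, feature_columns

__all__ = [
    "ImputerModel",
    "ScalerModel",
    "SEX_ENCODING",
    "eliminate_features",
    "fit_imputer",
    "apply_imputer",
    "encode_sex",
    "decode_sex",
    "fit_scaler",
    "apply_scaler",
    "design_matrix",
]

#: Fixed binary sex encoding used throughout the pipeline.
SEX_ENCODING = {"female": 0, "male": 1}
SEX_DECODING = {v: k for k, v in SEX_ENCODING.items()}

#: Default elimination threshold: drop features missing in more than half the rows.
DEFAULT_ELIMINATION_THRESHOLD = 0.50


@dataclass(frozen=True)
class ImputerModel:
    """Per-feature medians (numeric) and modes (categorical) fit on training data."""

    medians: dict[str, float]
    modes: dict[str, str] = field(default_factory=dict)
    fitted_on_n: int = 0


@dataclass(frozen=True)
class ScalerModel:
    """Per-feature train means/SDs for z-scoring; constant columns get SD 1."""

    means: dict[str, float]
    sds: dict[str, float]


def eliminate_features(
    table: pd.DataFrame, threshold: float = DEFAULT_ELIMINATION_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Drop analyte columns whose missing fraction strictly exceeds ``threshold``.

    Meta columns are never dropped.  Returns ``(reduced_table, dropped_names)``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    dropped = [
        name
        for name in feature_columns(table)
        if table[name].isna().mean() > threshold
    ]
    return table.drop(columns=dropped), dropped


def fit_imputer(train: pd.DataFrame) -> ImputerModel:
    """Learn per-feature medians (and the sex mode) from observed train values.

    A feature with no observed value in the train table is an error: callers
    must eliminate it first.  Mode ties break lexicographically.
    """
    medians: dict[str, float] = {}
    for name in feature_columns(train) + ["age"]:
        observed = train[name].dropna()
        if observed.empty:
            raise ValueError(
                f"feature {name!r} has no observed values in the training data; "
                "eliminate it before imputation"
            )
        medians[name] = float(observed.median())

    modes: dict[str, str] = {}
    if "sex" in train.columns:
        observed = train["sex"].dropna()
        if observed.empty:
            raise ValueError("sex has no observed values in the training data")
        counts = observed.value_counts()
        top = counts[counts == counts.max()]
        modes["sex"] = sorted(top.index)[0]

    return ImputerModel(medians=medians, modes=modes, fitted_on_n=len(train))


def apply_imputer(model: ImputerModel, table: pd.DataFrame) -> pd.DataFrame:
    """Fill every missing cell from the model; observed values are untouched."""
    out = table.copy()
    for name in feature_columns(table) + ["age"]:
        if name not in model.medians:
            raise ValueError(f"imputer was not fitted on feature {name!r}")
        out[name] = out[name].fillna(model.medians[name])
    if "sex" in out.columns and out["sex"].isna().any():
        if "sex" not in model.modes:
            raise ValueError("imputer has no mode for sex")
        out["sex"] = out["sex"].fillna(model.modes["sex"])
    return out


def encode_sex(table: pd.DataFrame) -> pd.DataFrame:
    """Map sex to binary: female -> 0, male -> 1 (fixed convention)."""
    out = table.copy()
    sex = out["sex"]
    if sex.dtype != object and set(np.unique(sex)) <= {0, 1}:
        return out  # already encoded
    unknown = set(sex.dropna().unique()) - set(SEX_ENCODING)
    if unknown:
        raise ValueError(f"unknown sex categories: {sorted(unknown)}")
    if sex.isna().any():
        raise ValueError("sex contains missing values; impute before encoding")
    out["sex"] = sex.map(SEX_ENCODING).astype(int)
    return out


def decode_sex(table: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`encode_sex`."""
    out = table.copy()
    out["sex"] = out["sex"].map(SEX_DECODING)
    return out


def fit_scaler(train: pd.DataFrame, columns: list[str] | None = None) -> ScalerModel:
    """Learn z-score parameters per numeric column from the training table.

    Constant columns get SD 1 so they map to zero instead of dividing by zero.
    """
    if columns is None:
        columns = feature_columns(train) + ["age"]
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in columns:
        values = train[name].astype(float)
        if values.isna().any():
            raise ValueError(f"column {name!r} has missing values; impute before scaling")
        means[name] = float(values.mean())
        sd = float(values.std(ddof=0))
        sds[name] = sd if sd > 0.0 else 1.0
    return ScalerModel(means=means, sds=sds)


def design_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a complete, sex-encoded cohort table into ``(X, y)``.

    ``X`` holds age, encoded sex and every analyte column (in table order);
    ``y`` is 1 for cases and 0 for controls (case is the positive class).
    """
    encoded = encode_sex(table)
    cols = ["age", "sex"] + feature_columns(encoded)
    X = encoded[cols].astype(float)
    if X.isna().any().any():
        raise ValueError("cohort has missing values; impute before modelling")
    y = (encoded["group"] == "case").to_numpy(dtype=int)
    return X, y


def apply_scaler(model: ScalerModel, table: pd.DataFrame) -> pd.DataFrame:
    """Z-score the model's columns of ``table`` using the train statistics."""
    out = table.copy()
    for name in model.means:
        if name not in out.columns:
            raise ValueError(f"scaler column {name!r} absent from table")
        out[name] = (out[name].astype(float) - model.means[name]) / model.sds[name]
    return out
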