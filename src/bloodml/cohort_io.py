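"""Cohort CSV reading/writing and run configuration.

Cohort files are UTF-8 comma-separated with a header row
(``subject_id,group,sex,age,<analyte...>``); missing cells are empty
strings.  The run configuration is a YAML/JSON mapping validated into a
:class:`RunConfig`; every stage's seed is derived deterministically from the
single global seed via a keyed hash, so one knob reproduces the whole run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classifiers, evaluation, gwo_select, preprocessing, synthetic_cohort
from .synthetic_cohort import META_COLUMNS

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "RunConfig",
    "load_run_config",
    "derive_seed",
    "config_hash",
]

VALID_GROUPS = {"case", "control"}
VALID_SEX = {"male", "female"}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2b of ``"<seed>:<stage>"`` mod 2^31."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become missing values (never zero)."""
    path = Path(path)
    table = pd.read_csv(path, dtype={"subject_id": str, "group": str, "sex": str})
    missing_meta = [c for c in META_COLUMNS if c not in table.columns]
    if missing_meta:
        raise ValueError(f"{path}: missing required columns {missing_meta}")

    for row_pos, value in enumerate(table["group"], start=2):
        if value not in VALID_GROUPS:
            raise ValueError(
                f"{path}: row {row_pos}: bad group token {value!r} "
                f"(expected one of {sorted(VALID_GROUPS)})"
            )
    for row_pos, value in enumerate(table["sex"], start=2):
        if not (pd.isna(value) or value in VALID_SEX):
            raise ValueError(
                f"{path}: row {row_pos}: bad sex token {value!r} "
                f"(expected one of {sorted(VALID_SEX)})"
            )
    for col in synthetic_cohort.feature_columns(table) + ["age"]:
        if table[col].dtype == object:
            try:
                table[col] = pd.to_numeric(table[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    return table


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV; missing values become empty cells.  Floats use
    Python's shortest round-trip repr, so write -> read is identity."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="")


@dataclass(frozen=True)
class RunConfig:
    """Validated end-to-end run configuration."""

    seed: int = 0
    cohort_path: str | None = None  # exclusive with simulate
    simulate: synthetic_cohort.CohortConfig | None = None
    feature_specs: str = "builtin"
    correlation: float = 0.0
    missing_rates: dict[str, float] = field(default_factory=dict)
    elimination_threshold: float = preprocessing.DEFAULT_ELIMINATION_THRESHOLD
    models: tuple[str, ...] = classifiers.MODEL_IDS
    model_params: dict = field(default_factory=dict)
    gwo: gwo_select.GWOParams = field(default_factory=gwo_select.GWOParams)
    fitness: gwo_select.FitnessSpec = field(default_factory=gwo_select.FitnessSpec)
    gwo_scope: str = "global"
    k: int = 10
    repeats: int = 5

    def experiment_config(self) -> evaluation.ExperimentConfig:
        return evaluation.ExperimentConfig(
            k=self.k,
            repeats=self.repeats,
            seed=derive_seed(self.seed, "evaluate"),
            elimination_threshold=self.elimination_threshold,
            models=tuple(self.models),
            model_params=self.model_params,
            gwo_params=self.gwo,
            fitness=self.fitness,
            gwo_scope=self.gwo_scope,
        )


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(f"config error: {message}")


def load_run_config(source: str | Path | dict, seed: int | None = None) -> RunConfig:
    """Parse and validate a YAML/JSON config file (or an already-parsed
    mapping).  ``seed`` overrides the config's global seed."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    else:
        raw = dict(source)
    _require(isinstance(raw, dict), "top level must be a mapping")

    known = {
        "seed",
        "cohort_path",
        "simulate",
        "elimination_threshold",
        "models",
        "model_params",
        "gwo",
        "evaluation",
    }
    unknown = set(raw) - known
    _require(not unknown, f"unknown keys {sorted(unknown)}")

    global_seed = int(seed if seed is not None else raw.get("seed", 0))

    sim_cfg = None
    feature_specs = "builtin"
    correlation = 0.0
    missing_rates: dict[str, float] = {}
    if "simulate" in raw:
        sim = dict(raw["simulate"] or {})
        sim_known = {
            "n_control",
            "n_case",
            "correlation",
            "feature_specs",
            "missing_rates",
            "male_fraction_control",
            "male_fraction_case",
        }
        _require(
            not set(sim) - sim_known,
            f"unknown simulate keys {sorted(set(sim) - sim_known)}",
        )
        n_control = int(sim.get("n_control", synthetic_cohort.DEMOGRAPHICS["n_control"]))
        n_case = int(sim.get("n_case", synthetic_cohort.DEMOGRAPHICS["n_case"]))
        _require(n_control > 0 and n_case > 0, "group sizes must be positive")
        correlation = float(sim.get("correlation", 0.0))
        feature_specs = str(sim.get("feature_specs", "builtin"))
        missing_rates = {
            str(k): float(v) for k, v in (sim.get("missing_rates") or {}).items()
        }
        kwargs = dict(
            n_control=n_control,
            n_case=n_case,
            seed=derive_seed(global_seed, "simulate"),
            correlation=correlation,
        )
        for key in ("male_fraction_control", "male_fraction_case"):
            if key in sim:
                kwargs[key] = float(sim[key])
        sim_cfg = synthetic_cohort.CohortConfig(**kwargs)
    else:
        _require("cohort_path" in raw, "either 'simulate' or 'cohort_path' is required")

    gwo_raw = dict(raw.get("gwo") or {})
    fitness_raw = dict(gwo_raw.pop("fitness", {}) or {})
    gwo_scope = str(gwo_raw.pop("scope", "global"))
    gwo_params = gwo_select.GWOParams(
        seed=derive_seed(global_seed, "gwo"),
        **{k: v for k, v in gwo_raw.items() if k != "seed"},
    )
    fitness = gwo_select.FitnessSpec(
        classifier_id=str(fitness_raw.get("classifier", "random_forest")),
        cv_folds=int(fitness_raw.get("cv_folds", 5)),
        seed=derive_seed(global_seed, "fitness"),
        classifier_params=dict(fitness_raw.get("classifier_params", {})),
    )

    eval_raw = dict(raw.get("evaluation") or {})
    models = tuple(raw.get("models", classifiers.MODEL_IDS))

    return RunConfig(
        seed=global_seed,
        cohort_path=raw.get("cohort_path"),
        simulate=sim_cfg,
        feature_specs=feature_specs,
        correlation=correlation,
        missing_rates=missing_rates,
        elimination_threshold=float(
            raw.get("elimination_threshold", preprocessing.DEFAULT_ELIMINATION_THRESHOLD)
        ),
        models=models,
        model_params=dict(raw.get("model_params", {})),
        gwo=gwo_params,
        fitness=fitness,
        gwo_scope=gwo_scope,
        k=int(eval_raw.get("k", 10)),
        repeats=int(eval_raw.get("repeats", 5)),
    )


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the full configuration, for manifests/logs."""
    blob = json.dumps(_to_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj
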