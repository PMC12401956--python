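"""Synthetic case-control cohort generation from per-group summary statistics.

Each laboratory analyte is described by a :class:`FeatureSpec` giving its
per-group Gaussian mean/SD, a physiological lower bound, and an optional
missingness rate.  :func:`generate_cohort` draws a cohort whose marginal
distributions match those parameters, with optional between-feature
correlation injected through a single shared latent factor, and
:func:`inject_missingness` blanks cells completely at random (MCAR).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._reference import ANALYTE_STATS, DEMOGRAPHICS

__all__ = [
    "FeatureSpec",
    "CohortConfig",
    "META_COLUMNS",
    "builtin_feature_specs",
    "load_feature_specs",
    "default_cohort_config",
    "generate_cohort",
    "inject_missingness",
    "feature_columns",
]

#: Non-analyte columns present in every cohort table; never blanked or dropped.
META_COLUMNS = ("subject_id", "group", "sex", "age")

SPEC_HEADER = [
    "name",
    "unit",
    "control_mean",
    "control_sd",
    "case_mean",
    "case_sd",
    "lower_bound",
    "missing_rate",
]

# Cap on truncation re-draw rounds before clamping at the bound.
_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class FeatureSpec:
    """Generative parameters for one laboratory analyte."""

    name: str
    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float
    unit: str = ""
    lower_bound: float | None = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.control_sd < 0 or self.case_sd < 0:
            raise ValueError(f"feature {self.name!r}: SDs must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"feature {self.name!r}: missing_rate must be in [0, 1]")
        if not self.name:
            raise ValueError("feature name must be non-empty")

    def group_params(self, group: str) -> tuple[float, float]:
        if group == "control":
            return self.control_mean, self.control_sd
        if group == "case":
            return self.case_mean, self.case_sd
        raise ValueError(f"unknown group {group!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative parameters (sizes, demographics, seed)."""

    n_control: int
    n_case: int
    seed: int = 0
    correlation: float = 0.0
    age_spec: FeatureSpec = field(
        default_factory=lambda: FeatureSpec(
            name="age",
            control_mean=DEMOGRAPHICS["age_control_mean"],
            control_sd=DEMOGRAPHICS["age_control_sd"],
            case_mean=DEMOGRAPHICS["age_case_mean"],
            case_sd=DEMOGRAPHICS["age_case_sd"],
        )
    )
    male_fraction_control: float = DEMOGRAPHICS["male_control"] / DEMOGRAPHICS["n_control"]
    male_fraction_case: float = DEMOGRAPHICS["male_case"] / DEMOGRAPHICS["n_case"]

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_case <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_control + self.n_case < 4:
            raise ValueError("total cohort size must be at least 4")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        for frac, label in (
            (self.male_fraction_control, "male_fraction_control"),
            (self.male_fraction_case, "male_fraction_case"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")


def builtin_feature_specs() -> list[FeatureSpec]:
    """The 45-analyte builtin spec set with the reference cohort's means/SDs."""
    return [
        FeatureSpec(name=name, control_mean=cm, control_sd=cs, case_mean=sm, case_sd=ss)
        for name, cm, cs, sm, ss in ANALYTE_STATS
    ]


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Config matching the reference cohort: 192 controls, 203 cases."""
    kwargs = dict(
        n_control=DEMOGRAPHICS["n_control"],
        n_case=DEMOGRAPHICS["n_case"],
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def load_feature_specs(source: str | Path) -> list[FeatureSpec]:
    """Load feature specs from a CSV file, or the builtin set if ``source == "builtin"``.

    The CSV header must be ``name,unit,control_mean,control_sd,case_mean,
    case_sd,lower_bound,missing_rate``; an empty ``lower_bound`` cell means 0.
    """
    if str(source) == "builtin":
        return builtin_feature_specs()

    path = Path(source)
    specs: list[FeatureSpec] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty spec file")
        if list(reader.fieldnames) != SPEC_HEADER:
            raise ValueError(
                f"{path}: bad header {reader.fieldnames}; expected {SPEC_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                lb_raw = (row["lower_bound"] or "").strip()
                mr_raw = (row["missing_rate"] or "").strip()
                spec = FeatureSpec(
                    name=row["name"].strip(),
                    unit=(row["unit"] or "").strip(),
                    control_mean=float(row["control_mean"]),
                    control_sd=float(row["control_sd"]),
                    case_mean=float(row["case_mean"]),
                    case_sd=float(row["case_sd"]),
                    lower_bound=float(lb_raw) if lb_raw else 0.0,
                    missing_rate=float(mr_raw) if mr_raw else 0.0,
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed spec row {lineno}: {exc}") from exc
            specs.append(spec)
    _check_unique_names(specs)
    if not specs:
        raise ValueError(f"{path}: spec file contains no feature rows")
    return specs


def save_feature_specs(specs: list[FeatureSpec], path: str | Path) -> None:
    """Write specs in the CSV format accepted by :func:`load_feature_specs`."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPEC_HEADER)
        for s in specs:
            writer.writerow(
                [
                    s.name,
                    s.unit,
                    repr(s.control_mean),
                    repr(s.control_sd),
                    repr(s.case_mean),
                    repr(s.case_sd),
                    "" if s.lower_bound is None else repr(s.lower_bound),
                    repr(s.missing_rate),
                ]
            )


def _check_unique_names(specs: list[FeatureSpec]) -> None:
    seen: set[str] = set()
    for s in specs:
        if s.name in seen:
            raise ValueError(f"duplicate feature name {s.name!r}")
        if s.name in META_COLUMNS:
            raise ValueError(f"feature name {s.name!r} collides with a reserved column")
        seen.add(s.name)


def _draw_truncated(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lower_bound: float | None,
    latent: np.ndarray | None,
    loading: float,
) -> np.ndarray:
    """Gaussian draws, truncated below at ``lower_bound`` by re-drawing the
    idiosyncratic part.  ``latent`` is the shared standard-normal factor."""
    if sd == 0.0:
        values = np.full(n, mean)
        if lower_bound is not None:
            values = np.maximum(values, lower_bound)
        return values

    resid = np.sqrt(1.0 - loading**2)
    common = loading * latent if latent is not None else 0.0

    eps = rng.standard_normal(n)
    values = mean + sd * (common + resid * eps)
    if lower_bound is not None:
        for _ in range(_MAX_REDRAWS):
            bad = values < lower_bound
            if not bad.any():
                break
            eps_new = rng.standard_normal(int(bad.sum()))
            values[bad] = mean + sd * (
                (common[bad] if latent is not None else 0.0) + resid * eps_new
            )
        else:
            np.maximum(values, lower_bound, out=values)
    return values


def generate_cohort(config: CohortConfig, specs: list[FeatureSpec]) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Rows are controls first then cases; lab values are truncated Gaussians
    per group; ``config.correlation`` > 0 mixes a per-subject shared latent
    factor into every standardized lab draw with loading
    ``sqrt(correlation)``.  Fully deterministic given ``config.seed``.
    Missingness is applied afterwards from each spec's ``missing_rate``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    _check_unique_names(specs)

    rng = np.random.default_rng(config.seed)
    loading = float(np.sqrt(config.correlation))

    frames = []
    for group, n, male_frac in (
        ("control", config.n_control, config.male_fraction_control),
        ("case", config.n_case, config.male_fraction_case),
    ):
        age_mean, age_sd = config.age_spec.group_params(group)
        latent = rng.standard_normal(n) if config.correlation > 0 else None
        cols: dict[str, np.ndarray | list] = {
            "group": [group] * n,
            "sex": np.where(rng.random(n) < male_frac, "male", "female"),
            "age": _draw_truncated(
                rng, n, age_mean, age_sd, config.age_spec.lower_bound, None, 0.0
            ),
        }
        for spec in specs:
            mean, sd = spec.group_params(group)
            cols[spec.name] = _draw_truncated(
                rng, n, mean, sd, spec.lower_bound, latent, loading
            )
        frames.append(pd.DataFrame(cols))

    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(table))])

    rates = {s.name: s.missing_rate for s in specs if s.missing_rate > 0}
    if rates:
        table = inject_missingness(table, rates, seed=int(rng.integers(2**31)))
    return table


def inject_missingness(
    table: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Blank each targeted cell independently with its feature's rate (MCAR).

    Meta columns (group/sex/age/subject_id) are never blanked.  Returns a new
    table; deterministic given ``seed``.
    """
    for name, rate in rates.items():
        if name in META_COLUMNS:
            raise ValueError(f"cannot inject missingness into reserved column {name!r}")
        if name not in table.columns:
            raise ValueError(f"unknown feature {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {name!r} must be in [0, 1]")

    out = table.copy()
    rng = np.random.default_rng(seed)
    for name in table.columns:
        rate = rates.get(name, 0.0)
        if rate <= 0.0:
            continue
        mask = rng.random(len(out)) < rate
        col = out[name].astype(float)
        col[mask] = np.nan
        out[name] = col
    return out


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Analyte column names of a cohort table (everything but the meta columns)."""
    return [c for c in table.columns if c not in META_COLUMNS]
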