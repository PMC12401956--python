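"""Per-feature group-comparison statistics for case-control cohort tables.

Two-sample Welch t-tests (unequal-variance, Satterthwaite df; pooled
Student variant available) on every numeric feature, a Pearson 2x2
chi-square for sex, and a p-sorted comparison table with a significance
flag at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_cohort import feature_columns

__all__ = [
    "GroupComparisonRow",
    "welch_t",
    "welch_t_from_stats",
    "chi_square_2x2",
    "sex_chi_square",
    "comparison_table",
    "comparison_frame",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupComparisonRow:
    feature: str
    mean_control: float
    sd_control: float
    mean_case: float
    sd_case: float
    statistic: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_LEVEL

    def display_p(self) -> str:
        """p to 4 decimals, floored at 0.0001 for display."""
        return f"{max(self.p, 0.0001):.4f}"


def welch_t_from_stats(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics (sample SDs, ddof=1).

    Default is Welch with Satterthwaite degrees of freedom; ``equal_var``
    switches to the pooled-variance Student test.  Returns ``(t, df, p)``
    with a two-sided p-value.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = sd_a**2, sd_b**2
    if equal_var:
        df = n_a + n_b - 2
        pooled = ((n_a - 1) * va + (n_b - 1) * vb) / df
        se2 = pooled * (1.0 / n_a + 1.0 / n_b)
    else:
        se2 = va / n_a + vb / n_b
        if se2 == 0.0:
            return 0.0, float(n_a + n_b - 2), 1.0
        df = se2**2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        )
    if se2 == 0.0:
        return 0.0, float(df), 1.0
    t = (mean_a - mean_b) / np.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def welch_t(values_a, values_b, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test on raw observations (see :func:`welch_t_from_stats`)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observed values")
    return welch_t_from_stats(
        float(a.mean()),
        float(a.std(ddof=1)),
        a.size,
        float(b.mean()),
        float(b.std(ddof=1)),
        b.size,
        equal_var=equal_var,
    )


def chi_square_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction by default; ``yates`` enables it.  Both row and
    column margins must be positive.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: a margin is zero")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    statistic = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(statistic, df=1))
    return float(statistic), p


def sex_chi_square(cohort: pd.DataFrame, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square of the sex x group 2x2 contingency table."""
    male_control = int(((cohort["group"] == "control") & (cohort["sex"] == "male")).sum())
    female_control = int(
        ((cohort["group"] == "control") & (cohort["sex"] == "female")).sum()
    )
    male_case = int(((cohort["group"] == "case") & (cohort["sex"] == "male")).sum())
    female_case = int(((cohort["group"] == "case") & (cohort["sex"] == "female")).sum())
    return chi_square_2x2(male_control, female_control, male_case, female_case, yates=yates)


def comparison_table(
    cohort: pd.DataFrame, equal_var: bool = False, include_age: bool = True
) -> list[GroupComparisonRow]:
    """Per-feature group comparison, sorted by ascending p (stable).

    Uses observed (non-missing) values only.  Requires both groups present.
    """
    groups = set(cohort["group"].unique())
    if groups != {"case", "control"}:
        raise ValueError(f"cohort must contain both groups, found {sorted(groups)}")

    control = cohort[cohort["group"] == "control"]
    case = cohort[cohort["group"] == "case"]

    names = feature_columns(cohort)
    if include_age:
        names = ["age"] + names

    rows: list[GroupComparisonRow] = []
    for name in names:
        a = control[name].dropna().to_numpy(dtype=float)
        b = case[name].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        t, df, p = welch_t(a, b, equal_var=equal_var)
        rows.append(
            GroupComparisonRow(
                feature=name,
                mean_control=float(a.mean()),
                sd_control=float(a.std(ddof=1)),
                mean_case=float(b.mean()),
                sd_case=float(b.std(ddof=1)),
                statistic=t,
                df=df,
                p=p,
            )
        )
    rows.sort(key=lambda r: r.p)  # list.sort is stable: equal p keeps input order
    return rows


def comparison_frame(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    """Tabular view of :func:`comparison_table` output."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "control_mean": r.mean_control,
                "control_sd": r.sd_control,
                "case_mean": r.mean_case,
                "case_sd": r.sd_case,
                "statistic": r.statistic,
                "df": r.df,
                "p": r.p,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
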