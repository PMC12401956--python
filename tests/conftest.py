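"""Shared fixtures: small synthetic cohorts built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from bloodml import synthetic_cohort as sc


def make_specs(
    n_features: int,
    shift: float = 0.0,
    n_informative: int | None = None,
    sd: float = 1.0,
    mean: float = 10.0,
) -> list[sc.FeatureSpec]:
    """Gaussian specs: the first ``n_informative`` features have their case
    mean shifted by ``shift``; the rest are identical across groups."""
    if n_informative is None:
        n_informative = n_features if shift else 0
    return [
        sc.FeatureSpec(
            name=f"f{i}",
            control_mean=mean,
            control_sd=sd,
            case_mean=mean + (shift if i < n_informative else 0.0),
            case_sd=sd,
            lower_bound=None,
        )
        for i in range(n_features)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def null_cohort():
    """60/60 cohort with zero group separation, 6 features."""
    cfg = sc.CohortConfig(n_control=60, n_case=60, seed=7)
    return sc.generate_cohort(cfg, make_specs(6))


@pytest.fixture
def separable_cohort():
    """50/50 cohort with a huge shift on every feature: trivially separable."""
    cfg = sc.CohortConfig(n_control=50, n_case=50, seed=11)
    return sc.generate_cohort(cfg, make_specs(4, shift=8.0))


@pytest.fixture
def planted_cohort():
    """40/40 cohort, 3 informative features (shift 1.5 SD) among 8."""
    cfg = sc.CohortConfig(n_control=40, n_case=40, seed=5)
    return sc.generate_cohort(cfg, make_specs(8, shift=1.5, n_informative=3))
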