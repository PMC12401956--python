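"""Binary Grey Wolf Optimization wrapper feature selection, from scratch.

Wolves are continuous positions in [0, 1]^d binarized into feature masks.
Fitness is the cross-validated accuracy of a wrapper classifier trained on
the masked columns, optionally penalized by the selected-feature fraction.
Positions move toward the alpha/beta/delta leaders under the canonical
update with a linearly decaying exploration coefficient::

    A = 2a*r1 - a,  C = 2*r2
    D_L = |C*X_L - X|,  X'_L = X_L - A*D_L,  L in {alpha, beta, delta}
    X_new = mean(X'_alpha, X'_beta, X'_delta), clamped to [0, 1]

Among equal-fitness masks, the one with fewer selected features is
preferred; at equal count the earlier-encountered mask is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classifiers
from .preprocessing import design_matrix

__all__ = [
    "GWOParams",
    "Wolf",
    "WolfPack",
    "FitnessSpec",
    "SelectionResult",
    "initialize_pack",
    "binarize",
    "evaluate_fitness",
    "update_positions",
    "run_gwo",
]

# Sigmoid steepness of the stochastic transfer function.
_SIGMOID_SLOPE = 10.0

TRANSFERS = ("sigmoid_stochastic", "threshold_half")


@dataclass(frozen=True)
class GWOParams:
    pop_size: int = 10
    n_iter: int = 20
    seed: int = 0
    a_start: float = 2.0
    a_end: float = 0.0
    transfer: str = "sigmoid_stochastic"
    min_features: int = 1
    penalty_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        if self.transfer not in TRANSFERS:
            raise ValueError(f"transfer must be one of {TRANSFERS}")
        if self.min_features < 1:
            raise ValueError("min_features must be >= 1")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be non-negative")


@dataclass
class Wolf:
    position: np.ndarray  # continuous, in [0, 1]^d
    mask: np.ndarray  # binary, length d
    fitness: float | None = None


@dataclass
class WolfPack:
    wolves: list[Wolf]
    alpha: int = 0
    beta: int = 0
    delta: int = 0
    iteration: int = 0


@dataclass(frozen=True)
class FitnessSpec:
    """How mask fitness is scored: wrapper classifier + stratified CV."""

    classifier_id: str = "random_forest"
    cv_folds: int = 5
    seed: int = 0
    classifier_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.classifier_id not in classifiers.MODEL_IDS:
            raise ValueError(f"unknown classifier_id {self.classifier_id!r}")


@dataclass
class SelectionResult:
    best_mask: np.ndarray
    best_fitness: float
    feature_names: list[str]
    trace: list[float]

    @property
    def n_selected(self) -> int:
        return int(self.best_mask.sum())

    @property
    def selected_features(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.best_mask) if m]


def binarize(
    position: np.ndarray, params: GWOParams, rng: np.random.Generator
) -> np.ndarray:
    """Map a continuous position to a feature mask via the transfer function.

    ``sigmoid_stochastic``: bit j is 1 iff sigmoid(10*(pos_j - 0.5)) > u_j,
    u_j uniform.  ``threshold_half``: bit j is 1 iff pos_j > 0.5.  If fewer
    than ``min_features`` bits survive, the largest-position components are
    forced on (ties broken by lowest index).
    """
    position = np.asarray(position, dtype=float)
    if params.transfer == "sigmoid_stochastic":
        prob = 1.0 / (1.0 + np.exp(-_SIGMOID_SLOPE * (position - 0.5)))
        mask = (prob > rng.random(position.shape)).astype(int)
    else:
        mask = (position > 0.5).astype(int)
    return _repair(mask, position, params.min_features)


def _repair(mask: np.ndarray, position: np.ndarray, min_features: int) -> np.ndarray:
    if mask.sum() >= min_features:
        return mask
    mask = mask.copy()
    # stable argsort descending: lowest index wins ties
    order = np.argsort(-position, kind="stable")
    mask[order[:min_features]] = 1
    return mask


def initialize_pack(
    d: int, params: GWOParams, rng: np.random.Generator
) -> WolfPack:
    """Uniformly random initial pack of ``pop_size`` wolves in [0, 1]^d."""
    if d < 1:
        raise ValueError("d must be at least 1")
    if d < params.min_features:
        raise ValueError(f"d={d} smaller than min_features={params.min_features}")
    wolves = []
    for _ in range(params.pop_size):
        position = rng.random(d)
        wolves.append(Wolf(position=position, mask=binarize(position, params, rng)))
    return WolfPack(wolves=wolves)


def evaluate_fitness(
    mask: np.ndarray,
    train: pd.DataFrame,
    spec: FitnessSpec,
    penalty_weight: float = 0.0,
) -> float:
    """Mean stratified CV accuracy of the wrapper classifier on the masked
    feature columns, minus ``penalty_weight * popcount(mask)/d``."""
    X, y = design_matrix(train)
    return _evaluate_fitness_xy(np.asarray(mask), X.to_numpy(), y, spec, penalty_weight)


def _evaluate_fitness_xy(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: FitnessSpec,
    penalty_weight: float,
) -> float:
    d = X.shape[1]
    if mask.shape != (d,):
        raise ValueError(f"mask length {mask.shape} does not match d={d}")
    if mask.sum() < 1:
        raise ValueError("all-zero mask; repair before evaluating fitness")

    Xm = X[:, mask.astype(bool)]
    splitter = StratifiedKFold(
        n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed
    )
    accs = []
    for train_idx, test_idx in splitter.split(Xm, y):
        model = classifiers.train_model(
            classifiers.ModelSpec(
                spec.classifier_id, hyperparams=spec.classifier_params, seed=spec.seed
            ),
            Xm[train_idx],
            y[train_idx],
        )
        pred = classifiers.predict_labels(model, Xm[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs)) - penalty_weight * (float(mask.sum()) / d)


def update_positions(pack: WolfPack, a: float, rng: np.random.Generator) -> WolfPack:
    """Move every wolf toward the three leaders (canonical position update).

    New positions are the mean of the three leader attraction points,
    clamped to [0, 1].  Leader indices are left as-is; masks and fitness
    must be refreshed by the caller.
    """
    leaders = [pack.wolves[i].position for i in (pack.alpha, pack.beta, pack.delta)]
    new_wolves = []
    for wolf in pack.wolves:
        X = wolf.position
        attraction = np.empty((3, X.size))
        for i, XL in enumerate(leaders):
            r1 = rng.random(X.size)
            r2 = rng.random(X.size)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            D = np.abs(C * XL - X)
            attraction[i] = XL - A * D
        new_position = np.clip(attraction.mean(axis=0), 0.0, 1.0)
        new_wolves.append(Wolf(position=new_position, mask=wolf.mask, fitness=None))
    return WolfPack(
        wolves=new_wolves,
        alpha=pack.alpha,
        beta=pack.beta,
        delta=pack.delta,
        iteration=pack.iteration + 1,
    )


def _better(
    fitness_a: float, count_a: int, fitness_b: float, count_b: int
) -> bool:
    """True if (a) strictly beats (b): higher fitness, then fewer features.
    Equal on both -> False, so the earlier-encountered incumbent is kept."""
    if fitness_a != fitness_b:
        return fitness_a > fitness_b
    return count_a < count_b


def _assign_leaders(pack: WolfPack) -> None:
    ranked = sorted(
        range(len(pack.wolves)),
        key=lambda i: (
            -pack.wolves[i].fitness,
            int(pack.wolves[i].mask.sum()),
            i,
        ),
    )
    pack.alpha, pack.beta, pack.delta = ranked[0], ranked[1], ranked[2 % len(ranked)]


def run_gwo(
    train: pd.DataFrame,
    params: GWOParams,
    spec: FitnessSpec,
) -> SelectionResult:
    """Run the full binary GWO search on a complete, preprocessed cohort.

    The exploration coefficient decays linearly from ``a_start`` to
    ``a_end`` over the iterations.  Returns the best-ever mask, its fitness
    and the best-so-far trace (length ``n_iter + 1``, including the initial
    evaluation); the trace is non-decreasing by construction.  Identical
    fitness evaluations are cached within the run.
    """
    X_df, y = design_matrix(train)
    X = X_df.to_numpy()
    feature_names = list(X_df.columns)
    d = X.shape[1]

    cache: dict[bytes, float] = {}

    def fitness_of(mask: np.ndarray) -> float:
        key = np.packbits(mask.astype(np.uint8)).tobytes()
        if key not in cache:
            cache[key] = _evaluate_fitness_xy(mask, X, y, spec, params.penalty_weight)
        return cache[key]

    rng = np.random.default_rng(params.seed)
    pack = initialize_pack(d, params, rng)
    for wolf in pack.wolves:
        wolf.fitness = fitness_of(wolf.mask)
    _assign_leaders(pack)

    best_wolf = pack.wolves[pack.alpha]
    best_mask = best_wolf.mask.copy()
    best_fitness = best_wolf.fitness
    trace = [best_fitness]

    for t in range(params.n_iter):
        a = params.a_start - (params.a_start - params.a_end) * (t / params.n_iter)
        pack = update_positions(pack, a, rng)
        for wolf in pack.wolves:
            wolf.mask = binarize(wolf.position, params, rng)
            wolf.fitness = fitness_of(wolf.mask)
        _assign_leaders(pack)
        alpha_wolf = pack.wolves[pack.alpha]
        if _better(
            alpha_wolf.fitness,
            int(alpha_wolf.mask.sum()),
            best_fitness,
            int(best_mask.sum()),
        ):
            best_fitness = alpha_wolf.fitness
            best_mask = alpha_wolf.mask.copy()
        trace.append(best_fitness)

    return SelectionResult(
        best_mask=best_mask,
        best_fitness=best_fitness,
        feature_names=feature_names,
        trace=trace,
    )
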