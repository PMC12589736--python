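"""Ant-colony-optimization feature subset selection.

Each iteration, every ant builds a candidate subset of a fixed target size
by drawing features sequentially without replacement with probability
proportional to ``tau_j**alpha * eta_j**gamma``, where tau is the learned
pheromone intensity and eta a fixed class-separability heuristic (one-way
ANOVA F statistic of the feature against the class label). Subsets are
scored by a cross-validated shallow decision tree; pheromone evaporates by
a factor ``(1 - rho)`` and the iteration-best subset deposits ``Q * score``
on its features. The search stops at ``max_iters`` or when the best
subset's error rate ``1 - score`` falls below ``error_threshold``.

The target subset sizes used for the fused feature matrices default to the
published per-combination counts (625 / 690 / 720 / 810); see
``DEFAULT_SUBSET_SIZES``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.feature_selection import f_classif
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "ACOConfig",
    "PheromoneState",
    "SelectionResult",
    "StratificationError",
    "DEFAULT_SUBSET_SIZES",
    "default_subset_size",
    "heuristic_importance",
    "init_pheromone",
    "construct_subset",
    "evaluate_subset",
    "update_pheromone",
    "run_aco",
]

logger = logging.getLogger(__name__)

_TAU_FLOOR = 1e-12

#: Published retained-feature counts per fusion combination (extractor names
#: sorted is NOT assumed; keys follow the fusion order used in the pipeline).
DEFAULT_SUBSET_SIZES = {
    ("resnet50", "densenet169"): 625,
    ("densenet169", "mobilenet"): 690,
    ("resnet50", "mobilenet"): 720,
    ("resnet50", "densenet169", "mobilenet"): 810,
}


def default_subset_size(extractor_names: Sequence[str]) -> Optional[int]:
    """Look up the published subset size for a fusion combination, else None."""
    return DEFAULT_SUBSET_SIZES.get(tuple(extractor_names))


class StratificationError(RuntimeError):
    """A cross-validation fold cannot be stratified (class too small)."""


@dataclass
class ACOConfig:
    subset_size: int = 0                # 0 means "all features"
    n_ants: int = 20
    evaporation_rate: float = 0.1       # rho
    initial_pheromone: float = 0.1      # tau0
    pheromone_exponent: float = 1.0     # alpha
    importance_exponent: float = 1.0    # gamma
    deposit_scale: float = 1.0          # Q
    heuristic_baseline: float = 0.1     # exploration floor added to eta
    max_iters: int = 100
    error_threshold: float = 0.01
    greedy: bool = False                # argmax construction instead of sampling
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.evaporation_rate < 1):
            raise ValueError("evaporation_rate must be in [0, 1)")
        if self.initial_pheromone <= 0:
            raise ValueError("initial_pheromone must be > 0")
        if self.pheromone_exponent < 0 or self.importance_exponent < 0:
            raise ValueError("exponents must be >= 0")
        if self.deposit_scale <= 0:
            raise ValueError("deposit_scale must be > 0")
        if self.n_ants < 1 or self.max_iters < 1:
            raise ValueError("n_ants and max_iters must be >= 1")


@dataclass
class PheromoneState:
    tau: np.ndarray
    eta: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.tau.shape != self.eta.shape:
            raise ValueError("tau and eta must have equal length")
        if np.any(self.tau <= 0):
            raise ValueError("pheromone intensities must stay positive")
        if np.any(self.eta < 0):
            raise ValueError("heuristic importances must be nonnegative")


@dataclass
class SelectionResult:
    best_subset: list
    best_score: float
    score_trace: list
    config: ACOConfig

    def __post_init__(self) -> None:
        if len(set(self.best_subset)) != len(self.best_subset):
            raise ValueError("selected indices must be unique")
        trace = np.asarray(self.score_trace)
        if np.any(np.diff(trace) < -1e-12):
            raise ValueError("score trace must be non-decreasing (global best)")


def _as_xy(X, y=None):
    if isinstance(X, FeatureMatrix):
        return X.values, np.asarray(X.labels if y is None else y)
    return np.asarray(X, dtype=float), np.asarray(y)


def heuristic_importance(X, y=None) -> np.ndarray:
    """Per-feature one-way ANOVA F statistic against the class label, floored at 0.

    Zero-variance features get importance 0 rather than an error.
    """
    values, labels = _as_xy(X, y)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stats, _ = f_classif(values, labels)
    f_stats = np.nan_to_num(f_stats, nan=0.0, posinf=0.0, neginf=0.0)
    return np.maximum(f_stats, 0.0)


def init_pheromone(X, y=None, config: Optional[ACOConfig] = None) -> PheromoneState:
    """Uniform low pheromone tau0 plus the fixed ANOVA heuristic."""
    if config is None:
        config = ACOConfig()
    values, labels = _as_xy(X, y)
    n = values.shape[1]
    tau = np.full(n, config.initial_pheromone)
    eta = heuristic_importance(values, labels)
    return PheromoneState(tau=tau, eta=eta)


def construct_subset(state: PheromoneState, config: ACOConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw ``subset_size`` distinct features, p ∝ tau^alpha · eta^gamma.

    Sequential proportional sampling without replacement is realised with
    the Gumbel-top-k equivalence (exponential-race sampling). All-zero
    weights fall back to uniform sampling. ``greedy`` takes the top-k
    weights deterministically (the "always pick the strongest trail" mode).
    """
    n = len(state.tau)
    k = config.subset_size if config.subset_size > 0 else n
    if k > n:
        raise ValueError(f"subset_size {k} exceeds feature count {n}")
    if k == n:
        return np.arange(n)
    # exploration floor: a zero-ANOVA feature would otherwise have zero
    # selection probability forever, making parts of the subset space
    # unreachable (a feature useless marginally can matter jointly)
    eta = state.eta
    if config.heuristic_baseline > 0:
        scale = float(eta.mean()) if eta.max() > 0 else 1.0
        eta = eta + config.heuristic_baseline * scale
    with np.errstate(divide="ignore"):
        w = (state.tau ** config.pheromone_exponent) * (eta ** config.importance_exponent)
    w = np.nan_to_num(w, nan=0.0, posinf=0.0)
    if not np.any(w > 0):
        logger.warning("all construction weights are zero; falling back to uniform")
        w = np.ones(n)
    elif np.count_nonzero(w > 0) < k:
        # not enough positively-weighted features to fill the subset; give the
        # rest a vanishing but nonzero chance so the draw stays well defined
        w = w + w[w > 0].min() * 1e-9
    if config.greedy:
        order = np.argsort(-w, kind="stable")
        return np.sort(order[:k])
    logw = np.where(w > 0, np.log(w), -np.inf)
    gumbel = rng.gumbel(size=n)
    keys = logw + gumbel
    chosen = np.argpartition(-keys, k - 1)[:k]
    return np.sort(chosen)


def _default_objective(seed: int) -> Callable:
    def objective(X: np.ndarray, y: np.ndarray) -> float:
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < 3:
            raise StratificationError(
                "a class has fewer samples than the 3 stratified folds")
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        clf = DecisionTreeClassifier(max_depth=8, random_state=seed)
        return float(cross_val_score(clf, X, y, cv=cv).mean())
    return objective


def evaluate_subset(X, y, subset: Sequence[int],
                    objective: Optional[Callable] = None, seed: int = 0) -> float:
    """Score a feature subset; default objective is mean stratified 3-fold
    accuracy of a depth-8 decision tree on the subset's columns."""
    values, labels = _as_xy(X, y)
    subset = np.asarray(list(subset), dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    if objective is None:
        objective = _default_objective(seed)
    return float(objective(values[:, subset], labels))


def update_pheromone(state: PheromoneState, evaluated: Sequence[tuple],
                     config: ACOConfig) -> PheromoneState:
    """Evaporate all trails, then deposit on the iteration-best subset.

    ``evaluated`` is a sequence of (subset, score) pairs from one iteration;
    tau is floored at 1e-12 so no feature's trail ever vanishes entirely.
    """
    tau = state.tau * (1.0 - config.evaporation_rate)
    if evaluated:
        best_subset, best_score = max(evaluated, key=lambda t: t[1])
        deposit = config.deposit_scale * best_score
        tau = tau.copy()
        tau[np.asarray(list(best_subset), dtype=int)] += deposit
    tau = np.maximum(tau, _TAU_FLOOR)
    return PheromoneState(tau=tau, eta=state.eta, iteration=state.iteration + 1)


def run_aco(X, y=None, config: Optional[ACOConfig] = None,
            objective: Optional[Callable] = None) -> SelectionResult:
    """Full construct → evaluate → update loop with global-best tracking."""
    if config is None:
        config = ACOConfig()
    values, labels = _as_xy(X, y)
    n = values.shape[1]
    k = config.subset_size if config.subset_size > 0 else n
    if k > n:
        raise ValueError(f"subset_size {k} exceeds feature count {n}")
    rng = np.random.default_rng(config.seed)
    state = init_pheromone(values, labels, config)

    best_subset: Optional[np.ndarray] = None
    best_score = -np.inf
    trace = []
    for _ in range(config.max_iters):
        evaluated = []
        for _ant in range(config.n_ants):
            subset = construct_subset(state, config, rng)
            score = evaluate_subset(values, labels, subset,
                                    objective=objective, seed=config.seed)
            evaluated.append((subset, score))
            if score > best_score:
                best_score, best_subset = score, subset
        state = update_pheromone(state, evaluated, config)
        trace.append(best_score)
        if k == n or (1.0 - best_score) <= config.error_threshold:
            break
    assert best_subset is not None
    return SelectionResult(best_subset=[int(j) for j in best_subset],
                           best_score=float(best_score),
                           score_trace=[float(s) for s in trace],
                           config=config)
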