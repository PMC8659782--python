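"""Metaheuristic tuning of the SVM hyperparameters (c, g).

Three population metaheuristics — grey wolf optimizer, real-coded genetic
algorithm, and particle swarm optimization — maximize a fitness function over
a 2-D box. For SVM tuning the fitness is the 5-fold cross-validated accuracy
(%) of the RBF-SVM at (c, g). Defaults: 100 iterations,
population 20, and per-algorithm search ranges (GWO: both in [0.01, 100];
GA: c up to 100, g up to 1000; PSO: c in [0.1, 100], g in [0.01, 1000]).

All candidates are clipped to the declared bounds, non-finite fitness values
discard the candidate with a warning, and the recorded best-so-far trace is
monotone non-decreasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .classifiers import cv_accuracy, split_features
from .exceptions import InputError

__all__ = [
    "SearchSpace",
    "OptResult",
    "TuneConfig",
    "gwo",
    "ga",
    "pso",
    "tune_svm",
    "DEFAULT_SPACES",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds for (c, g)."""

    lower: tuple[float, float]
    upper: tuple[float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, float)
        hi = np.asarray(self.upper, float)
        if not np.all(lo < hi):
            raise InputError("lower bounds must be strictly below upper bounds")
        if not np.all(lo > 0):
            raise InputError("bounds must be positive")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.lower, float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.upper, float)

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lo, self.hi)


#: per-algorithm default (c, g) ranges
#: (GA lower bounds clamped to 0.01: the SVM needs strictly positive c, g)
DEFAULT_SPACES = {
    "gwo": SearchSpace((0.01, 0.01), (100.0, 100.0)),
    "ga": SearchSpace((0.01, 0.01), (100.0, 1000.0)),
    "pso": SearchSpace((0.1, 0.01), (100.0, 1000.0)),
}


@dataclass(frozen=True)
class OptResult:
    """Best point, fitness, and convergence trace of one metaheuristic run."""

    algorithm: str
    best_x: tuple[float, ...]
    best_fitness: float
    trace: list[float]  # best-so-far fitness per iteration
    best_iteration: int  # iteration at which the best was first reached
    seed: int

    @property
    def best_c(self) -> float:
        return self.best_x[0]

    @property
    def best_g(self) -> float:
        return self.best_x[1]

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_c": self.best_c,
            "best_g": self.best_g,
            "best_fitness": self.best_fitness,
            "trace": list(map(float, self.trace)),
            "best_iteration": self.best_iteration,
            "seed": self.seed,
        }


def _safe_eval(fitness: Callable, x: np.ndarray) -> float:
    val = float(fitness(*x))
    if not np.isfinite(val):
        warnings.warn(f"non-finite fitness at {x}; candidate discarded")
        return -np.inf
    return val


class _Tracker:
    """Best-so-far bookkeeping shared by the three algorithms."""

    def __init__(self) -> None:
        self.best_x: np.ndarray | None = None
        self.best_f = -np.inf
        self.trace: list[float] = []
        self.best_iter = 0

    def offer(self, x: np.ndarray, f: float) -> None:
        if f > self.best_f:
            self.best_f = f
            self.best_x = x.copy()
            self.best_iter = len(self.trace)

    def close_iteration(self) -> None:
        self.trace.append(self.best_f)

    def result(self, algorithm: str, seed: int) -> OptResult:
        return OptResult(
            algorithm=algorithm,
            best_x=tuple(map(float, self.best_x)),
            best_fitness=float(self.best_f),
            trace=self.trace,
            best_iteration=self.best_iter,
            seed=seed,
        )


def gwo(
    fitness: Callable[[float, float], float],
    space: SearchSpace,
    pop: int = 20,
    iters: int = 100,
    seed: int = 0,
) -> OptResult:
    """Grey wolf optimizer (maximization).

    The three best wolves (alpha, beta, delta) lead; every wolf moves to the
    mean of three leader-relative pulls whose exploration coefficient `a`
    decays linearly from 2 to 0 over the iterations.
    """
    if pop < 3:
        raise InputError("GWO needs a population of at least 3")
    if iters < 1:
        raise InputError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    dim = 2
    X = rng.uniform(space.lo, space.hi, size=(pop, dim))
    F = np.array([_safe_eval(fitness, x) for x in X])
    tracker = _Tracker()
    for x, f in zip(X, F):
        tracker.offer(x, f)
    for t in range(iters):
        order = np.argsort(F)[::-1]
        leaders = X[order[:3]]
        a = 2.0 * (1.0 - t / max(iters - 1, 1))
        for m in range(pop):
            pulls = np.empty((3, dim))
            for ldr in range(3):
                r1 = rng.random(dim)
                r2 = rng.random(dim)
                A = 2.0 * a * r1 - a
                C = 2.0 * r2
                D = np.abs(C * leaders[ldr] - X[m])
                pulls[ldr] = leaders[ldr] - A * D
            X[m] = space.clip(pulls.mean(axis=0))
            F[m] = _safe_eval(fitness, X[m])
            tracker.offer(X[m], F[m])
        tracker.close_iteration()
    return tracker.result("gwo", seed)


def ga(
    fitness: Callable[[float, float], float],
    space: SearchSpace,
    pop: int = 20,
    iters: int = 100,
    p_cross: float = 0.6,
    p_mut: float = 0.03,
    seed: int = 0,
) -> OptResult:
    """Real-coded genetic algorithm (maximization).

    Tournament selection (size 2), arithmetic crossover at ``p_cross``,
    Gaussian mutation at ``p_mut`` (sd = 10% of each bound range), and
    elitism of one.
    """
    if pop < 4 or pop % 2:
        raise InputError("GA needs an even population of at least 4")
    if not (0 <= p_cross <= 1 and 0 <= p_mut <= 1):
        raise InputError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dim = 2
    span = space.hi - space.lo
    X = rng.uniform(space.lo, space.hi, size=(pop, dim))
    F = np.array([_safe_eval(fitness, x) for x in X])
    tracker = _Tracker()
    for x, f in zip(X, F):
        tracker.offer(x, f)
    for _ in range(iters):
        elite = X[int(np.argmax(F))].copy()
        children = []
        while len(children) < pop - 1:
            # tournament selection of two parents
            pa = max(rng.integers(0, pop, 2), key=lambda i: F[i])
            pb = max(rng.integers(0, pop, 2), key=lambda i: F[i])
            c1, c2 = X[pa].copy(), X[pb].copy()
            if rng.random() < p_cross:
                alpha = rng.random(dim)
                c1, c2 = alpha * c1 + (1 - alpha) * c2, alpha * c2 + (1 - alpha) * c1
            for child in (c1, c2):
                mut = rng.random(dim) < p_mut
                child[mut] += rng.normal(0.0, 0.1 * span[mut])
                children.append(space.clip(child))
        X = np.vstack([elite] + children[: pop - 1])
        F = np.array([_safe_eval(fitness, x) for x in X])
        for x, f in zip(X, F):
            tracker.offer(x, f)
        tracker.close_iteration()
    return tracker.result("ga", seed)


def pso(
    fitness: Callable[[float, float], float],
    space: SearchSpace,
    pop: int = 20,
    iters: int = 100,
    inertia: float = 0.729,
    c1: float = 1.494,
    c2: float = 1.494,
    seed: int = 0,
) -> OptResult:
    """Particle swarm optimization with constriction-style coefficients."""
    if pop < 2:
        raise InputError("PSO needs a population of at least 2")
    rng = np.random.default_rng(seed)
    dim = 2
    span = space.hi - space.lo
    vmax = 0.2 * span
    X = rng.uniform(space.lo, space.hi, size=(pop, dim))
    V = rng.uniform(-vmax, vmax, size=(pop, dim))
    F = np.array([_safe_eval(fitness, x) for x in X])
    P = X.copy()  # personal bests
    Pf = F.copy()
    tracker = _Tracker()
    for x, f in zip(X, F):
        tracker.offer(x, f)
    for _ in range(iters):
        gbest = P[int(np.argmax(Pf))]
        r1 = rng.random((pop, dim))
        r2 = rng.random((pop, dim))
        V = inertia * V + c1 * r1 * (P - X) + c2 * r2 * (gbest - X)
        V = np.clip(V, -vmax, vmax)
        X = space.clip(X + V)
        F = np.array([_safe_eval(fitness, x) for x in X])
        better = F > Pf
        P[better] = X[better]
        Pf[better] = F[better]
        for x, f in zip(X, F):
            tracker.offer(x, f)
        tracker.close_iteration()
    return tracker.result("pso", seed)


@dataclass(frozen=True)
class TuneConfig:
    pop: int = 20
    iters: int = 100
    k_folds: int = 5
    space: SearchSpace | None = None  # None: the algorithm's printed default
    p_cross: float = 0.6
    p_mut: float = 0.03
    cache_digits: int = 6


def tune_svm(
    table: pd.DataFrame, algorithm: str, cfg: TuneConfig | None = None, seed: int = 0
) -> OptResult:
    """Tune (c, g) of the RBF-SVM by one of the three metaheuristics.

    Fitness is the stratified 5-fold CV accuracy on the given table. Repeated
    (c, g) evaluations (rounded to 6 significant digits) are cached.
    """
    cfg = cfg or TuneConfig()
    if algorithm not in ("gwo", "ga", "pso"):
        raise InputError(f"unknown algorithm {algorithm!r}")
    X, y = split_features(table)
    space = cfg.space or DEFAULT_SPACES[algorithm]
    cache: dict[tuple[float, float], float] = {}

    def fitness(c: float, g: float) -> float:
        key = (
            float(np.format_float_positional(c, precision=cfg.cache_digits,
                                             unique=False, fractional=False)),
            float(np.format_float_positional(g, precision=cfg.cache_digits,
                                             unique=False, fractional=False)),
        )
        if key not in cache:
            cache[key] = cv_accuracy(X, y, key[0], key[1], k=cfg.k_folds, seed=seed)
        return cache[key]

    if algorithm == "gwo":
        return gwo(fitness, space, cfg.pop, cfg.iters, seed)
    if algorithm == "ga":
        return ga(fitness, space, cfg.pop, cfg.iters, cfg.p_cross, cfg.p_mut, seed)
    return pso(fitness, space, pop=cfg.pop, iters=cfg.iters, seed=seed)
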