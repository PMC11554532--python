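"""Generalized Normal Distribution Optimization (GNDO).

A population metaheuristic whose update rules mimic sampling from
generalized normal distributions.  Each iteration, every individual
independently takes one of two moves:

* **local exploitation** — a trial drawn around the generalized mean
  position ``mu_i = (y_i + y_best + M) / 3`` with componentwise scale
  ``delta_i = sqrt(((y_i - mu_i)^2 + (y_best - mu_i)^2 + (M - mu_i)^2) / 3)``
  and a heavy-tailed, zero-mean penalty factor
  ``eta = sqrt(-log l1) * cos(2 pi l2 [+ pi])`` (branch chosen by
  comparing two fresh uniforms ``a <= b``);
* **global exploration** — a move built from three distinct randomly
  chosen peers, ``v = y_i + beta*|g3|*v1 + (1 - beta)*|g4|*v2``, where
  ``v1``/``v2`` are signed differences pointing toward the fitter
  member of each pair and ``g3``, ``g4`` are standard normal draws.

Greedy screening then keeps each trial only if it strictly improves the
individual's fitness, which makes the best-so-far trace monotone
non-increasing.  Trials are clamped componentwise to the box bounds
before evaluation.  A single ``numpy`` Generator drives all draws, so a
fixed seed reproduces the trace bitwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Bounds",
    "Individual",
    "Population",
    "GNDOConfig",
    "initialize_population",
    "local_exploitation",
    "global_exploration",
    "screen",
    "gndo_minimize",
]


@dataclass
class Bounds:
    """Componentwise box bounds (lower strictly below upper)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper bounds must have equal shapes")
        if not np.all(self.lower < self.upper):
            bad = np.flatnonzero(~(self.lower < self.upper))
            raise ValueError(f"lower >= upper at dimensions {bad.tolist()}")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class Individual:
    position: np.ndarray
    fitness: float


@dataclass
class GNDOConfig:
    """Population size (default 20), iteration budget (default 200), seed."""

    population_size: int = 20
    max_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError(
                "population_size must be >= 4 (global exploration draws 3 distinct peers)"
            )
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")


class Population:
    """GNDO search state: individuals, incumbent best, mean position."""

    def __init__(self, individuals: list[Individual], bounds: Bounds, rng: np.random.Generator):
        self.individuals = individuals
        self.bounds = bounds
        self.rng = rng
        self.iteration = 0
        best = min(individuals, key=lambda ind: ind.fitness)
        self.best = Individual(best.position.copy(), best.fitness)

    @property
    def size(self) -> int:
        return len(self.individuals)

    @property
    def positions(self) -> np.ndarray:
        return np.stack([ind.position for ind in self.individuals])

    @property
    def mean_position(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def refresh_best(self) -> None:
        cand = min(self.individuals, key=lambda ind: ind.fitness)
        if cand.fitness < self.best.fitness:
            self.best = Individual(cand.position.copy(), cand.fitness)


def initialize_population(
    bounds: Bounds, config: GNDOConfig, objective=None
) -> Population:
    """Uniform initialization ``y_ij = p_j + (r_j - p_j) * U(0,1)``."""
    rng = np.random.default_rng(config.seed)
    span = bounds.upper - bounds.lower
    individuals = []
    for _ in range(config.population_size):
        pos = bounds.lower + span * rng.uniform(0.0, 1.0, size=bounds.dim)
        fit = float(objective(pos)) if objective is not None else np.inf
        individuals.append(Individual(pos, fit))
    return Population(individuals, bounds, rng)


def local_exploitation(pop: Population, i: int, rng: np.random.Generator) -> np.ndarray:
    """Trial vector from the generalized-normal local move.

    Draw order (fixed for reproducibility): ``a``, ``b``, then
    componentwise ``l1``, ``l2``.
    """

    y = pop.individuals[i].position
    mu = (y + pop.best.position + pop.mean_position) / 3.0
    delta = np.sqrt(
        (
            (y - mu) ** 2
            + (pop.best.position - mu) ** 2
            + (pop.mean_position - mu) ** 2
        )
        / 3.0
    )
    a = rng.uniform()
    b = rng.uniform()
    l1 = rng.uniform(size=y.shape)
    l2 = rng.uniform(size=y.shape)
    phase = 0.0 if a <= b else np.pi
    eta = np.sqrt(-np.log(np.maximum(l1, 1e-300))) * np.cos(2.0 * np.pi * l2 + phase)
    return mu + delta * eta


def _three_distinct(rng: np.random.Generator, n: int, i: int) -> tuple[int, int, int]:
    pool = np.delete(np.arange(n), i)
    p1, p2, p3 = rng.choice(pool, size=3, replace=False)
    return int(p1), int(p2), int(p3)


def global_exploration(pop: Population, i: int, rng: np.random.Generator) -> np.ndarray:
    """Trial vector from the three-peer global move.

    Draw order: peer indices ``p1, p2, p3`` (distinct, != i), then
    ``beta ~ U(0,1)``, then ``g3, g4 ~ N(0,1)``.
    """

    if pop.size < 4:
        raise ValueError("global exploration needs a population of at least 4")
    inds = pop.individuals
    p1, p2, p3 = _three_distinct(rng, pop.size, i)
    y = inds[i].position
    if inds[i].fitness < inds[p1].fitness:
        v1 = y - inds[p1].position
    else:
        v1 = inds[p1].position - y
    if inds[p2].fitness < inds[p3].fitness:
        v2 = inds[p2].position - inds[p3].position
    else:
        v2 = inds[p3].position - inds[p2].position
    beta = rng.uniform()
    g3 = rng.standard_normal()
    g4 = rng.standard_normal()
    return y + beta * abs(g3) * v1 + (1.0 - beta) * abs(g4) * v2


def screen(pop: Population, trials: np.ndarray, objective) -> Population:
    """Greedy replacement: adopt a trial iff its fitness strictly improves.

    Trials are clamped to bounds before evaluation; non-finite trial
    fitness rejects the trial (logged).  Updates the incumbent best.
    """

    if len(trials) != pop.size:
        raise ValueError(f"{len(trials)} trials for population of {pop.size}")
    for i, trial in enumerate(trials):
        cand = pop.bounds.clip(np.asarray(trial, dtype=float))
        fit = float(objective(cand))
        if not np.isfinite(fit):
            logger.warning("non-finite fitness for trial %d rejected", i)
            continue
        if fit < pop.individuals[i].fitness:
            pop.individuals[i] = Individual(cand, fit)
    pop.refresh_best()
    return pop


def gndo_minimize(
    objective, bounds: Bounds, config: GNDOConfig
) -> tuple[Individual, pd.DataFrame]:
    """Minimize ``objective`` over box bounds with GNDO.

    Per iteration each individual draws a fresh ``alpha ~ U(0,1)`` and
    takes the local-exploitation move when ``alpha > 0.5``, else the
    global-exploration move; screening follows.  Returns the best
    individual found and a trace ``(iteration, best_fitness,
    mean_fitness)`` of length ``max_iterations``.
    """

    pop = initialize_population(bounds, config, objective)
    rng = pop.rng
    rows = []
    for t in range(1, config.max_iterations + 1):
        trials = []
        for i in range(pop.size):
            alpha = rng.uniform()
            if alpha > 0.5:
                trials.append(local_exploitation(pop, i, rng))
            else:
                trials.append(global_exploration(pop, i, rng))
        screen(pop, np.stack(trials), objective)
        pop.iteration = t
        rows.append(
            {
                "iteration": t,
                "best_fitness": pop.best.fitness,
                "mean_fitness": float(np.mean([ind.fitness for ind in pop.individuals])),
            }
        )
    trace = pd.DataFrame(rows, columns=["iteration", "best_fitness", "mean_fitness"])
    return Individual(pop.best.position.copy(), pop.best.fitness), trace
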