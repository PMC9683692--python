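"""In-house real-coded genetic algorithm for box-bounded calibration.

Minimizes an arbitrary scalar objective over a box.  Candidates on which
the forward solver fails receive infinite cost, so they can never win a
tournament or survive elitism — the rejection semantics shared with the
MCMC stage.  Tournament selection, blend (BLX-alpha) crossover,
per-gene Gaussian mutation scaled to the box width, elitism, and a
stall-based early stop.  Fully deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["GAConfig", "FitResult", "ga_optimize", "evaluate_population"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    generations: int = 300
    tournament_size: int = 3
    crossover_rate: float = 0.9
    crossover_alpha: float = 0.5
    mutation_rate: float = 0.2
    mutation_scale: float = 0.05  # std of Gaussian mutation, fraction of box width
    elitism: int = 2
    stall_generations: int = 50
    seed: int = 0
    init_retries: int = 5
    parallel: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than the population")


@dataclass
class FitResult:
    theta_star: np.ndarray
    best_cost: float
    cost_history: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    n_rejected: int = 0


def evaluate_population(candidates: np.ndarray,
                        objective: Callable[[np.ndarray], float],
                        parallel: bool = False) -> np.ndarray:
    """Objective values aligned with the candidate rows.

    The objective must be a pure function of its argument, so evaluation
    order (or concurrency) cannot change the result; non-finite values
    map to +inf.
    """
    if parallel:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor() as ex:
            costs = list(ex.map(objective, candidates))
    else:
        costs = [objective(c) for c in candidates]
    costs = np.asarray(costs, dtype=float)
    return np.where(np.isfinite(costs), costs, math.inf)


def ga_optimize(objective: Callable[[np.ndarray], float],
                bounds: np.ndarray,
                cfg: GAConfig | None = None) -> FitResult:
    """Minimize ``objective`` over the box ``bounds`` ((n, 2) lo/hi)."""
    cfg = cfg or GAConfig()
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite with hi > lo")
    width = hi - lo
    ndim = lo.size
    rng = np.random.default_rng(cfg.seed)

    # initial population; reseed if everything is infeasible
    for attempt in range(cfg.init_retries):
        pop = lo + rng.random((cfg.population_size, ndim)) * width
        costs = evaluate_population(pop, objective, cfg.parallel)
        if np.any(np.isfinite(costs)):
            break
    else:
        raise RuntimeError(
            "objective infinite for every candidate in "
            f"{cfg.init_retries} initial populations; revise the bounds")

    n_evals = cfg.population_size * (attempt + 1)
    n_rejected = int(np.sum(~np.isfinite(costs)))

    order = np.argsort(costs)
    best = pop[order[0]].copy()
    best_cost = float(costs[order[0]])
    history = [best_cost]
    stall = 0

    for _gen in range(cfg.generations):
        # tournament selection of parents
        idx = rng.integers(0, cfg.population_size,
                           size=(cfg.population_size, cfg.tournament_size))
        winners = idx[np.arange(cfg.population_size),
                      np.argmin(costs[idx], axis=1)]
        parents = pop[winners]

        # blend crossover on consecutive pairs
        children = parents.copy()
        a = cfg.crossover_alpha
        for k in range(0, cfg.population_size - 1, 2):
            if rng.random() < cfg.crossover_rate:
                p1, p2 = parents[k], parents[k + 1]
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                span = cmax - cmin
                low = cmin - a * span
                high = cmax + a * span
                children[k] = low + rng.random(ndim) * (high - low)
                children[k + 1] = low + rng.random(ndim) * (high - low)

        # per-gene Gaussian mutation
        mask = rng.random(children.shape) < cfg.mutation_rate
        children = children + mask * rng.normal(
            0.0, cfg.mutation_scale, children.shape) * width
        np.clip(children, lo, hi, out=children)

        # elitism: keep the current best individuals
        elite_idx = np.argsort(costs)[: cfg.elitism]
        children[: cfg.elitism] = pop[elite_idx]

        child_costs = evaluate_population(children, objective, cfg.parallel)
        n_evals += cfg.population_size
        n_rejected += int(np.sum(~np.isfinite(child_costs)))
        pop, costs = children, child_costs

        gen_best = int(np.argmin(costs))
        improved = costs[gen_best] < best_cost * (1.0 - 1e-12)
        if costs[gen_best] < best_cost:
            best_cost = float(costs[gen_best])
            best = pop[gen_best].copy()
        stall = 0 if improved else stall + 1
        history.append(best_cost)
        if stall >= cfg.stall_generations:
            break

    return FitResult(
        theta_star=best,
        best_cost=best_cost,
        cost_history=history,
        n_evaluations=n_evals,
        n_rejected=n_rejected,
    )
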