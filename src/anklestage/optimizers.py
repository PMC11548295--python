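"""Whale optimization algorithm, GA/PSO baselines and benchmark functions.

The whale optimization algorithm (WOA) is a population metaheuristic
modelled on humpback bubble-net hunting.  Each iteration every agent
either

* spirals toward the incumbent best (exploitation, probability 1/2):
  ``X' = X* + |X* - X| * exp(b*l) * cos(2*pi*l)`` with l ~ U[-1, 1]
  drawn per coordinate, since the spiral is defined component-wise;
* encircles the best when |A1| < 1:
  ``X' = X* - A1 * |C1*X* - X|`` with A1 = 2*a*r1 - a, C1 = 2*r2; or
* searches around a random agent when |A1| >= 1 (exploration):
  ``X' = Xrand - A1 * |C1*Xrand - X|``.

The convergence parameter ``a`` decays linearly from 2 to 0 over the
iteration budget, shifting the population from exploration to
exploitation.  Positions are hard-clipped to the box bounds; the
incumbent best is elitist, so the best-cost trace is non-increasing.

The baselines are a real-coded genetic algorithm (tournament selection,
arithmetic crossover, Gaussian mutation with an annealed step, elitism)
and a global-best particle swarm (inertia 0.7, cognitive/social weights
1.5/1.5).  Four classic box-bounded test functions are provided: the
sphere F1, Schwefel 2.22 F2 (sum plus product of absolute coordinates),
the shifted sphere F6 and the noisy quartic F7.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class WoaConfig:
    """Search configuration shared by WOA, GA and PSO.

    Defaults match the hyperparameter search: 8 agents, 5 iterations,
    3 dimensions with bounds (learning rate, hidden units, L2).
    """

    n_agents: int = 8
    max_iteration: int = 5
    dim: int = 3
    lb: tuple[float, ...] = (1e-4, 10.0, 1e-5)
    ub: tuple[float, ...] = (1e-1, 30.0, 1e-2)
    b: float = 1.0  # logarithmic-spiral shape constant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1 or self.max_iteration < 0 or self.dim < 1:
            raise ValueError("n_agents >= 1, max_iteration >= 0, dim >= 1 required")
        lb, ub = np.asarray(self.lb, float), np.asarray(self.ub, float)
        if lb.shape != (self.dim,) or ub.shape != (self.dim,):
            raise ValueError("lb and ub must be dim-vectors")
        if not np.all(lb < ub):
            raise ValueError("lb must be < ub component-wise")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lb, float), np.asarray(self.ub, float)


@dataclass
class OptimizerRun:
    best_pos: np.ndarray
    best_cost: float
    trace: np.ndarray  # best cost after init and after each iteration


def convergence_a(t: int, max_iteration: int) -> float:
    """a = 2 - t * (2 / max_iteration): linear decay from 2 to 0."""
    if max_iteration < 1:
        raise ValueError("max_iteration must be >= 1")
    if not 0 <= t <= max_iteration:
        raise ValueError(f"iteration t={t} outside [0, {max_iteration}]")
    return 2.0 - t * (2.0 / max_iteration)


def encircle_update(Xj: np.ndarray, Xstar: np.ndarray, a: float,
                    r1: float, r2: float) -> np.ndarray:
    """Shrinking-encirclement step toward the incumbent best."""
    A1 = 2.0 * a * r1 - a
    C1 = 2.0 * r2
    D = np.abs(C1 * Xstar - Xj)
    return Xstar - A1 * D


def spiral_update(Xj: np.ndarray, Xstar: np.ndarray, b: float, l) -> np.ndarray:
    """Logarithmic-spiral step toward the incumbent best.

    ``l`` in [-1, 1] may be a scalar or a per-coordinate vector; the
    update is component-wise either way.
    """
    D = np.abs(Xstar - Xj)
    return Xstar + D * np.exp(b * np.asarray(l)) * np.cos(2.0 * np.pi * np.asarray(l))


def search_update(Xj: np.ndarray, Xrand: np.ndarray, a: float,
                  r1: float, r2: float) -> np.ndarray:
    """Exploration step toward a randomly chosen agent."""
    A1 = 2.0 * a * r1 - a
    C1 = 2.0 * r2
    D = np.abs(C1 * Xrand - Xj)
    return Xrand - A1 * D


def _evaluate(objective: Objective, x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        raise ValueError(f"objective returned non-finite value {v} at position {x}")
    return v


def _init_population(cfg: WoaConfig, rng: np.random.Generator) -> np.ndarray:
    lb, ub = cfg.bounds
    return rng.uniform(lb, ub, size=(cfg.n_agents, cfg.dim))


def woa_optimize(objective: Objective, config: WoaConfig) -> OptimizerRun:
    """Minimize ``objective`` over the box with the whale optimization algorithm.

    Fully reproducible from ``config.seed``; the returned trace holds the
    incumbent best cost after initialization and after every iteration.
    """
    rng = np.random.default_rng(config.seed)
    lb, ub = config.bounds
    X = _init_population(config, rng)
    costs = np.array([_evaluate(objective, x) for x in X])
    best = int(np.argmin(costs))
    best_pos, best_cost = X[best].copy(), float(costs[best])
    trace = [best_cost]

    for t in range(config.max_iteration):
        a = convergence_a(t, config.max_iteration)
        for i in range(config.n_agents):
            p = rng.uniform()
            r1, r2 = rng.uniform(), rng.uniform()
            if p >= 0.5:
                l = rng.uniform(-1.0, 1.0, size=config.dim)
                X[i] = spiral_update(X[i], best_pos, config.b, l)
            else:
                A1 = 2.0 * a * r1 - a
                if abs(A1) < 1.0:
                    X[i] = encircle_update(X[i], best_pos, a, r1, r2)
                else:
                    j = int(rng.integers(config.n_agents))
                    X[i] = search_update(X[i], X[j], a, r1, r2)
            np.clip(X[i], lb, ub, out=X[i])
            c = _evaluate(objective, X[i])
            if c < best_cost:
                best_cost = c
                best_pos = X[i].copy()
        trace.append(best_cost)

    return OptimizerRun(best_pos=best_pos, best_cost=best_cost, trace=np.array(trace))


def ga_optimize(objective: Objective, config: WoaConfig) -> OptimizerRun:
    """Real-coded GA baseline: tournament selection (size 3), whole
    arithmetic crossover, Gaussian mutation with a linearly annealed
    step size, one-elite survival."""
    rng = np.random.default_rng(config.seed)
    lb, ub = config.bounds
    span = ub - lb
    X = _init_population(config, rng)
    costs = np.array([_evaluate(objective, x) for x in X])
    best = int(np.argmin(costs))
    best_pos, best_cost = X[best].copy(), float(costs[best])
    trace = [best_cost]

    p_mut = max(1.0 / config.dim, 0.05)
    for t in range(config.max_iteration):
        frac = t / max(config.max_iteration - 1, 1)
        sigma = (0.1 * (1.0 - frac) + 0.001) * span
        children = np.empty_like(X)
        children[0] = best_pos  # elitism
        for i in range(1, config.n_agents):
            cand = rng.integers(config.n_agents, size=3)
            pa = X[cand[np.argmin(costs[cand])]]
            cand = rng.integers(config.n_agents, size=3)
            pb = X[cand[np.argmin(costs[cand])]]
            alpha = rng.uniform()
            child = alpha * pa + (1.0 - alpha) * pb
            mask = rng.uniform(size=config.dim) < p_mut
            child = child + mask * rng.normal(0.0, sigma)
            children[i] = np.clip(child, lb, ub)
        X = children
        costs = np.array([_evaluate(objective, x) for x in X])
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_cost:
            best_cost = float(costs[gen_best])
            best_pos = X[gen_best].copy()
        trace.append(best_cost)

    return OptimizerRun(best_pos=best_pos, best_cost=best_cost, trace=np.array(trace))


def pso_optimize(objective: Objective, config: WoaConfig,
                 inertia: float = 0.7, c_cog: float = 1.5, c_soc: float = 1.5) -> OptimizerRun:
    """Global-best PSO baseline with velocity clamped to half the box span."""
    rng = np.random.default_rng(config.seed)
    lb, ub = config.bounds
    span = ub - lb
    vmax = 0.5 * span
    X = _init_population(config, rng)
    V = rng.uniform(-vmax, vmax, size=X.shape)
    costs = np.array([_evaluate(objective, x) for x in X])
    pbest = X.copy()
    pbest_cost = costs.copy()
    g = int(np.argmin(costs))
    best_pos, best_cost = X[g].copy(), float(costs[g])
    trace = [best_cost]

    for _ in range(config.max_iteration):
        r_cog = rng.uniform(size=X.shape)
        r_soc = rng.uniform(size=X.shape)
        V = inertia * V + c_cog * r_cog * (pbest - X) + c_soc * r_soc * (best_pos - X)
        np.clip(V, -vmax, vmax, out=V)
        X = np.clip(X + V, lb, ub)
        costs = np.array([_evaluate(objective, x) for x in X])
        improved = costs < pbest_cost
        pbest[improved] = X[improved]
        pbest_cost[improved] = costs[improved]
        g = int(np.argmin(pbest_cost))
        if pbest_cost[g] < best_cost:
            best_cost = float(pbest_cost[g])
            best_pos = pbest[g].copy()
        trace.append(best_cost)

    return OptimizerRun(best_pos=best_pos, best_cost=best_cost, trace=np.array(trace))


OPTIMIZERS: dict[str, Callable[[Objective, WoaConfig], OptimizerRun]] = {
    "woa": woa_optimize,
    "ga": ga_optimize,
    "pso": pso_optimize,
}

# (bounds, conventional dimension) per benchmark function
TEST_FUNCTION_SPECS: dict[str, tuple[float, float, int]] = {
    "F1": (-100.0, 100.0, 30),
    "F2": (-10.0, 10.0, 30),
    "F6": (-100.0, 100.0, 30),
    "F7": (-1.28, 1.28, 30),
}


def test_function(name: str, x: np.ndarray,
                  rng: np.random.Generator | None = None) -> float:
    """Evaluate one of the benchmark functions F1/F2/F6/F7 at x.

    F7 adds uniform [0, 1) noise per evaluation and therefore needs a
    seeded generator.
    """
    x = np.asarray(x, dtype=float)
    if name == "F1":
        return float(np.sum(x**2))
    if name == "F2":
        ax = np.abs(x)
        return float(np.sum(ax) + np.prod(ax))
    if name == "F6":
        return float(np.sum((x + 0.5) ** 2))
    if name == "F7":
        if rng is None:
            raise ValueError("F7 requires a seeded random generator for its noise term")
        i = np.arange(1, x.size + 1)
        return float(np.sum(i * x**4) + rng.uniform())
    raise ValueError(f"unknown test function {name!r}; expected one of {sorted(TEST_FUNCTION_SPECS)}")


def make_objective(name: str, noise_seed: int | None = None) -> Objective:
    """Closure over :func:`test_function`; F7's noise stream is seeded once."""
    if name not in TEST_FUNCTION_SPECS:
        raise ValueError(f"unknown test function {name!r}")
    rng = np.random.default_rng(noise_seed) if name == "F7" else None
    return lambda x: test_function(name, x, rng)


def benchmark(functions: list[str] | None = None,
              optimizers: list[str] | None = None,
              n_seeds: int = 5, seed0: int = 1,
              n_agents: int = 30, max_iteration: int = 500,
              dim: int | None = None) -> dict:
    """Run every (optimizer, function) pair over ``n_seeds`` seeds.

    Returns a JSON-serializable dict with per-pair final costs, their
    median and best, and the per-seed convergence traces.
    """
    functions = functions or list(TEST_FUNCTION_SPECS)
    optimizers = optimizers or list(OPTIMIZERS)
    results: dict = {"settings": {"n_agents": n_agents, "max_iteration": max_iteration,
                                  "n_seeds": n_seeds, "seed0": seed0},
                     "runs": {}}
    for fname in functions:
        lo, hi, d0 = TEST_FUNCTION_SPECS[fname]
        d = dim or d0
        for oname in optimizers:
            finals, traces = [], []
            for s in range(n_seeds):
                seed = seed0 + s
                cfg = WoaConfig(n_agents=n_agents, max_iteration=max_iteration,
                                dim=d, lb=(lo,) * d, ub=(hi,) * d, seed=seed)
                obj = make_objective(fname, noise_seed=seed + 10_000)
                run = OPTIMIZERS[oname](obj, cfg)
                finals.append(run.best_cost)
                traces.append(run.trace.tolist())
            results["runs"][f"{oname}:{fname}"] = {
                "final_costs": finals,
                "median": float(np.median(finals)),
                "best": float(np.min(finals)),
                "traces": traces,
            }
    return results
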