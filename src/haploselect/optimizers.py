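"""Four seeded, cardinality-constrained metaheuristics with one run interface.

Every algorithm searches the space of exactly-k subsets of N candidates for
a maximal group fitness, records a per-iteration convergence trace, and
draws all randomness from a single ``numpy`` generator seeded from its
config, so identical (problem, config, seed) gives an identical trace.
Tie-breaks are always by lowest index.

* **GA** — binary subset chromosomes, tournament selection, one-point
  crossover followed by cardinality repair, per-selected-slot swap
  mutation, elitism, and a stagnation restart that replaces the worst half
  of the population after three improvement-free generations.
* **DE** — continuous priority keys in [0,1]^N decoded to a subset by top-k
  (random-keys encoding), an adaptive pool of rand/1/bin, best/1/bin and
  current-to-best/1/bin strategies with +-10% jitter on F and CR, and
  greedy trial-vs-target replacement.
* **PSO** — binary positions with the standard inertia/cognitive/social
  velocity update, Bernoulli(sigmoid(v)) position sampling, deterministic
  add/remove repair with sigmoid(v) priorities, and personal/global bests
  updated only from repaired (feasible) evaluations.
* **SA** — single-solution Metropolis walk with a feasibility-preserving
  swap neighbourhood and geometric cooling T_k = T0 * alpha^k.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from math import ceil, exp

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fitness import SelectionProblem, SubsetSolution

__all__ = [
    "GAConfig",
    "DEConfig",
    "PSOConfig",
    "SAConfig",
    "ConvergenceTrace",
    "random_feasible_solution",
    "repair_to_k",
    "tournament_select",
    "one_point_crossover_with_repair",
    "swap_mutation",
    "de_mutation",
    "topk_decode",
    "pso_velocity_update",
    "sa_accept_probability",
    "run_ga",
    "run_de",
    "run_pso",
    "run_sa",
    "run_optimizer",
]


# ---------------------------------------------------------------------------
# configurations (defaults = the tuned values for the wheat-panel problem)


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 200
    generations: int = 250
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    tournament_size: int = 3
    elitism_fraction: float = 0.1
    stagnation_generations: int = 3
    stagnation_replace_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ParameterError("rates must lie in [0, 1]")
        if self.tournament_size < 2:
            raise ParameterError("tournament_size must be >= 2")
        if self.elitism_fraction * self.pop_size < 1:
            raise ParameterError("elitism must retain at least one solution")


@dataclass(frozen=True)
class DEConfig:
    pop_size: int = 200
    generations: int = 250
    F: float = 0.4
    CR: float = 0.8
    jitter_fraction: float = 0.1
    strategy_pool: tuple[str, ...] = ("rand/1/bin", "best/1/bin", "current-to-best/1/bin")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ParameterError("F must be > 0")
        if not (0 <= self.CR <= 1):
            raise ParameterError("CR must lie in [0, 1]")
        if not self.strategy_pool:
            raise ParameterError("strategy pool must be non-empty")
        if self.pop_size < 4:
            raise ParameterError("DE needs a population of >= 4")


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 100
    iterations: int = 100
    c1: float = 1.5
    c2: float = 2.0
    w_start: float = 0.5
    w_end: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ParameterError("c1 and c2 must be > 0")
        if not (self.w_start >= self.w_end >= 0):
            raise ParameterError("need w_start >= w_end >= 0")


@dataclass(frozen=True)
class SAConfig:
    initial_temp: float = 0.01
    cooling_rate: float = 0.96
    iterations_per_temp: int = 10
    max_temps: int | None = None
    total_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.cooling_rate < 1):
            raise ParameterError("cooling_rate must lie in (0, 1)")
        if self.initial_temp <= 0:
            raise ParameterError("initial_temp must be > 0")


@dataclass
class ConvergenceTrace:
    """Per-iteration best-so-far / mean fitness and wall time, plus the winner."""

    algorithm: str
    iteration: np.ndarray
    best_fitness: np.ndarray  # best-so-far series (non-decreasing)
    mean_fitness: np.ndarray
    elapsed_seconds: np.ndarray
    final_solution: SubsetSolution
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": self.iteration,
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
                "elapsed_seconds": self.elapsed_seconds,
            }
        )


class _Recorder:
    def __init__(self) -> None:
        self.t0 = time.perf_counter()
        self.iters: list[int] = []
        self.best: list[float] = []
        self.mean: list[float] = []
        self.secs: list[float] = []
        self._best_so_far = -np.inf

    def record(self, iteration: int, best: float, mean: float) -> None:
        self._best_so_far = max(self._best_so_far, best)
        self.iters.append(iteration)
        self.best.append(self._best_so_far)
        self.mean.append(mean)
        self.secs.append(time.perf_counter() - self.t0)

    def trace(self, algorithm: str, final: SubsetSolution, seed: int) -> ConvergenceTrace:
        return ConvergenceTrace(
            algorithm,
            np.asarray(self.iters),
            np.asarray(self.best),
            np.asarray(self.mean),
            np.asarray(self.secs),
            final,
            seed,
        )


# ---------------------------------------------------------------------------
# shared primitives


def random_feasible_solution(n: int, k: int, rng: np.random.Generator) -> SubsetSolution:
    """Uniformly random k-subset of n candidates."""
    if not (1 <= k <= n):
        raise ParameterError(f"k must be in [1, {n}]")
    include = np.zeros(n, dtype=np.uint8)
    include[rng.choice(n, size=k, replace=False)] = 1
    return SubsetSolution(include)


def repair_to_k(
    include: np.ndarray, k: int, priority: np.ndarray,
    rng: np.random.Generator | None = None,
) -> SubsetSolution:
    """Deterministic cardinality repair driven by a priority vector.

    Over-full subsets drop the lowest-priority selected indices; under-full
    subsets add the highest-priority unselected indices.  Ties break to the
    lowest index.  ``rng`` is accepted for interface symmetry but unused: all
    randomness lives in the priorities the caller supplies.
    """
    include = np.asarray(include, dtype=np.uint8).copy()
    priority = np.asarray(priority, dtype=float)
    sel = np.flatnonzero(include)
    if len(sel) > k:
        order = sel[np.lexsort((sel, priority[sel]))]  # ascending priority
        include[order[: len(sel) - k]] = 0
    elif len(sel) < k:
        unsel = np.flatnonzero(include == 0)
        order = unsel[np.lexsort((unsel, -priority[unsel]))]  # descending priority
        include[order[: k - len(sel)]] = 1
    return SubsetSolution(include)


def tournament_select(
    population: list[SubsetSolution], size: int, rng: np.random.Generator
) -> SubsetSolution:
    """Best of ``size`` members sampled with replacement (tie: lowest index)."""
    idx = rng.integers(0, len(population), size=size)
    best_f = -np.inf
    best_i = None
    for i in sorted(idx):
        f = population[i].fitness
        if f is None:
            raise ParameterError("tournament requires evaluated solutions")
        if f > best_f:
            best_f, best_i = f, i
    return population[best_i]


def one_point_crossover_with_repair(
    p1: SubsetSolution, p2: SubsetSolution, k: int, rng: np.random.Generator
) -> tuple[SubsetSolution, SubsetSolution]:
    """Splice at a uniform cut point, then repair with uniform-random priorities."""
    n = len(p1.include)
    cut = int(rng.integers(1, n))
    raw1 = np.concatenate([p1.include[:cut], p2.include[cut:]])
    raw2 = np.concatenate([p2.include[:cut], p1.include[cut:]])
    c1 = repair_to_k(raw1, k, rng.random(n))
    c2 = repair_to_k(raw2, k, rng.random(n))
    return c1, c2


def swap_mutation(
    sol: SubsetSolution, rate: float, rng: np.random.Generator
) -> SubsetSolution:
    """Per selected slot, with probability ``rate``, swap it with a random
    unselected index.  Cardinality is preserved exactly."""
    include = sol.include.copy()
    selected = np.flatnonzero(include)
    for idx in selected:
        if rng.random() < rate:
            unselected = np.flatnonzero(include == 0)
            if len(unselected) == 0:
                break  # k == N: nothing to swap with
            j = unselected[rng.integers(0, len(unselected))]
            include[idx] = 0
            include[j] = 1
    return SubsetSolution(include)


def topk_decode(keys: np.ndarray, k: int) -> SubsetSolution:
    """Subset of the k largest keys; ties resolve to the lowest index."""
    order = np.argsort(-np.asarray(keys, dtype=float), kind="stable")
    include = np.zeros(len(keys), dtype=np.uint8)
    include[order[:k]] = 1
    return SubsetSolution(include)


# ---------------------------------------------------------------------------
# genetic algorithm


def run_ga(problem: SelectionProblem, cfg: GAConfig = GAConfig()) -> ConvergenceTrace:
    rng = np.random.default_rng(cfg.seed)
    n, k = problem.n_individuals, problem.k
    pop = [random_feasible_solution(n, k, rng) for _ in range(cfg.pop_size)]
    for sol in pop:
        problem.evaluate(sol)
    n_elite = ceil(cfg.elitism_fraction * cfg.pop_size)
    rec = _Recorder()

    def fitnesses() -> np.ndarray:
        return np.asarray([s.fitness for s in pop])

    f = fitnesses()
    rec.record(0, float(f.max()), float(f.mean()))
    best_prev = float(f.max())
    stagnant = 0
    for gen in range(1, cfg.generations + 1):
        order = np.argsort(-f, kind="stable")
        children: list[SubsetSolution] = [pop[i].copy() for i in order[:n_elite]]
        while len(children) < cfg.pop_size:
            p1 = tournament_select(pop, cfg.tournament_size, rng)
            p2 = tournament_select(pop, cfg.tournament_size, rng)
            if rng.random() < cfg.crossover_rate:
                c1, c2 = one_point_crossover_with_repair(p1, p2, k, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                if len(children) < cfg.pop_size:
                    child = swap_mutation(child, cfg.mutation_rate, rng)
                    problem.evaluate(child)
                    children.append(child)
        pop = children
        f = fitnesses()
        best_now = float(f.max())
        if best_now > best_prev:
            stagnant = 0
            best_prev = best_now
        else:
            stagnant += 1
            if stagnant >= cfg.stagnation_generations:
                # restart: keep elites, replace the worst tail with fresh solutions
                n_replace = min(
                    int(cfg.stagnation_replace_fraction * cfg.pop_size),
                    cfg.pop_size - n_elite,
                )
                worst = np.argsort(-f, kind="stable")[::-1][:n_replace]
                for i in worst:
                    fresh = random_feasible_solution(n, k, rng)
                    problem.evaluate(fresh)
                    pop[i] = fresh
                f = fitnesses()
                stagnant = 0
        rec.record(gen, float(f.max()), float(f.mean()))
    best_idx = int(np.argmax(f))
    return rec.trace("ga", pop[best_idx].copy(), cfg.seed)


# ---------------------------------------------------------------------------
# differential evolution


def _distinct_indices(
    rng: np.random.Generator, pop_size: int, exclude: int, count: int
) -> list[int]:
    pool = [i for i in range(pop_size) if i != exclude]
    picks = rng.choice(len(pool), size=count, replace=False)
    return [pool[int(p)] for p in picks]


def de_mutation(
    population: np.ndarray,
    target_idx: int,
    strategy: str,
    f_eff: float,
    rng: np.random.Generator,
    best_idx: int,
) -> np.ndarray:
    """Differential mutant key vector for one target, clipped to [0, 1]."""
    pop_size = population.shape[0]
    if pop_size < 4:
        raise ParameterError("DE mutation needs >= 4 population members")
    x = population
    if strategy == "rand/1/bin":
        r1, r2, r3 = _distinct_indices(rng, pop_size, target_idx, 3)
        mutant = x[r1] + f_eff * (x[r2] - x[r3])
    elif strategy == "best/1/bin":
        r1, r2 = _distinct_indices(rng, pop_size, target_idx, 2)
        mutant = x[best_idx] + f_eff * (x[r1] - x[r2])
    elif strategy == "current-to-best/1/bin":
        r1, r2 = _distinct_indices(rng, pop_size, target_idx, 2)
        mutant = (
            x[target_idx]
            + f_eff * (x[best_idx] - x[target_idx])
            + f_eff * (x[r1] - x[r2])
        )
    else:
        raise ParameterError(f"unknown DE strategy {strategy!r}")
    return np.clip(mutant, 0.0, 1.0)


def run_de(problem: SelectionProblem, cfg: DEConfig = DEConfig()) -> ConvergenceTrace:
    rng = np.random.default_rng(cfg.seed)
    n, k = problem.n_individuals, problem.k
    keys = rng.random((cfg.pop_size, n))
    fitness = np.empty(cfg.pop_size)
    for i in range(cfg.pop_size):
        fitness[i] = problem.evaluate(topk_decode(keys[i], k))
    rec = _Recorder()
    rec.record(0, float(fitness.max()), float(fitness.mean()))
    for gen in range(1, cfg.generations + 1):
        best_idx = int(np.argmax(fitness))
        for i in range(cfg.pop_size):
            strategy = cfg.strategy_pool[rng.integers(0, len(cfg.strategy_pool))]
            f_eff = cfg.F * (1.0 + cfg.jitter_fraction * rng.uniform(-1.0, 1.0))
            cr_eff = float(
                np.clip(cfg.CR * (1.0 + cfg.jitter_fraction * rng.uniform(-1.0, 1.0)),
                        0.0, 1.0)
            )
            mutant = de_mutation(keys, i, strategy, f_eff, rng, best_idx)
            cross = rng.random(n) < cr_eff
            cross[rng.integers(0, n)] = True  # guarantee one mutant coordinate
            trial_keys = np.where(cross, mutant, keys[i])
            trial = topk_decode(trial_keys, k)
            trial_f = problem.evaluate(trial)
            if trial_f >= fitness[i]:  # greedy; ties keep the trial
                keys[i] = trial_keys
                fitness[i] = trial_f
        rec.record(gen, float(fitness.max()), float(fitness.mean()))
    best_idx = int(np.argmax(fitness))
    final = topk_decode(keys[best_idx], k)
    final.fitness = float(fitness[best_idx])
    return rec.trace("de", final, cfg.seed)


# ---------------------------------------------------------------------------
# particle swarm


def pso_velocity_update(
    v: np.ndarray, x: np.ndarray, p_best: np.ndarray, g_best: np.ndarray,
    w: float, c1: float, c2: float, rng: np.random.Generator,
) -> np.ndarray:
    """Standard inertia + cognitive + social update with fresh per-component r1, r2."""
    r1 = rng.random(len(v))
    r2 = rng.random(len(v))
    return w * v + c1 * r1 * (p_best - x) + c2 * r2 * (g_best - x)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def run_pso(problem: SelectionProblem, cfg: PSOConfig = PSOConfig()) -> ConvergenceTrace:
    rng = np.random.default_rng(cfg.seed)
    n, k = problem.n_individuals, problem.k
    swarm = [random_feasible_solution(n, k, rng) for _ in range(cfg.swarm_size)]
    pos = np.stack([s.include for s in swarm]).astype(float)
    vel = rng.uniform(-1.0, 1.0, size=(cfg.swarm_size, n))
    fit = np.asarray([problem.evaluate(s) for s in swarm])
    pbest = pos.copy()
    pbest_f = fit.copy()
    g_idx = int(np.argmax(pbest_f))
    gbest, gbest_f = pbest[g_idx].copy(), float(pbest_f[g_idx])
    rec = _Recorder()
    rec.record(0, gbest_f, float(fit.mean()))
    for t in range(1, cfg.iterations + 1):
        if cfg.iterations > 1:
            w = cfg.w_start + (cfg.w_end - cfg.w_start) * (t - 1) / (cfg.iterations - 1)
        else:
            w = cfg.w_start
        for i in range(cfg.swarm_size):
            vel[i] = pso_velocity_update(
                vel[i], pos[i], pbest[i], gbest, w, cfg.c1, cfg.c2, rng
            )
            prob1 = _sigmoid(vel[i])
            provisional = (rng.random(n) < prob1).astype(np.uint8)
            sol = repair_to_k(provisional, k, prob1)
            fit[i] = problem.evaluate(sol)
            pos[i] = sol.include.astype(float)
            if fit[i] > pbest_f[i]:
                pbest_f[i] = fit[i]
                pbest[i] = pos[i].copy()
            if fit[i] > gbest_f:
                gbest_f = float(fit[i])
                gbest = pos[i].copy()
        rec.record(t, gbest_f, float(fit.mean()))
    final = SubsetSolution(gbest.astype(np.uint8), gbest_f)
    return rec.trace("pso", final, cfg.seed)


# ---------------------------------------------------------------------------
# simulated annealing


def sa_accept_probability(current: float, neighbor: float, temp: float) -> float:
    """Metropolis acceptance: 1 for non-worse moves, else exp(delta / T)."""
    if temp <= 0:
        raise ParameterError("temperature must be > 0")
    if neighbor >= current:
        return 1.0
    return exp((neighbor - current) / temp)


def run_sa(problem: SelectionProblem, cfg: SAConfig = SAConfig()) -> ConvergenceTrace:
    rng = np.random.default_rng(cfg.seed)
    n, k = problem.n_individuals, problem.k
    current = random_feasible_solution(n, k, rng)
    cur_f = problem.evaluate(current)
    best = current.copy()
    best_f = cur_f
    rec = _Recorder()
    rec.record(0, cur_f, cur_f)
    for step in range(1, cfg.total_iterations + 1):
        level = (step - 1) // cfg.iterations_per_temp
        if cfg.max_temps is not None and level >= cfg.max_temps:
            break
        temp = cfg.initial_temp * cfg.cooling_rate**level
        include = current.include
        selected = np.flatnonzero(include)
        unselected = np.flatnonzero(include == 0)
        if len(unselected) == 0:
            rec.record(step, cur_f, cur_f)
            continue  # k == N: no feasible neighbour
        out_i = selected[rng.integers(0, len(selected))]
        in_i = unselected[rng.integers(0, len(unselected))]
        neighbor = current.copy()
        neighbor.include[out_i] = 0
        neighbor.include[in_i] = 1
        nb_f = problem.evaluate(neighbor)
        if rng.random() < sa_accept_probability(cur_f, nb_f, temp):
            current, cur_f = neighbor, nb_f
            if cur_f > best_f:
                best_f = cur_f
                best = current.copy()
        rec.record(step, cur_f, cur_f)
    return rec.trace("sa", best, cfg.seed)


_RUNNERS = {"ga": run_ga, "de": run_de, "pso": run_pso, "sa": run_sa}
_CONFIGS = {"ga": GAConfig, "de": DEConfig, "pso": PSOConfig, "sa": SAConfig}


def run_optimizer(problem: SelectionProblem, algo: str, config=None, **kwargs):
    """Dispatch: run the named algorithm with its default (or given) config."""
    if algo not in _RUNNERS:
        raise ParameterError(f"unknown algorithm {algo!r}")
    if config is None:
        config = _CONFIGS[algo](**kwargs)
    return _RUNNERS[algo](problem, config)
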