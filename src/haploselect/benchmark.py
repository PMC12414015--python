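"""Normalized convergence analysis, AUC scoring, run grids and overlap tables.

Raw convergence traces from different algorithms live on incomparable
fitness and iteration scales, so each trace is min-max normalised within
itself before comparison; convergence efficiency is then the trapezoidal
area under the normalised best-so-far curve (1.0 = the optimum was already
held at the first recorded iteration).  A trace whose best fitness never
changes maps to y = 1 by convention: the run is always at its best.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fitness import SelectionProblem
from .optimizers import ConvergenceTrace, run_optimizer

__all__ = [
    "NormalizedTrace",
    "normalize_trace",
    "convergence_auc",
    "overlap_table",
    "benchmark_grid",
    "plot_convergence",
]


@dataclass(frozen=True)
class NormalizedTrace:
    x: np.ndarray  # normalized iteration, strictly increasing 0 -> 1
    y: np.ndarray  # normalized best fitness in [0, 1]

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) < 2:
            raise ParameterError("normalized trace needs >= 2 aligned points")


def normalize_trace(trace: ConvergenceTrace) -> NormalizedTrace:
    """Min-max normalise iterations and best-so-far fitness within one trace."""
    it = np.asarray(trace.iteration, dtype=float)
    best = np.asarray(trace.best_fitness, dtype=float)
    if len(it) < 2:
        raise ParameterError("single-point trace cannot be normalised")
    span = it[-1] - it[0]
    if span <= 0:
        raise ParameterError("iteration axis is constant")
    x = (it - it[0]) / span
    lo, hi = best.min(), best.max()
    y = np.ones_like(best) if hi == lo else (best - lo) / (hi - lo)
    return NormalizedTrace(x, y)


def convergence_auc(nt: NormalizedTrace) -> float:
    """Trapezoidal area under the normalised convergence curve, in [0, 1]."""
    return float(np.trapezoid(nt.y, nt.x))


def overlap_table(selections: dict[str, set]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclusive Venn-region sizes and the pairwise intersection matrix.

    Regions are labelled by the '&'-joined member names (deterministic
    order: by member count, then label); only non-empty regions appear.
    """
    if len(selections) < 2:
        raise ParameterError("need >= 2 selections to intersect")
    names = list(selections)
    regions = []
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(selections[m] for m in members))
            outside = set.union(
                set(), *(selections[m] for m in names if m not in members)
            )
            size = len(inside - outside)
            if size:
                regions.append(("&".join(members), r, size))
    region_df = pd.DataFrame(regions, columns=["region", "n_members", "size"])
    region_df = region_df.sort_values(["n_members", "region"]).reset_index(drop=True)
    pair = pd.DataFrame(
        [[len(selections[a] & selections[b]) for b in names] for a in names],
        index=names, columns=names,
    )
    return region_df, pair


def benchmark_grid(
    problem: SelectionProblem,
    grid: list[tuple[str, object]],
    seeds: list[int],
) -> pd.DataFrame:
    """Run every (algorithm, config) cell for every seed; one row per run.

    ``grid`` entries are (algo_name, config) pairs; the config's own seed is
    replaced by each grid seed in turn.  Reports final fitness, AUC of the
    normalised best-so-far curve, elapsed seconds and evaluation counts.
    """
    import dataclasses

    rows = []
    run_ids = set()
    for algo, cfg in grid:
        for seed in seeds:
            run_id = (algo, repr(cfg), seed)
            if run_id in run_ids:
                raise ParameterError(f"duplicate benchmark run {run_id}")
            run_ids.add(run_id)
            cfg_seeded = dataclasses.replace(cfg, seed=seed)
            evals_before = problem.n_evaluations
            trace = run_optimizer(problem, algo, cfg_seeded)
            rows.append(
                {
                    "algorithm": algo,
                    "seed": seed,
                    "final_fitness": float(trace.best_fitness[-1]),
                    "auc": convergence_auc(normalize_trace(trace)),
                    "elapsed_seconds": float(trace.elapsed_seconds[-1]),
                    "n_evaluations": problem.n_evaluations - evals_before,
                }
            )
    return pd.DataFrame(rows)


def plot_convergence(traces: list[ConvergenceTrace], path: str | Path) -> None:
    """Normalised convergence curves, one line per trace."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for trace in traces:
        nt = normalize_trace(trace)
        ax.plot(nt.x, nt.y, label=f"{trace.algorithm} (seed {trace.seed})")
    ax.set_xlabel("normalised iteration")
    ax.set_ylabel("normalised best fitness")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
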