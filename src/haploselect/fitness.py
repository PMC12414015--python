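"""Group-fitness functions over a candidate founder subset.

All three criteria score a set of exactly k individuals through their
per-block haplotype values (a :class:`~haploselect.haploblocks.BlockValueTensor`):

* **OHS** (optimal haplotype selection): per block, the sum of the two best
  *distinct* haplotype values present among the subset's 2k copies — the
  value of the best achievable heterozygous "ultimate genotype" at every
  block simultaneously.  A block with a single distinct variant contributes
  that value twice (homozygous ultimate genotype).
* **OPV** (optimal population value): twice the per-block maximum — the
  doubled value of the ideal gamete assembled block-wise under unrestricted
  recombination; an upper bound, so ``opv >= ohs`` on any subset.
* **GEBV sum**: the sum of the selected individuals' total values; its exact
  argmax is top-k truncation on individual totals, making it the
  conventional-selection baseline.

Distinctness in OHS defaults to variant identity (allele string); an
alternative reading — best copy per *individual*, two distinct donors —
is available via ``distinct_by="individual"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .errors import ConstraintError, EnumerationCapError, ParameterError
from .haploblocks import BlockValueTensor

__all__ = [
    "SelectionProblem",
    "SubsetSolution",
    "ohs_fitness",
    "opv_fitness",
    "gebv_sum_fitness",
    "brute_force_optimum",
    "log10_search_space",
]


def log10_search_space(n: int, k: int) -> float:
    """log10 of C(n, k) via log-gamma: the size of the subset search space.

    Selecting 50 founders from 583 candidates gives ~1e74 combinations —
    the scale that motivates metaheuristic search over enumeration.
    """
    from scipy.special import gammaln

    return float(
        (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / np.log(10.0)
    )

FITNESS_KINDS = ("ohs", "opv", "gebv_sum")


@dataclass
class SubsetSolution:
    """Binary inclusion vector with exactly k ones; fitness set when evaluated."""

    include: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=np.uint8)

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.include)

    def copy(self) -> "SubsetSolution":
        return SubsetSolution(self.include.copy(), self.fitness)


@dataclass
class SelectionProblem:
    """A fixed-size founder-selection instance over a block-value tensor."""

    tensor: BlockValueTensor
    k: int
    fitness_kind: str = "ohs"
    distinct_by: str = "variant"  # OHS only
    n_evaluations: int = field(default=0, init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.tensor.n_individuals
        if not (1 <= self.k <= n):
            raise ParameterError(f"k must be in [1, {n}]")
        if self.fitness_kind not in FITNESS_KINDS:
            raise ParameterError(f"fitness_kind must be one of {FITNESS_KINDS}")
        if self.distinct_by not in ("variant", "individual"):
            raise ParameterError("distinct_by must be variant|individual")
        v = self.tensor.values
        b, _, _ = v.shape
        # flattened copy-level views used by the vectorized evaluators
        self._flat_values = v.reshape(b, -1)  # (B, 2N), copy-major per individual
        self._flat_codes = self.tensor.variant_codes.reshape(b, -1)
        self._best_copy = v.max(axis=2)  # (B, N)
        self._totals = self.tensor.individual_totals()  # (N,)

    @property
    def n_individuals(self) -> int:
        return self.tensor.n_individuals

    def evaluate_subset(self, indices: np.ndarray) -> float:
        """Fitness of the subset given as sorted individual indices."""
        self.n_evaluations += 1
        if self.fitness_kind == "gebv_sum":
            return float(self._totals[indices].sum())
        if self.fitness_kind == "opv":
            return 2.0 * float(self._best_copy[:, indices].max(axis=1).sum())
        return self._ohs(indices)

    def _ohs(self, indices: np.ndarray) -> float:
        if self.distinct_by == "individual":
            sub = self._best_copy[:, indices]  # (B, k)
            if sub.shape[1] == 1:
                return 2.0 * float(sub.sum())
            part = np.partition(sub, sub.shape[1] - 2, axis=1)
            return float(part[:, -2:].sum())
        cols = np.empty(2 * len(indices), dtype=np.intp)
        cols[0::2] = 2 * indices
        cols[1::2] = 2 * indices + 1
        v = self._flat_values[:, cols]  # (B, 2k)
        c = self._flat_codes[:, cols]
        rows = np.arange(v.shape[0])
        i1 = np.argmax(v, axis=1)
        v1 = v[rows, i1]
        c1 = c[rows, i1]
        masked = np.where(c == c1[:, None], -np.inf, v)
        v2 = masked.max(axis=1)
        v2 = np.where(np.isfinite(v2), v2, v1)  # single distinct variant: doubled
        return float(v1.sum() + v2.sum())

    def evaluate(self, solution: SubsetSolution) -> float:
        """Evaluate a solution in place, enforcing the cardinality constraint."""
        idx = solution.indices
        if len(idx) != self.k:
            raise ConstraintError(
                f"subset has {len(idx)} selected, expected exactly {self.k}"
            )
        solution.fitness = self.evaluate_subset(idx)
        return solution.fitness


def _check(problem: SelectionProblem, subset: SubsetSolution) -> np.ndarray:
    idx = subset.indices
    if len(idx) != problem.k:
        raise ConstraintError(f"infeasible subset: {len(idx)} != k={problem.k}")
    return idx


def ohs_fitness(problem: SelectionProblem, subset: SubsetSolution) -> float:
    """Sum over blocks of the two best distinct haplotype values in the subset."""
    idx = _check(problem, subset)
    return problem._ohs(idx)


def opv_fitness(problem: SelectionProblem, subset: SubsetSolution) -> float:
    """Doubled block-wise maximum: value of the ideal gamete, both copies."""
    idx = _check(problem, subset)
    return 2.0 * float(problem._best_copy[:, idx].max(axis=1).sum())


def gebv_sum_fitness(problem: SelectionProblem, subset: SubsetSolution) -> float:
    """Sum of the selected individuals' total block values."""
    idx = _check(problem, subset)
    return float(problem._totals[idx].sum())


def brute_force_optimum(
    problem: SelectionProblem, cap: int = 2_000_000
) -> tuple[float, list[tuple[int, ...]]]:
    """Exhaustive enumeration oracle: maximum fitness and every tied argmax.

    Argmax subsets are returned as 0-based index tuples in lexicographic
    order.  Refuses instances with C(N, k) beyond ``cap``.
    """
    n = problem.n_individuals
    total = comb(n, problem.k)
    if total > cap:
        raise EnumerationCapError(f"C({n},{problem.k}) = {total} exceeds cap {cap}")
    best = -np.inf
    argmax: list[tuple[int, ...]] = []
    for subset in combinations(range(n), problem.k):
        f = problem.evaluate_subset(np.asarray(subset, dtype=np.intp))
        if f > best:
            best, argmax = f, [subset]
        elif f == best:
            argmax.append(subset)
    return float(best), argmax
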