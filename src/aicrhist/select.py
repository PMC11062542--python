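"""Greedy forward restricted-AIC cut selection, plus an exhaustive oracle.

The full model search over groupings of k cells into K groups has
``C(k−1, K−1)`` candidates per K and is infeasible for realistic k.  The
restricted search keeps every previously chosen threshold fixed and adds
one cut at a time: the first step is an exhaustive search over the k−1
two-group models, each later step scans the remaining interior thresholds,
and the walk stops as soon as the best addition fails to lower the AIC.

``exhaustive_fit`` enumerates groupings outright and exists as an
independent correctness oracle for small grids; it is not the estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import xlogy

from .histcore import (
    CutSet,
    FineGrid,
    FitTrace,
    IrregularHistogram,
    TraceStep,
    aic_score,
    build_fine_grid,
    grouped_loglik,
    to_histogram,
)

__all__ = [
    "FitResult",
    "SaturatedGridError",
    "EnumerationBudgetError",
    "best_single_addition",
    "aicr_fit",
    "aicr_fit_grid",
    "exhaustive_fit",
    "n_partitions",
]


class SaturatedGridError(RuntimeError):
    """Raised when no interior threshold remains to be added."""


class EnumerationBudgetError(RuntimeError):
    """Raised when an exhaustive search would exceed its enumeration budget."""


@dataclass(frozen=True)
class FitResult:
    """Fitted irregular histogram with its search trace and fine grid."""

    histogram: IrregularHistogram
    cuts: CutSet
    trace: FitTrace
    fine_grid: FineGrid


def _g(N: np.ndarray, m: np.ndarray) -> np.ndarray:
    # Group term N ln(N/m) with 0 ln 0 = 0; the shared -N ln n cancels in
    # the split deltas used below.
    return xlogy(N, N) - N * np.log(m)


def best_single_addition(grid: FineGrid, fixed: CutSet) -> tuple[int, float]:
    """Best single cut to add to ``fixed``, with the resulting AIC.

    Evaluates the AIC of ``fixed ∪ {c}`` for every interior threshold
    ``c ∉ fixed`` and returns the minimiser; ties are broken toward the
    smallest cut index so the search is deterministic.
    """
    k = grid.k
    edges = fixed.group_edges(k)
    if fixed.K >= k:
        raise SaturatedGridError("all interior thresholds already cut")

    csum = np.concatenate(([0], np.cumsum(grid.counts)))
    cand = np.setdiff1d(np.arange(1, k), np.asarray(fixed.cut_indices, dtype=np.intp))
    # Group each candidate falls in: edges[g] < c < edges[g+1].
    g_idx = np.searchsorted(edges, cand, side="right") - 1
    left, right = edges[g_idx], edges[g_idx + 1]
    N1 = csum[cand] - csum[left]
    N2 = csum[right] - csum[cand]
    m1 = cand - left
    m2 = right - cand
    delta = _g(N1, m1) + _g(N2, m2) - _g(N1 + N2, m1 + m2)

    base_aic = aic_score(grouped_loglik(grid, fixed), fixed.K)
    aics = base_aic - 2.0 * delta + 2.0
    best = int(np.argmin(aics))  # first minimum -> smallest index
    return int(cand[best]), float(aics[best])


def aicr_fit_grid(grid: FineGrid) -> FitResult:
    """Run the greedy restricted-AIC selection on a pre-built fine grid.

    The AIC-best two-group model is the starting point — the single-group
    histogram is not a competitor.  From there each step adds the best
    remaining cut only if it strictly lowers the AIC, and the walk stops
    at the first non-improving step or when the grid is saturated.
    """
    cut, current_aic = best_single_addition(grid, CutSet())
    cuts = CutSet((cut,))
    trace = FitTrace()
    trace.steps.append(TraceStep(K=2, cut_index=cut, aic=current_aic, accepted=True))

    while cuts.K < grid.k:
        cut, aic = best_single_addition(grid, cuts)
        if aic < current_aic:
            cuts = CutSet(tuple(sorted(cuts.cut_indices + (cut,))))
            current_aic = aic
            trace.steps.append(TraceStep(K=cuts.K, cut_index=cut, aic=aic, accepted=True))
        else:
            trace.steps.append(
                TraceStep(K=cuts.K + 1, cut_index=cut, aic=aic, accepted=False)
            )
            break

    trace.final_aic = current_aic
    return FitResult(
        histogram=to_histogram(grid, cuts), cuts=cuts, trace=trace, fine_grid=grid
    )


def aicr_fit(data: np.ndarray) -> FitResult:
    """Fit the restricted-AIC irregular histogram to a univariate sample."""
    return aicr_fit_grid(build_fine_grid(data))


def n_partitions(k: int, K: int) -> int:
    """Number of ways to divide k ordered cells into K contiguous groups.

    Choosing the K−1 interior thresholds out of k−1 gives ``C(k−1, K−1)``;
    K=2 yields k−1 and K=3 yields (k−1)(k−2)/2.
    """
    if not 1 <= K <= k:
        raise ValueError("need 1 <= K <= k")
    return math.comb(k - 1, K - 1)


def exhaustive_fit(
    grid: FineGrid, max_K: int, budget: int = 10**6
) -> tuple[CutSet, float]:
    """Globally best cut set with at most ``max_K`` groups, by enumeration.

    Intended as a test oracle on small grids; refuses to run if the total
    number of candidate cut sets exceeds ``budget``.  Ties keep the
    lexicographically smallest cut set.
    """
    k = grid.k
    max_K = min(max_K, k)
    total = sum(n_partitions(k, K) for K in range(1, max_K + 1))
    if total > budget:
        raise EnumerationBudgetError(
            f"{total} cut sets exceed the enumeration budget of {budget}"
        )

    best_cuts, best_aic = None, math.inf
    interior = range(1, k)
    for K in range(1, max_K + 1):
        for combo in combinations(interior, K - 1):
            cuts = CutSet(combo)
            aic = aic_score(grouped_loglik(grid, cuts), K)
            if aic < best_aic:
                best_cuts, best_aic = cuts, aic
    assert best_cuts is not None
    return best_cuts, best_aic
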