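"""Core types and scores for grouped-multinomial histogram models.

A histogram with k equal-width cells is a multinomial model for the cell
counts ``n_1, …, n_k``; its log-likelihood is ``C + Σ_j n_j ln p_j`` with
per-cell MLE ``p̂_j = n_j / n``.  Merging adjacent cells into a group of
``m`` cells constrains their probabilities to be equal, giving the merged
estimator ``p̂ = N_g / (m_g n)`` for every cell of group ``g`` where ``N_g``
is the group count.  The combinatorial constant ``C = ln n! − Σ ln n_j!``
depends only on the fine-grid counts, never on the grouping, so it is
dropped throughout: only AIC differences between groupings matter, and
omitting it avoids ``ln n!`` overflow.

The AIC of a grouping with K groups is ``−2·loglik + 2(K−1)``; K−1 is the
number of free probabilities once the within-group ties and the sum-to-one
constraint are imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "FineGrid",
    "CutSet",
    "IrregularHistogram",
    "TraceStep",
    "FitTrace",
    "max_fine_bins",
    "build_fine_grid",
    "grouped_loglik",
    "aic_score",
    "to_histogram",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class FineGrid:
    """Equal-width fine partition of the data range with per-cell counts.

    Attributes
    ----------
    breaks : ndarray, shape (k+1,)
        Strictly increasing, equally spaced cell boundaries in data units.
    counts : ndarray of int, shape (k,)
        Number of observations per cell; sums to ``n``.
    """

    breaks: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        breaks = np.asarray(self.breaks, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "counts", counts)
        if breaks.ndim != 1 or counts.ndim != 1 or breaks.size != counts.size + 1:
            raise ValueError("breaks must have exactly one more entry than counts")
        if counts.size < 2:
            raise ValueError("a fine grid needs at least k = 2 cells")
        widths = np.diff(breaks)
        if np.any(widths <= 0):
            raise ValueError("breaks must be strictly increasing")
        h = widths[0]
        if np.any(np.abs(widths - h) > _REL_TOL * max(abs(h), 1.0)):
            raise ValueError("fine-grid cells must have equal width")
        if np.any(counts < 0):
            raise ValueError("cell counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("total count must be positive")

    @property
    def k(self) -> int:
        """Number of fine cells."""
        return int(self.counts.size)

    @property
    def n(self) -> int:
        """Total number of observations."""
        return int(self.counts.sum())

    @property
    def h(self) -> float:
        """Common fine-cell width."""
        return float((self.breaks[-1] - self.breaks[0]) / self.k)


@dataclass(frozen=True)
class CutSet:
    """Ordered interior fine-grid thresholds defining K = |cuts| + 1 groups.

    Cut index ``c`` refers to fine-grid break ``breaks[c]``, so valid cuts
    lie in ``{1, …, k−1}``.  The empty cut set is the single-group model.
    """

    cut_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        cuts = tuple(int(c) for c in self.cut_indices)
        object.__setattr__(self, "cut_indices", cuts)
        if any(c <= 0 for c in cuts):
            raise ValueError("cut indices must be positive interior positions")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cut indices must be strictly increasing")

    @property
    def K(self) -> int:
        """Number of groups."""
        return len(self.cut_indices) + 1

    def group_edges(self, k: int) -> np.ndarray:
        """Group boundaries ``[0, c_1, …, c_{K−1}, k]`` on the fine grid."""
        if self.cut_indices and self.cut_indices[-1] >= k:
            raise ValueError(f"cut index {self.cut_indices[-1]} outside grid with k={k}")
        return np.concatenate(([0], self.cut_indices, [k])).astype(np.intp)

    def multiplicities(self, k: int) -> np.ndarray:
        """Cells per group ``m_g``; all ≥ 1, summing to k."""
        return np.diff(self.group_edges(k))


@dataclass(frozen=True)
class IrregularHistogram:
    """Piecewise-constant density estimate on unequal-width bins."""

    breaks: np.ndarray
    group_counts: np.ndarray
    heights: np.ndarray
    n: int

    def __post_init__(self) -> None:
        breaks = np.asarray(self.breaks, dtype=float)
        counts = np.asarray(self.group_counts, dtype=np.int64)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "breaks", breaks)
        object.__setattr__(self, "group_counts", counts)
        object.__setattr__(self, "heights", heights)
        if breaks.size != counts.size + 1 or heights.size != counts.size:
            raise ValueError("inconsistent breaks/counts/heights lengths")
        if np.any(np.diff(breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if np.any(heights < 0) or np.any(counts < 0):
            raise ValueError("counts and heights must be non-negative")
        if counts.sum() != self.n:
            raise ValueError("group counts must sum to n")
        mass = float(np.sum(heights * np.diff(breaks)))
        if abs(mass - 1.0) > 1e-12:
            raise ValueError(f"histogram mass {mass} != 1")

    @property
    def K(self) -> int:
        return int(self.group_counts.size)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.breaks)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the estimate; 0 outside ``[breaks[0], breaks[-1]]``.

        Right-continuous at interior breaks; the last bin is closed on the
        right, matching the fine-grid cell convention.
        """
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.breaks, x, side="right") - 1
        idx = np.where((x == self.breaks[-1]), self.K - 1, idx)
        inside = (idx >= 0) & (idx < self.K)
        out = np.zeros(x.shape, dtype=float)
        out[inside] = self.heights[idx[inside]]
        return out


@dataclass(frozen=True)
class TraceStep:
    """One greedy step: the model examined and whether it was kept."""

    K: int
    cut_index: int | None
    aic: float
    accepted: bool


@dataclass
class FitTrace:
    """Record of the greedy search path; accepted AICs strictly decrease."""

    steps: list[TraceStep] = field(default_factory=list)
    final_aic: float = math.nan

    def accepted_aics(self) -> list[float]:
        return [s.aic for s in self.steps if s.accepted]


def max_fine_bins(n: int) -> int:
    """Number of fine-grid cells, ``k = ⌊n / ln n⌋``.

    Grows just fast enough that merging can recover both smooth and sharp
    densities; requires ``n ≥ 2`` (``ln 1 = 0``).
    """
    n = int(n)
    if n < 2:
        raise ValueError(f"need at least 2 observations, got n={n}")
    return int(math.floor(n / math.log(n)))


def build_fine_grid(data: np.ndarray) -> FineGrid:
    """Bin ``data`` into k = ``max_fine_bins(n)`` equal-width cells.

    The grid spans ``[min(data), max(data)]``; cells are half-open
    ``[b_i, b_{i+1})`` except the last, which is closed so the maximum is
    counted.
    """
    data = np.asarray(data, dtype=float).ravel()
    if data.size < 2:
        raise ValueError("need at least 2 observations to build a grid")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contain non-finite values")
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("degenerate range: all observations identical")
    k = max_fine_bins(data.size)
    breaks = np.linspace(lo, hi, k + 1)
    counts, _ = np.histogram(data, bins=breaks)
    return FineGrid(breaks=breaks, counts=counts)


def _group_sums(grid: FineGrid, cuts: CutSet) -> tuple[np.ndarray, np.ndarray]:
    edges = cuts.group_edges(grid.k)
    group_counts = np.add.reduceat(grid.counts, edges[:-1])
    return group_counts, np.diff(edges)


def grouped_loglik(grid: FineGrid, cuts: CutSet) -> float:
    """Maximised grouped-multinomial log-likelihood, constant C dropped.

    Equals ``Σ_j n_j ln p̂_{g(j)}`` with ``p̂ = N_g/(m_g n)`` for every fine
    cell of group g, which collapses to ``Σ_g N_g ln(N_g/(m_g n))``.  Empty
    groups contribute 0 (the ``0·ln 0 = 0`` convention).
    """
    group_counts, mult = _group_sums(grid, cuts)
    n = grid.n
    # xlogy gives N ln N with N=0 -> 0; subtract N(ln m + ln n) separately.
    return float(
        np.sum(xlogy(group_counts, group_counts) - group_counts * np.log(mult))
        - n * math.log(n)
    )


def aic_score(loglik: float, K: int) -> float:
    """AIC of a K-group histogram model: ``−2·loglik + 2(K−1)``."""
    if K < 1:
        raise ValueError("K must be at least 1")
    return -2.0 * loglik + 2.0 * (K - 1)


def to_histogram(grid: FineGrid, cuts: CutSet) -> IrregularHistogram:
    """Materialise the grouping as a density: ``f̂_g = N_g / (n w_g)``."""
    edges = cuts.group_edges(grid.k)
    group_counts, _ = _group_sums(grid, cuts)
    breaks = grid.breaks[edges]
    widths = np.diff(breaks)
    heights = group_counts / (grid.n * widths)
    return IrregularHistogram(
        breaks=breaks, group_counts=group_counts, heights=heights, n=grid.n
    )
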