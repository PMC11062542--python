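import numpy as np
import pytest

from aicrhist import FineGrid, IrregularHistogram


def make_grid(counts, lo=0.0, h=1.0):
    """FineGrid with the given cell counts on an equal-width grid."""
    counts = np.asarray(counts, dtype=np.int64)
    breaks = lo + h * np.arange(counts.size + 1, dtype=float)
    return FineGrid(breaks=breaks, counts=counts)


def make_hist(breaks, weights, n=100):
    """IrregularHistogram with bin masses proportional to ``weights``.

    Weights are scaled to integer counts summing to ``n``; heights follow
    as count/(n·width), so the result always integrates to one.
    """
    breaks = np.asarray(breaks, dtype=float)
    weights = np.asarray(weights, dtype=float)
    counts = np.round(n * weights / weights.sum()).astype(np.int64)
    counts[-1] += n - counts.sum()
    heights = counts / (n * np.diff(breaks))
    return IrregularHistogram(breaks=breaks, group_counts=counts, heights=heights, n=n)


@pytest.fixture
def grid_factory():
    return make_grid


@pytest.fixture
def hist_factory():
    return make_hist
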