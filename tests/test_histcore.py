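"""Grouped-multinomial likelihood, AIC score and fine-grid construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aicrhist import (
    CutSet,
    FineGrid,
    aic_score,
    build_fine_grid,
    grouped_loglik,
    max_fine_bins,
    to_histogram,
)
from conftest import make_grid

counts_strategy = st.lists(st.integers(0, 25), min_size=2, max_size=10).filter(
    lambda c: sum(c) > 0
)


def cuts_strategy(k):
    return st.sets(st.integers(1, k - 1)).map(lambda s: CutSet(tuple(sorted(s))))


def brute_force_loglik(counts, cuts):
    """Per-cell sum Σ_j n_j ln(N_g/(m_g n)) evaluated literally."""
    counts = np.asarray(counts)
    n, k = counts.sum(), counts.size
    edges = [0, *cuts.cut_indices, k]
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        N, m = counts[a:b].sum(), b - a
        for nj in counts[a:b]:
            if nj > 0:
                total += nj * math.log(N / (m * n))
    return total


@pytest.mark.parametrize("n,expected", [(50, 12), (100, 21), (800, 119), (2, 2)])
def test_max_fine_bins(n, expected):
    assert max_fine_bins(n) == expected


@pytest.mark.parametrize("n", [0, 1, -3])
def test_max_fine_bins_rejects_tiny_samples(n):
    with pytest.raises(ValueError):
        max_fine_bins(n)


def test_build_fine_grid_two_points():
    grid = build_fine_grid(np.array([0.0, 1.0]))
    np.testing.assert_allclose(grid.breaks, [0.0, 0.5, 1.0])
    np.testing.assert_array_equal(grid.counts, [1, 1])
    assert grid.k == 2 and grid.n == 2


@pytest.mark.parametrize(
    "data", [[0.0, 0.0, 0.0], [1.0, np.nan, 2.0], [1.0, np.inf], [3.0]]
)
def test_build_fine_grid_rejects_bad_input(data):
    with pytest.raises(ValueError):
        build_fine_grid(np.array(data))


@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=400))
@settings(deadline=None)
def test_fine_grid_counts_conserve_n(data):
    data = np.asarray(data)
    if data.max() <= data.min():
        return
    grid = build_fine_grid(data)
    assert grid.counts.sum() == data.size
    assert grid.breaks[0] == data.min() and grid.breaks[-1] == data.max()


def test_grouped_loglik_merged_pair():
    # cells with counts 3 and 5 merged out of n=10: both get p-hat = 8/20
    grid = make_grid([3, 5, 2])
    got = grouped_loglik(grid, CutSet((2,)))
    expected = (3 + 5) * math.log(0.4) + 2 * math.log(0.2)
    assert got == pytest.approx(expected, abs=1e-12)


def test_grouped_loglik_single_group():
    grid = make_grid([2, 2])
    assert grouped_loglik(grid, CutSet()) == pytest.approx(4 * math.log(0.5), abs=1e-10)
    assert grouped_loglik(grid, CutSet()) == pytest.approx(-2.77259, abs=1e-5)


@given(counts_strategy)
@settings(deadline=None)
def test_grouped_loglik_saturated(counts):
    grid = make_grid(counts)
    sat = CutSet(tuple(range(1, grid.k)))
    counts = np.asarray(counts)
    expected = sum(c * math.log(c / grid.n) for c in counts if c > 0)
    assert grouped_loglik(grid, sat) == pytest.approx(expected, abs=1e-9)


@given(counts_strategy, st.data())
@settings(deadline=None)
def test_grouped_loglik_matches_brute_force(counts, data):
    grid = make_grid(counts)
    cuts = data.draw(cuts_strategy(grid.k))
    assert grouped_loglik(grid, cuts) == pytest.approx(
        brute_force_loglik(counts, cuts), abs=1e-9
    )


@given(counts_strategy, st.data())
@settings(deadline=None)
def test_likelihood_nesting_and_saturated_bound(counts, data):
    """Refining a cut set never lowers the fitted likelihood; the
    saturated model bounds every grouping from above."""
    grid = make_grid(counts)
    big = data.draw(cuts_strategy(grid.k))
    sub = data.draw(st.sets(st.sampled_from(big.cut_indices)) if big.cut_indices else st.just(set()))
    small = CutSet(tuple(sorted(sub)))
    ll_small, ll_big = grouped_loglik(grid, small), grouped_loglik(grid, big)
    assert ll_big >= ll_small - 1e-9
    sat = grouped_loglik(grid, CutSet(tuple(range(1, grid.k))))
    assert ll_big <= sat + 1e-9


@given(counts_strategy, st.data(),
       st.floats(-50, 50), st.floats(0.01, 100))
@settings(deadline=None)
def test_loglik_invariant_to_translation_and_scale(counts, data, shift, scale):
    """The likelihood depends only on counts and multiplicities."""
    grid = make_grid(counts)
    moved = make_grid(counts, lo=shift, h=scale)
    cuts = data.draw(cuts_strategy(grid.k))
    assert grouped_loglik(grid, cuts) == pytest.approx(
        grouped_loglik(moved, cuts), rel=1e-12
    )


def test_aic_score_values():
    assert aic_score(-2.77259, 1) == pytest.approx(5.54518)
    assert aic_score(-2.77259, 2) == pytest.approx(7.54518)
    assert aic_score(0.0, 1) == 0.0
    with pytest.raises(ValueError):
        aic_score(0.0, 0)


@given(counts_strategy)
@settings(deadline=None)
def test_aic_saturated_minus_single_group_closed_form(counts):
    """AIC(saturated) − AIC(one group) has a closed form in the counts."""
    grid = make_grid(counts)
    k, n = grid.k, grid.n
    sat = aic_score(grouped_loglik(grid, CutSet(tuple(range(1, k)))), k)
    one = aic_score(grouped_loglik(grid, CutSet()), 1)
    sum_term = sum(c * math.log(c / n) for c in counts if c > 0)
    expected = -2 * (sum_term + n * math.log(k)) + 2 * (k - 1)
    assert sat - one == pytest.approx(expected, abs=1e-8)


def test_to_histogram_single_group():
    grid = make_grid([4, 6], lo=2.0, h=1.5)
    hist = to_histogram(grid, CutSet())
    assert hist.K == 1
    assert hist.heights[0] == pytest.approx(1.0 / 3.0)


def test_to_histogram_worked_grid():
    hist = to_histogram(make_grid([8, 0, 0, 8]), CutSet((1, 3)))
    np.testing.assert_array_equal(hist.group_counts, [8, 0, 8])
    np.testing.assert_allclose(hist.widths, [1.0, 2.0, 1.0])
    np.testing.assert_allclose(hist.heights, [0.5, 0.0, 0.5])


@given(counts_strategy, st.data())
@settings(deadline=None)
def test_to_histogram_integrates_to_one(counts, data):
    grid = make_grid(counts)
    cuts = data.draw(cuts_strategy(grid.k))
    hist = to_histogram(grid, cuts)
    assert np.sum(hist.heights * hist.widths) == pytest.approx(1.0, abs=1e-12)
    assert hist.group_counts.sum() == grid.n


def test_fine_grid_validation():
    with pytest.raises(ValueError):
        FineGrid(breaks=np.array([0.0, 1.0, 3.0]), counts=np.array([1, 1]))  # unequal
    with pytest.raises(ValueError):
        FineGrid(breaks=np.array([0.0, 1.0, 2.0]), counts=np.array([1, -1]))
    with pytest.raises(ValueError):
        CutSet((3, 2))
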