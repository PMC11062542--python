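# Methods

## Model and selection procedure

A histogram on `k` cells is the multinomial model for the cell counts:
`loglik(p) = C + Σ_j n_j ln p_j` with `C = ln n! − Σ_j ln n_j!`. Merging
adjacent cells into groups constrains the cell probabilities to be equal
within each group; the constrained MLE gives every cell of group `g`
probability `p̂ = N_g/(m_g n)` (group count over group size times sample
size). The fitted grouping is scored by `AIC = −2·loglik + 2(K−1)`, `K`
the number of groups. Two modelling conventions matter:

* **The constant `C` is dropped.** It depends only on the fine-grid
  counts, which the grouping never changes, so it cancels in every AIC
  comparison; dropping it also avoids `ln n!` overflow. Reported AIC
  values are therefore comparable within one fine grid, not across
  datasets.
* **Merged groups remain a k-cell multinomial** with tied probabilities,
  not a re-specified K-cell multinomial. This keeps log-likelihoods
  comparable across different `K` — the quantity the selection compares.

The fine grid has `k = ⌊n/ln n⌋` equal-width cells anchored at
`[min(data), max(data)]`; cells are half-open `[b_i, b_{i+1})` with the
last cell closed so the sample maximum is counted. The estimate is zero
outside the data range — a real feature of the estimator that the loss
functions account for (see below).

Selection is greedy and forward. The first step exhaustively scores all
`k−1` two-group models and keeps the best — the two-bin model is the
baseline of the procedure, and the one-bin histogram is never a
competitor. Each later step scans the remaining interior thresholds with
all previously accepted cuts held fixed (no backtracking) and accepts the
best addition only if it *strictly* lowers the AIC; a tie or an increase
stops the search. Ties among candidate cuts within a step are broken
toward the smallest index so fits are bit-reproducible.

The two-bin baseline deserves a note, since on very flat data a single
bin can have lower AIC than any split. We implement the forced two-bin
start because it is the procedure's actual definition, and the choice is
empirically identifiable: with a one-bin competitor the Uniform(0,1)
scenario cells fall visibly below their published Monte Carlo risk (the
one-bin model wins in roughly a third of Uniform samples at n=50 and is
nearly the truth there), while the forced start reproduces them.

`exhaustive_fit` enumerates every grouping up to a budget (default 10⁶
cut sets) and exists purely as an independent oracle for tests: the first
greedy step must match the exhaustive best two-group model exactly, and
the greedy final AIC can never beat the exhaustive optimum.

## Loss functions

Risk is measured between the exact reference density `f` and the fitted
step function `f̂`:

* `l1` — `∫|f−f̂|` (bounded by 2);
* `l2_ise` — the integrated squared error `∫(f−f̂)²`, not its square
  root;
* `hellinger2` — the squared Hellinger distance under the standard ½
  convention, `H² = ½∫(√f−√f̂)² = 1 − ∫√(f f̂)` (bounded by 1).

The ISE and H² conventions are deliberate: the three losses must be
jointly consistent (Le Cam: `H² ≤ ½L1 ≤ H√(2−H²)`, asserted on every
simulated replicate), and the Monte Carlo calibration below confirms both
conventions against the reference risk values, so no alternate scaling is
needed. Outside `[breaks[0], breaks[-1]]` the estimate is identically
zero; the tails therefore add their full `f`-mass to L1 (via the exact
cdf), `∫f²` to the ISE, and nothing to the Hellinger affinity.

Per-bin integrals use adaptive Gauss–Kronrod quadrature
(`scipy.integrate.quad`, `epsabs=1e-10`, `epsrel=1e-9`, up to 200
subintervals per bin); finite support endpoints falling inside a bin are
passed as known discontinuities, while the kinks of `|f−c|` are left to
adaptive refinement. Accumulated quadrature error bounds are reported on
every `LossValue` and are typically below 1e−8; the test suite checks the
quadrature against a dense segmented trapezoidal oracle to 1e−5. Infinite
`∫f²` tails are truncated 50 units beyond the histogram range, past which
every reference density squared carries below 1e−11 mass.

## Reference distributions and sampling

The six reference shapes — N(0,1), Exp(1), U(0,1),
0.5·N(0,1)+0.5·N(4,1), t₃, Beta(1.5,1.5) — are written as closed-form
pdf/cdf pairs on `scipy.special` ufuncs (`ndtr`, `stdtr`, `betainc`);
e.g. Beta(1.5,1.5) has `B(1.5,1.5) = π/8`, so `pdf = (8/π)√(x(1−x))`.
Closed forms keep scalar calls inside quadrature about fifty times
cheaper than frozen `scipy.stats` objects; exact agreement with
`scipy.stats` is unit-tested. Sampling uses `numpy.random.default_rng`
(PCG64): ziggurat normals, inverted exponentials/uniforms, numpy's
standard-t and beta generators, and for the mixture a normal draw shifted
by 4 with probability ½. A given seed reproduces the identical sample
vector on one platform; cross-platform bit-identity is not guaranteed by
numpy and not claimed.

## Monte Carlo harness

A study cell is (distribution, sample size); the default grid is all six
distributions × n ∈ {50, 100, 200, 400, 800} at 5000 replicates per cell,
the conditions under which the reference risk values were produced.
Replicate r of a cell gets the seed sequence
`SeedSequence([base_seed, dist_code, n, r, attempt])`, so cells and
replicates are reproducible in isolation and results never depend on
which other cells run alongside. A degenerate sample (zero range, so no
grid exists) is logged and redrawn with the next `attempt`; under
continuous reference distributions this is a measure-zero safeguard only.
Cell rows carry the mean loss, its standard error `sd/√R` and the
replicate count at full precision; rounding to the conventional three
decimals happens only at presentation.

## Problem sizes in the shipped checks

The acceptance script runs the full 5000-replicate protocol for its seven
cells (about two minutes on one CPU). The test suite uses smaller sizes
chosen for quick iteration: scenario-cell means at 1000 replicates with a
4-standard-error + rounding-quantum tolerance (the standard error is the
run's own, so the tolerance is not hand-tuned), the monotone
risk-decline check at 300 replicates on the n=50 and n=800 endpoints, and
the greedy-vs-exhaustive comparison on 200 random grids with k ≤ 10.

## What the synthetic study does and does not show

The generator draws i.i.d. samples from smooth, fully known densities.
That validates the selection rule, the likelihood algebra and the loss
integration, and reproduces the published risk surface; it says nothing
about dependent data, discretised/rounded measurements (ties shrink the
effective fine grid), or densities with unbounded peaks. Two known
limitations of the estimator itself: the data-range anchoring means tail
mass beyond the sample range is always missed (visible as the floor on
L1 for heavy-tailed t₃), and the greedy fixing of thresholds can lodge a
cut one fine cell off the optimum with no later correction — the
exhaustive oracle bound quantifies this gap on small grids.

## Empirical check

On the Old Faithful eruption-duration series (n = 299, Azzalini & Bowman
1990; shipped as a test fixture copied from the `MASS` R package) the
fitted histogram has 15 bins, matching the published analysis of that
dataset. The companion plasma-triglycerides dataset is not freely
redistributable and is left to the user; `aicrhist fit <file> --column
<name>` reproduces that analysis given the data.
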