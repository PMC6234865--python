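# Methods

## Transmission model

A mother's symbiont population is summarized by a lineage-abundance profile
`p = (p_1, …, p_L)`, `p_i > 0`, `Σ p_i = 1`. Each egg receives `N` cells
drawn independently with replacement from `p`; the per-egg composition is
therefore one draw from `Multinomial(N, p)`, and the simulator samples it as
such rather than placing cells one at a time. The two procedures are
distributionally identical (a multinomial is by definition the sum of `N`
iid categorical draws); the equivalence is property-tested against
sequential categorical sampling at small `N`. Assumptions: no within-host
replication or selection between sampling and hatching, lineages are carried
by distinct cells, and egg fate is a deterministic function of the received
composition.

**Viability.** An egg is viable iff it received at least `k_i` cells of
every lineage `i`. `k` is a scalar applied to all lineages by default
(`k ∈ {1, 50, 100}` are the standard settings); a per-lineage vector is
accepted for the alternative reading in which only the rarest lineage
carries a raised threshold. We apply `k` to every lineage because the raised
thresholds are described as so many cells "of each" lineage; with a scalar
`k` the rarest lineage is binding in practice anyway.

**Minimal transmission number.** The quantity of interest is the smallest
grid value of `N` at which *all* simulated eggs (default `I = 10,000` per
grid point) are viable — an operational reading of "guaranteed to receive
all lineages", since no finite `N` makes coverage certain. The grid starts
at 1 with step 20; the traditional 2,000-cell ceiling doubles automatically
until the minimum is found, because raised-`k` minima lie far above it.
Because the first all-viable grid point is a stochastic first-passage event,
the returned `N_min` varies by a few grid steps between seeds; a re-check
under an independent seed reports the viable fraction at `N_min` (typically
≥ 0.999). Refinement below the grid step is available but off by default:
grid-resolution results are the convention here. Unreachable criteria return
a sentinel (`found=False`) rather than raising, so sweeps over harsh
criteria complete.

**Oracles.** For `k = 1` the exact coverage probability is the
inclusion–exclusion sum over lineage subsets, `Σ_S (−1)^|S| (1 − p_S)^N`
(O(2^L), guarded at L = 25; note `0^0 = 1` so `N = 0` yields 0 for `L ≥ 1`).
For arbitrary `k` on tiny instances, the probability is summed directly over
all compositions of `N` into `L` parts (guarded at 10^6 compositions). The
two oracles agree to 1e-12 wherever both apply, and the simulator is tested
against the closed form at 4 Monte-Carlo standard errors.

**Random numbers.** Each (seed, grid point) pair gets its own
`SeedSequence`-derived generator, so changing the grid layout or iteration
count never reshuffles another grid point's eggs, and repeated runs are
bit-identical. The all-viable search draws eggs in fixed 1,000-egg blocks
and stops at the first failing block — an exact shortcut, since only the
existence of a failure matters below `N_min`.

## Profiles

Built-in communities: a six-lineage vector `(0.621, 0.18, 0.10, 0.06, 0.03,
0.009)` spanning a 69-fold range with the rarest lineage at 0.9%, and a
30-lineage geometric ladder spanning a 74-fold range. For the 30-lineage
community only the lineage count and fold-range are published, not the
coverage vector, so the geometric ladder is a declared stand-in: it is the
maximum-entropy-style one-parameter family fixed by those two constraints.
The complexity sweep in the reproduce report builds `n`-lineage ladders
sharing the 30-lineage ladder's common ratio, so unevenness grows with
lineage count as it does in sequencing-coverage-derived profiles. Profiles
are renormalized on input (never rejected for an off-by-rounding sum) and
stored most-abundant-first by the canonical constructors; all downstream
results are permutation-invariant (tested).

## Stereology

The ball envelope is a sphere or spheroid of semi-axes `(a, b, c)` μm,
volume `(4/3)πabc`; cells are assumed uniformly distributed points.

**Box route.** `N̂ = n_box · V_ball / V_box`. Exact for a deterministic
uniform grid of cells; unbiased with ~Poisson counting error for random
uniform cells (tested on synthetic balls across 20 seeds at 4 Poisson
standard deviations). Units cancel, so any length unit works if shared. A
second, intermixed species is co-estimated as `N̂_B = N̂_A · (n_B/n_A)` with
the count ratio taken on a single slice; replicate estimates (conventionally
three) are combined by arithmetic mean of point estimates and bounds.

**Section route.** A sphere of radius `R` sectioned at depth fraction `f`
(of the full ball length, from the nearer edge; `f = 0.5` is the great
circle) shows a disc of radius `R√(4f(1−f))`. The areal density of cell
profiles on the disc, `σ`, converts to volumetric density by the
mean-spacing argument `ρ = σ^{3/2}` — equivalently, the slab that a 2-D
count effectively samples is one mean inter-cell spacing thick. Multiplying
by the ball volume cancels `R`:

    N̂ = (4/3) n^{3/2} / ( √π (4f(1−f))^{3/2} ).

Since `f` is unknown, the estimate is a range: lower at `f = 0.5`, upper at
`f = 0.25`; the ratio of the bounds is identically `(4/3)^{3/2} ≈ 1.5396`,
and `N̂ ∝ n^{3/2}`. The point estimate is by convention the lower,
central-section value (ranges are conventionally printed lower–upper with
the central-section figure first). Estimates are rounded to the nearest
integer cell. Checked against a built-in compendium of 17 published
count/range pairs: both bounds match exactly for the exactly printed counts
(630, 1,750, 20, 21, 56); for counts published as approximate ("~") the
printed lower bounds can sit up to 5 cells off any integer-count prediction
— those printed pairs are internally inconsistent with their own upper
bounds, consistent with unrounded underlying counts that were not published.
Fractional section counts are accepted as real-valued `n`.

Known limitations: the section estimator assumes sphericity and even mixing
and degrades for off-center sections beyond `f = 0.25`; tube-shaped cells
cut twice by a section are not modelled; spheroid semi-axes are taken as
given, not inferred from images.

## Synthetic data

`generate_ball` places each species' cells uniformly in the envelope by
exact transform sampling — isotropic direction, radius `U^{1/3}`, then axis
scaling — so output is seed-stable with no rejection loop. Virtual sections
count cell centers in a slab perpendicular to the z-axis (depth convention
as above); virtual boxes count points in an axis-aligned box validated to
lie inside the envelope. `generate_egg_table` emits iid multinomial egg
compositions. What these fixtures deliberately lack relative to real data:
cell shape and size (centers only, so no double-counting of cut cells),
optical blur and segmentation error, spatial clustering of lineages, and
any biological variation in ball size or age. Passing recovery tests
therefore validate the estimators *under their own assumptions*, not the
microscopy pipeline.

A self-consistency property ties the two engines' assumptions together: on
a synthetic ball with slab thickness set to the mean inter-cell spacing
`(V/N)^{1/3}`, the section estimator recovers the true `N` within 15% for
`N ≥ 10^4` (in expectation it is exact up to the slab-curvature term,
because `σ = N^{2/3}/V^{2/3}` makes `σ^{3/2} = N/V` identically).

## Problem sizes and defaults

Simulations use `I = 10,000` eggs per grid point and grid step 20 — the
study-scale settings — throughout the acceptance checks and the reproduce
report; unit tests use smaller `I` where only mechanics are under test, and
the oracle-agreement checks use `I = 10^5` for tighter Monte-Carlo error.
At these sizes the full test suite runs in seconds on one CPU. Tolerances:
profile sums to 1 within 1e-9; oracle cross-agreement 1e-12; Monte-Carlo
assertions at 4 standard errors of the quantity under test.
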