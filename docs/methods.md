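# Methods

## The meristogram model

Acanthocephalan proboscis hooks are serially homologous structures: one
longitudinal row of a specimen shows smooth positional variation in hook
size and shape, and the *pattern* of that variation (rather than absolute
size) carries taxonomic information.  The meristogram condenses a pooled
collection of rows into four standardized curves over percent-position:

| symbol | quantity | definition | units before standardization |
|---|---|---|---|
| L | blade length | measured | µm |
| B | base width | measured | µm |
| A | area | L·B/2 (triangular approximation) | µm² |
| R | robustness | B·100/L | dimensionless |

The pipeline, applied in this fixed order:

1. **Position standardization.** Hook *i* of a row with *n* hooks (counted
   from the distal end) maps to *p = i·100/(n+1)*.  The *n+1* denominator
   centres the points inside (0, 100), so rows with different hook counts
   become comparable; the first and last hooks never sit on the axis
   endpoints.
2. **Derived variables.** A and R per hook.  The identity R·L = 100·B holds
   exactly and is used as a self-check.
3. **Row standardization.** Each of L, B, A, R is divided by its own
   maximum *within the row* and multiplied by 100.  The four maxima are
   independent and may sit on different hooks.  Any per-row scalar on both
   measured variables (allometry, sexual size dimorphism) cancels exactly:
   L and B scale by *c*, A by *c²*, R not at all, and every one of those
   factors is removed by its own row maximum.
4. **Moving average.** A window of integer width *w* percent slides along
   the percent-position axis.  Convention used here: half-open intervals
   [s, s+w) with the left edge at every integer s ∈ {0, …, 100−w}.  Each
   placement containing at least one hook yields a point whose abscissa is
   the *mean hook position in the window* (not the window midpoint — this
   produces the characteristic non-uniform point spacing) and whose
   ordinates are the means of the standardized variables.  Consecutive
   placements covering an identical hook set collapse to one point, and in
   the rare case that two distinct hook sets share a mean position the
   first is kept, so abscissae are strictly increasing.
5. **Linear interpolation (optional, default on).** The four curves are
   resampled at every integer position in [⌈x_min⌉, ⌊x_max⌋] by
   piecewise-linear interpolation; no extrapolation beyond the data span.
   Interpolated values are convex combinations, so they never leave the
   range of the smoothed values.  This step exists chiefly to give every
   collection a common abscissa for multivariate comparison.
6. **Collection rescaling.** Each curve is divided by its own maximum and
   multiplied by 100 (the "percent-max-collection-value"), so every final
   curve attains exactly 100 somewhere; with interpolation on, it does so
   on the integer grid.

**Minimum moving-average interval (MMAI).** Enforced as
⌈100/(n_min+1)⌉ where n_min is the hook count of the shortest row in the
collection.  Hooks of any row are spaced 100/(n+1) ≤ 100/(n_min+1) apart
and span a superset of [100/(n_min+1), 100·n_min/(n_min+1)], so any
admissible window inside that span contains at least one hook from every
row — every specimen contributes to every segment.  Requests below the
MMAI are refused with the computed bound in the message.

**Peak positions.** Reported per variable as the abscissa of the curve
maximum; exact ties resolve to the most distal (smallest) position for
deterministic reporting.

Numerical choices: double precision throughout, no rounding before output
formatting (curve CSVs print 6 significant digits, Newick branch lengths
10).  *w* is restricted to integers, matching the 1 %-step windowing.

## Area-formula validation

The triangular area estimate is validated against digitized
cross-sectional areas by simple OLS with the *estimate as response* and
the *measurement as predictor* (the orientation in which published
regression lines for this check are stated).  R² is the squared Pearson
correlation; fewer than three points or a constant predictor is refused.
Because the meristogram standardizes within rows, the estimate only needs
to be proportional to the true area; the regression quantifies absolute
accuracy as well.

## Comparison layer

Interpolated meristograms computed at one common interval are concatenated
into a matrix whose rows are collections and whose columns are
(variable, integer position) pairs restricted to the intersection of the
collections' position ranges.  Intersection (rather than union with
imputation) is this package's choice for handling range mismatches: it
uses only positions every collection actually covers.

PCA is performed on the mean-centered, *unscaled* matrix (all features
share the percent scale, and covariance PCA is the default convention of
the statistical environments this analysis style comes from), via SVD.
Component signs are fixed so each loading vector's largest-magnitude entry
is positive.  Clustering uses the first two PC scores by default (a flag
exposes more), under four distance metrics: Euclidean, Manhattan, maximum
(Chebyshev) and Minkowski with exponent p = 3 — p = 2 would duplicate
Euclidean, and the exponent used in the original analyses is unpublished,
so it is exposed as a flag.

UPGMA (size-weighted average linkage) is implemented directly rather than
through a library call so that ties in the minimum inter-cluster distance
can be broken deterministically by the lexicographically smallest pair of
sorted leaf-label tuples; node heights are half the merge distance, giving
an ultrametric tree.  The test suite cross-checks it against SciPy's
independent average-linkage implementation on random inputs.

## Synthetic data generator

The generator emulates the structure of real hook collections: per-row
hook counts drawn uniformly from a range, blade length and base width
following strictly positive unimodal trends over relative position
u ∈ (0,1), a per-row lognormal allometry factor applied to both measured
variables, and multiplicative lognormal measurement noise (error scales
with hook size and positivity is preserved).  Trends are
beta-density-shaped bumps on a positive floor, parameterized directly by
peak location so the true peak of every derived curve is known in closed
form or by dense evaluation.  Randomness comes from
`numpy.random.default_rng` (PCG64) under a single seed; replicate *r* of a
recovery experiment reseeds with seed + r.

Defaults model a mid-sized *Echinorhynchus*-like sample: 12 rows, 8–12
hooks per row, lengths ≈ 40–90 µm peaking at u = 0.35, bases ≈ 15–25 µm
peaking at u = 0.6, allometry SD 0.3, noise SD 0.03.

What the generator does **not** emulate: radial (dorsal/ventral)
asymmetry of real armature beyond carrying surface labels, bimodal or
non-unimodal trends, correlated noise between length and base of the same
hook, and between-population divergence within one collection.  Passing
the synthetic tests therefore shows the pipeline recovers known unimodal
trends under realistic noise — it does not certify the taxonomic
reliability of meristograms on field data.

**Peak-recovery resolution.** With zero noise the recovered peak sits at
(or interpolates near) the sampled hook position closest to the trend
peak, so recovery error is bounded by the position-grid offset.  When all
rows share one hook count the grid is common to all rows and a trend peak
falling between grid points produces a systematic error up to half the
hook spacing; with mixed hook counts (the default 8–12 range) the pooled
position grids interleave and the median error drops to about one position
unit.  This is a property of the method, not of the implementation.

## Known limitations

- The original software's exact window placement is unpublished; a
  different but defensible convention can shift reported peak positions by
  one or two position units.  Comparisons against published peak positions
  therefore use a ±2 tolerance.
- Smoothing rows with fewer than 3 hooks is accepted (the algorithm is
  defined for any n ≥ 1) but statistically weak; the reader logs a
  warning.
- The checks that reproduce published regression coefficients, study
  MMAIs, peak positions and dendrogram topologies require the original
  hook-measurement CSV files, which are third-party research data not
  redistributed with this package; place them under `data/` at the
  repository root to enable those tests.

## Problem sizes used in tests and the acceptance script

Test collections use 1–20 rows of up to ~12 hooks (≤ 200 hooks total per
case); the brute-force smoothing oracle enumerates all ≤ 101 window
placements; UPGMA is cross-validated on up to 7 leaves; recovery
experiments use 10 replicates of 20 rows.  The acceptance script simulates
6 taxa of 12 rows each.  These sizes match the scale of real collections
in this field (tens of specimens per taxon).
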