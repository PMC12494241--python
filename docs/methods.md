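# Methods

This note documents the statistical model behind `geogain`, the default
parameters and why they hold their values, the synthetic-data generator's
scope, and the numerical choices that make runs reproducible bit for bit.

## Model and assumptions

Yield (or any field variable) under one treatment is modelled as an
intrinsically stationary random field: an unknown constant mean plus a
zero-mean spatially correlated fluctuation whose structure is captured by a
semivariogram γ(h) depending only on separation distance h (isotropy is
assumed; anisotropic variograms are out of scope). Ordinary kriging is the
best linear unbiased predictor under this model. Treatments are assumed to
act additively and independently of location — the gain surface is then the
difference of two independently estimated final surfaces, and its mean
estimates the treatment effect.

The residual-correction step relaxes the stationarity assumption in
practice: systematic local bias of the base estimate shows up in the
holdout residuals, is kriged into an error surface, and added back. With a
nugget-free variogram this construction is exact at the held-out points
(kriging honours its data), which the test suite verifies to 1e-6.

## Variogram estimation and fitting

* Matheron estimator on equal-width, right-closed lag bins over
  (0, max_dist]; zero-pair bins are dropped. Defaults: 100 bins,
  max_dist = 1000 m, every point used (`skip = 1`) — the default values of
  the kriging backends common in GIS toolchains, kept so that results match
  practitioner expectations.
* Model families (nugget c0, partial sill c, range a, slope b):
  linear c0 + b·h; exponential c0 + c(1 − e^{−3h/a});
  Gaussian c0 + c(1 − e^{−3h²/a²}); spherical c0 + c(1.5(h/a) − 0.5(h/a)³)
  capped at the sill. The −3h/a scaling makes a an *effective* range
  (≈95% of the sill), the convention of most geostatistical software.
  γ(0) = 0 in all families.
* Fitting is weighted least squares with weights √N(h) applied to the
  residuals (i.e. pair-count weights on squared errors), non-negativity box
  constraints, and five deterministic starts whose range candidates span
  0.1–1.0 of the largest lag. The linear family reduces to a bounded linear
  least-squares problem solved directly. A fit requires ≥3 non-empty bins;
  the empirical estimator itself only requires one (so that degenerate but
  well-defined configurations, e.g. a single pair, still evaluate).

## Kriging

* System: dense ordinary-kriging solve per target with the unbiasedness
  constraint; estimate Σλᵢzᵢ, variance λ·γ₀ + μ.
* Neighborhood defaults: global search, min 16 / max 20 neighbors, 1000 m
  cap honoured in local mode only. With the neighbor cap active, the
  nearest max_neighbors points are used; distance ties break toward the
  lower point index, so output is deterministic. Fewer than min_neighbors
  available is a logged warning, not an error; zero admissible neighbors
  masks the cell.
* When the full training set fits within the neighbor cap, the kriging
  matrix is LU-factorised once and reused across all grid cells; this path
  and the per-cell path produce identical results on the same neighbor
  sets, and local mode with unconstraining parameters is bit-identical to
  global mode.
* Grid registration: cell-center evaluation, row 0 at the north edge,
  bounds = study-area envelope padded up to a whole number of pixels.
  Default pixel 1.5 m, the size typical for harvester-density data.
* Duplicate coordinates are merged at read time by averaging (within one
  treatment only — overlaid identical point sets under different labels are
  a legitimate null-experiment design), because exact duplicates make the
  kriging matrix singular.

## Pipeline

* Holdout: seeded permutation split per treatment; train size
  round(0.8·n) with ties rounding up and at least one test point. The same
  seed is applied to every treatment's split, so identical point sets under
  two labels traverse identical stages — the basis of the package's
  null-experiment guarantee (gain ≡ 0).
* The residual variogram is refitted to the residuals with the same model
  family as the base fit. If that fit is degenerate (e.g. all residuals
  equal → empirical variogram ≡ 0, which would make the kriging system
  singular) the pipeline falls back to a nugget-only model with
  c0 = max(var(residuals), 1e-12).
* `PipelineConfig.fixed_variogram` bypasses fitting entirely and uses one
  preset model for both base and residual kriging — useful when the
  variogram is known from prior work, and required for exactness checks
  (a *fitted* nugget is never exactly zero).
* Gains are computed reference-vs-each-other-treatment ((k−1) surfaces);
  `all_pairs=True` enumerates every ordered pair. Kriging runs over the
  area envelope and clipping happens after summation.
* Gain statistics use the population standard deviation (divisor n) over
  valid cells.

## Evaluation

RMSE% normalises the root-mean-square error by the observed mean, so values
are comparable across crops and units; Pearson's r measures linear
agreement. Evaluation points falling on masked cells or off-grid are
dropped and `n` reports the usable count. Points take the value of their
containing cell (half-open in x, top-edge-inclusive in y); no inter-cell
interpolation.

## Synthetic trial generator

The generator emulates the structure of harvester-sampled strip trials:

* **Baseline field** — a Gaussian random field on the grid's cell centers
  with covariance C(h) = sill − γ(h), drawn by exact Cholesky factorisation
  with a 1e-8·sill diagonal jitter. Exactness limits grids to ~10⁴ cells;
  the factor is cached across seeds. The unbounded linear variogram has no
  positive-definite truncation in 2-D, so it is simulated through a
  spherical surrogate with range equal to the grid diameter D and partial
  sill b·D/1.5 (matching the near-origin slope).
* **Strips** — parallel strips of configurable width tile the rectangle;
  interleaved layouts cycle T1…Tk, the continuous layout (2 treatments)
  halves the field.
* **Sampling** — points on regular tracks (defaults 4 m along × 5 m
  across), giving ≈500 samples/ha on the default 2.4 ha field — inside the
  418–1122 samples/ha band of real combine yield monitors. Value =
  baseline at the point's cell + treatment effect + N(0, noise_sd);
  an optional dropout fraction emulates planting-line faults.
* **Default conditions** — 200 m × 120 m field, 2 m pixel, spherical
  variogram with nugget 4,000 (kg/ha)², partial sill 40,000 (kg/ha)²
  (sd 200 kg/ha = 4% of the mean), range 40 m, baseline mean 5,000 kg/ha,
  noise 100 kg/ha (2%), 20 m strips.

What the generator does *not* emulate: harvester positional error, strip
edge effects (border rows), anisotropy along the driving direction, trends,
and non-Gaussian yield distributions. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not robustness to every artefact of real yield data.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale problems chosen to exercise every
code path with comfortable margins: 60×60-cell grids, 200–1200 samples per
trial, 5–10 replicate seeds for stochastic checks. Effect recovery of a
+300 kg/ha treatment effect is asserted within ±10% of the truth averaged
over seeds; variogram recovery from 800-point simulated fields within ±20%
(sill) and ±30% (range) on the 5-seed average.

Degenerate inputs are rejected early with typed errors (coincident points,
geographic CRS where metric is required, all-masked rasters, constant
vectors in Pearson's r). Rasters are written as float64 GeoTIFF with
nodata −9999 so that a write→read round trip is bit-exact; the in-memory
representation keeps an explicit boolean mask instead of sentinel values.
Coordinate transforms (WGS84 ↔ UTM) use the Krüger series to order n⁶,
sub-millimetre accurate across a UTM zone and cross-checked in the tests
against an independent Snyder-series implementation.

## Known limitations

* Only WGS84-family geographic coordinates and WGS84/UTM projected zones
  are transformable natively; data in other projected CRSs can be used
  as-is but not reprojected.
* No universal/regression kriging, co-kriging, or anisotropy.
* The kriging variance is computed per point but not exported as a surface.
* Shapefile input is not supported; use GeoJSON or CSV.
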