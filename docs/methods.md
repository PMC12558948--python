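# Methods

This note records the models implemented in `bamboocarbon`, the choices
made where the design was genuinely open, and what the synthetic test bed
does and does not demonstrate.

## Allometry

Per-culm above-ground biomass is a power law `w = a·DBH^b` per component
(culm 0.145/2.4197, branch 0.0224/2.5286, leaf 0.0196/1.917), with DBH in
cm and biomass in kg per culm — units follow the bamboo allometry
literature; the equations themselves are dimensionally opaque, so the unit
convention is asserted here once. Carbon fractions are 0.45 (culm), 0.45
(branch) and 0.43 (leaf). Plot AGC density is `Σ carbon / area`, reported
in Mg/ha.

Two conventions are exposed deliberately:

* `plot_area(radius, pi_decimals)` — inventory sheets often print the
  12.5 m plot as 490.63 m², which presumes π ≈ 3.14; the default is full
  precision (490.87 m²) with the rounded convention available.
* `plot_agc_density(..., mean_tree=True)` — the "representative mean tree"
  shortcut (one culm at quadratic-mean DBH scaled by culm count) versus the
  default full-list summation. Field protocols differ; both paths are
  provided and tested.
* `summarize_agc` uses the n−1 (sample) standard deviation; a single plot
  reports sd = 0.

## Partial thin-plate smoothing spline

The interpolation model for a LiDAR parameter z at footprint location x
with covariate y (elevation) is `z_i = f(x_i) + bᵀy_i + e_i`, minimising

    Σ [(z_i − f(x_i) − bᵀy_i) / w_i]² + p · J_m(f).

Implementation choices:

* **Basis.** For d = 2 and order m the minimiser is a radial expansion in
  the polyharmonic kernel `(−1)^m r^(2m−2) log r` plus a polynomial null
  space of total degree ≤ m−1 (dimension 3/6/10 for m = 2/3/4) and the
  covariate as one extra linear column. The `(−1)^m` factor is the sign of
  the conditionally positive definite kernel in two dimensions; without it
  the roughness form is indefinite for odd m and the influence matrix
  ceases to be a shrinkage operator (this is observable: its trace drops
  below the null-space dimension and eigenvalues leave [0, 1]).
* **System.** All data points are knots (target N is a few thousand at
  most). The bordered system `(K + pW²)c + Td = z`, `Tᵀc = 0` is solved
  densely; the residual identity `z − ẑ = pW²c` gives fitted values and
  the top-left block C of the bordered inverse gives
  `tr(A) = N − p·Σ w_i² C_ii`.
* **Conditioning guard.** `tr(A)` must lie in `[k, N]` (k = number of
  unpenalized columns, since A has k unit eigenvalues and the rest in
  [0, 1]). A trace outside that interval flags an untrustworthy solve at
  that smoothing parameter; such p values are excluded from the GCV search
  and raise if requested directly. Coordinates are standardised (centred,
  scaled by their joint range) and covariates z-scored before basis
  evaluation.
* **GCV search.** 17-point log₁₀ grid over p ∈ [1e−8, 1e4], refined by
  golden-section to relative tolerance 1e−3 in log space. A minimum pinned
  to the bracket boundary (or an entirely infeasible bracket) sets the
  failure flag (`star_flag`) on the fit — the analogue of the `*` marker
  classical surface-fitting software writes to its error log.
* **Diagnostics.** Signal = tr(A), Error = N − tr(A) (the two sum to N by
  construction), SNR = Signal/Error, MSR = weighted RSS/N,
  VAR = weighted RSS/(N − tr A), GCV = MSR/(Error/N)²; RT• = √•. VAR's
  denominator (residual degrees of freedom) is chosen to satisfy the
  √-relations visible in published diagnostic tables. When the published
  per-order diagnostic rows are replayed through the order-selection rule,
  the SNR column is taken as printed: for one parameter (asr) the printed
  SNRs are not Signal/Error of the same rows, and for h_max_canopy_abs the
  order-3 SNR cell is off by 0.004 — the package computes SNR =
  Signal/Error for its own fits and does not emulate those inconsistencies.
* **Order selection.** Discard candidates with the failure flag or with
  Signal ≥ N/2 (surface more complex than the data can support); among the
  rest choose minimal SNR, ties to the lowest order.
* **Weights** default to 1 (no heteroscedasticity information in the data
  model); duplicate coordinates are averaged before fitting with weight
  w/√n, the standard error of a group mean, because the system is singular
  otherwise.
* **Prediction standard error** is `√(VAR · A_ii)`, the pointwise Bayesian
  error of a smoothing spline at a data point. It understates wall-to-wall
  prediction error away from the data — acceptable here because it is used
  only for the standardized-error and ASE columns of the cross-validation
  comparison.

## Co-kriging

The geostatistical benchmark is ordinary co-kriging with elevation as the
single co-located secondary variable.

* The empirical (cross-)semivariogram uses `γ(h) = (1/2N(h)) Σ (Δa·Δb)`
  in 12 equal-width lags to half the maximum pairwise distance (both
  configurable; no canonical values exist).
* Models: Spherical, Exponential, Gaussian with `γ(h) = C0 + C·g(h/a)`;
  the Gaussian range convention is `exp(−h²/a²)` (practical range √3·a).
  Fits are N(h)-weighted least squares with C0, C ≥ 0 bounds, so
  negative-sill candidates surface as fit failures rather than invalid
  models. The best model maximises R² (tie → minimal RSS).
* The linear model of coregionalisation is kept minimal: secondary and
  cross structures share the primary's model type and range, leaving only
  their nugget and partial sill free. Cross sills are projected onto
  `|b₁₂| ≤ √(b₁₁b₂₂)` with a warning when the empirical fit violates
  positive semi-definiteness.
* The per-target system uses the 16 nearest data points (configurable)
  with the two unbiasedness constraints (primary weights sum to 1,
  secondary to 0); a singular neighbourhood is retried once with a doubled
  neighbourhood. Nugget ratios `100·C0/(C0+C)` classify autocorrelation:
  < 25 % strong, 25–75 % moderate, > 75 % weak.

## Interpolator cross-validation

Leave-one-out throughout. For the spline, the smoothing parameter is
selected once by GCV on the full data and held fixed across folds
(re-searching per fold multiplies cost by the search length and changes
results negligibly on smooth fields); for co-kriging, variogram models are
fitted once and each fold re-solves the kriging system. "MSE" is the mean
*standardized* error `mean((pred−obs)/se)` — the GIS cross-validation
vocabulary, which is signed — not mean squared error. Method comparison
flags, per variable, the smaller |ME|, smaller RMSE and smaller |ASE−RMSE|;
the overall winner takes the majority of flags.

## Regression models

Shipped hyperparameter defaults are the grid-search optima of the study
design: LightGBM (num_leaves 20, max_depth 5, learning_rate 0.1, 100
rounds), random forest (mtry 9, ntree 200), XGBoost (45 rounds, max_depth
3, eta 0.1). Conventions chosen where the design was open:

* Ten-fold cross-validation assigns folds by a seeded random permutation
  without stratification; R² is computed on pooled out-of-fold predictions
  (not averaged per fold). P = 100 − rRMSE by definition.
* %IncMSE uses the standard OOB permutation definition: per tree, the
  increase in out-of-bag MSE after permuting one predictor; the score is
  the mean increase divided by its standard error across trees, ×100
  (zero when the increase never varies). The importance forest is a
  hand-rolled bagging loop over decision trees so the per-tree OOB index
  bookkeeping is explicit; model *fits* go through the libraries.
* Progressive selection adds variables in importance order and picks the
  RMSE-minimal prefix (ties to fewer variables); a one-standard-error
  variant exists but is off by default.
* Mapped predictions are clipped at zero (tree ensembles can extrapolate
  slightly negative); the clip count is logged.

## Synthetic scenes

The generator emulates the statistical structure of a real campaign — it
is the test bed, not a simulator of any physical instrument:

* Smooth fields are sums of eight seeded Gaussian bumps (differentiable,
  matching the spline's smoothness assumptions, cheap to evaluate),
  standardised and scaled. The DEM spans 450–1800 m by default, the
  elevation band the species occupies.
* Each of the nine parameter fields is
  `intercept + amplitude·smooth + elev_coeff·elevation` — exactly the
  partial-spline data model — with nugget noise added only when footprints
  sample the field. Default levels follow typical full-waveform /
  photon-counting value ranges over dense subtropical bamboo (cover ≈ 0.6,
  pai ≈ 3, canopy heights 15–24 m, nugget sd 5–10 % of field sd); the true
  spatial covariance of the real fields is unpublished, so ranges and
  sills are free parameters documented in the config defaults.
* Footprints lie on parallel ground tracks (azimuth 15°, 60 m along-track
  spacing, 12 tracks on the default 2.5 km scene, alternating sensor
  labels), reproducing the striping geometry that makes track data hard to
  interpolate; a jitter option (off by default) breaks the regularity.
* AGC truth is `−30 + 40·cover + 6·pai + 1.5·h_canopy_abs + smooth noise`,
  clipped at zero — a stated linear target so supervised recovery is
  well-defined. Defaults give mean ≈ 42 Mg/ha with plot-level values
  spanning roughly 5–100 Mg/ha, matching the inventory scale of the
  51-plot default.
* Plot inventories draw log-normal DBH (μ = log 12 cm, σ = 0.25) and scale
  the culm count so allometric plot carbon matches the AGC field at the
  plot centre, leaving only culm-sampling noise.

What passing tests on these scenes show: the estimators recover known
structure under the model's own assumptions (smooth fields, linear
elevation link, additive nugget, linear AGC target). What they do not
show: robustness to the pathologies of real campaigns — geolocation error,
non-Gaussian waveform noise, canopy-density-dependent sensitivity,
saturation, species mixtures, or plots mislocated relative to footprints.
Published real-data accuracy figures are therefore used only for
arithmetic-identity checks, never as synthetic targets.

## Problem sizes

Default test and demonstration scenes use a 2.5 km × 2.5 km extent at 25 m
cells (100×100 grid), ~360 footprints and 51 plots; the spline system at
that size solves densely in well under a second per GCV evaluation, and the
full end-to-end chain (nine surfaces, ten-fold CV over three model
families) completes in seconds per seed. Larger extents scale as N³ in the
footprint count for the spline and as the cell count for kriging.

## Known limitations

* One covariate (elevation); no aspect/slope terms, no d > 2 splines, and
  no knot thinning for very large N.
* No universal kriging, no more than one secondary variable, no sequential
  simulation.
* The spline standard error is a training-point quantity; kriging standard
  errors and spline ASE are therefore not strictly comparable calibrations,
  only the published comparison convention.
* File formats are deliberately plain (ASCII grid, CSV); no GeoTIFF/HDF5
  ingestion — upstream sensor products are out of scope.
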