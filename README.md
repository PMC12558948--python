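# bamboocarbon

Above-ground carbon (AGC) estimation for giant bamboo (*Dendrocalamus
giganteus*) stands from spaceborne-LiDAR footprint parameters.

Spaceborne LiDAR (full-waveform GEDI, photon-counting ICESat-2/ATLAS)
samples forest structure only along discrete ground tracks. Turning those
footprints into a wall-to-wall carbon map takes four steps, and this package
implements all of them as a tested, reusable library:

1. **Plot carbon from allometry.** Per-culm biomass follows power laws of
   DBH (cm): culm `w = 0.145·DBH^2.4197`, branch `w = 0.0224·DBH^2.5286`,
   leaf `w = 0.0196·DBH^1.917` (kg). Carbon applies component fractions
   0.45/0.45/0.43, and plot AGC density (Mg/ha) scales summed culm carbon
   by the plot area.
2. **Footprint-to-surface interpolation.** The workhorse is a *partial
   thin-plate smoothing spline* with elevation as a linear covariate,

   `z_i = f(x_i) + bᵀy_i + e_i`,

   minimising `Σ[(z_i − f(x_i) − bᵀy_i)/w_i]² + p·J_m(f)` with the order-m
   roughness penalty. The smoothing parameter p is chosen by generalized
   cross-validation, `GCV = (‖W⁻¹(I−A)z‖²/N) / [tr(I−A)/N]²`, and the fit is
   summarised with the classic surface-fitting diagnostics Signal = tr(A),
   Error = N − tr(A), SNR = Signal/Error, MSR, VAR and their square roots.
   The spline order (2, 3 or 4) is selected by the rule: discard fits that
   carry the failure flag or whose Signal exceeds half the observation
   count, then take the minimal SNR. Ordinary co-kriging with fitted
   nugget/sill/range variogram models (Gaussian, Spherical, Exponential)
   is provided as the geostatistical benchmark, and both interpolators are
   compared by leave-one-out cross-validation (ME, RMSE, standardized MSE,
   ASE).
3. **Regression modelling.** Interpolated surfaces are sampled at plot
   centres; predictors are ranked by random-forest out-of-bag permutation
   importance (%IncMSE) and a prefix is chosen by progressive addition
   against cross-validated RMSE. Three families are compared by ten-fold
   cross-validation — LightGBM, random forest, XGBoost — with
   `R² = 1 − SSE/SST`, RMSE, `rRMSE = 100·RMSE/mean(obs)` and overall
   estimation accuracy `P = 100 − rRMSE`.
4. **Mapping.** The best model predicts AGC per pixel over the predictor
   surfaces; the zonal summary reports min/mean/max density and total stock
   (pixel area 0.0625 ha at 25 m cells).

Because the underlying satellite and field campaign data are not publicly
deposited, the package ships a first-class **synthetic scene generator**
(`bamboocarbon.scene`) that reproduces the statistical structure the
analysis assumes — a smooth DEM, nine parameter fields with elevation
dependence, footprints on parallel ground tracks (striping included), and
plot inventories whose allometric carbon tracks a known AGC truth field —
so every stage is testable end-to-end from a single seed.

## Worked example

`examples/03_carbon_mapping.py` runs the full chain on the default
synthetic scene (2.5 km × 2.5 km, 51 plots, seed 1):

```
interpolated 9 parameter surfaces from 358 footprints
top predictors by %IncMSE: h_canopy_abs, pai, cover
lightgbm  R2= 0.59  RMSE= 7.21 Mg/ha  P=83.83%  rRMSE=16.17%
rfr       R2= 0.77  RMSE= 5.39 Mg/ha  P=87.92%  rRMSE=12.08%
xgboost   R2= 0.78  RMSE= 5.36 Mg/ha  P=87.97%  rRMSE=12.03%
best family: xgboost (+30.5% R2 over lightgbm)
mapped AGC: mean 41.6 Mg/ha (range 19.8-59.8), total 26,002 Mg over 625 ha
scene truth mean for comparison: 42.2 Mg/ha
```

The three model rows are pooled out-of-fold scores: XGBoost recovers the
planted AGC signal best, and the mapped mean (41.6 Mg/ha) sits within one
Mg/ha of the scene's ground truth (42.2 Mg/ha). `examples/01_plot_carbon.py`
shows the allometric step alone and `examples/02_surface_fitting.py` the
spline-order selection and the spline-versus-co-kriging comparison.

A thin CLI drives the same pipeline from a YAML file
(`simulate`, `sample`, `interp-tps`, `interp-ck`, `validate`, `select`,
`fit`, `map`, `report`, `run-all`):

```sh
bamboocarbon run-all --config examples/pipeline.yaml
```

Rasters are exchanged as plain-text ESRI ASCII grids (`.asc`, nodata
−9999), tables as CSV with embedded config-hash/seed metadata lines.

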