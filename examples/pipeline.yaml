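# Full pipeline configuration for the `bamboocarbon` CLI.
# Run:  bamboocarbon run-all --config examples/pipeline.yaml
seed: 5
out_dir: bamboocarbon_run
scene:
  extent: [0.0, 0.0, 1200.0, 1200.0]
  n_tracks: 8
  along_track_spacing: 60.0
  n_plots: 25
  # three-parameter subset keeps the demonstration quick; omit `parameters`
  # entirely to simulate all nine predictors with their defaults
  parameters:
    cover:        {intercept: 0.49,  amplitude: 0.12, elev_coeff: 1.0e-4, nugget_sd: 0.03}
    pai:          {intercept: 2.40,  amplitude: 0.80, elev_coeff: 5.0e-4, nugget_sd: 0.15}
    h_canopy_abs: {intercept: 17.75, amplitude: 4.00, elev_coeff: 2.0e-3, nugget_sd: 0.50}
  agc_coeffs: {intercept: -10.0, cover: 40.0, pai: 6.0, h_canopy_abs: 1.5}
sampling:
  interval: 1          # synthetic tracks are already sparse
spline:
  orders: [2, 3, 4]
kriging:
  n_lags: 12
  neighborhood: 16
model:
  families: [lightgbm, rfr, xgboost]
  n_folds: 5
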