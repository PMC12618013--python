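{
 "description": "Generative parameters of the synthetic behavioral model. Slopes and the confidence-error coupling are the fitted group-level values from the tactile intruder experiment; intercepts and noise terms are free defaults chosen to keep error probabilities inside (0,1) and confidence inside [1,10] across all complexity ranks.",
 "blind": {
  "label": "blind",
  "n_subjects": 9,
  "error_intercept": 0.05,
  "error_slope_per_rank": 0.041,
  "subject_sd": 0.03,
  "conf_intercept": 9.0,
  "conf_slope_per_rank": -0.24,
  "conf_error_coupling": -5.8,
  "conf_noise_sd": 1.0
 },
 "blindfolded": {
  "label": "blindfolded",
  "n_subjects": 13,
  "error_intercept": 0.30,
  "error_slope_per_rank": 0.012,
  "subject_sd": 0.06,
  "conf_intercept": 8.5,
  "conf_slope_per_rank": -0.052,
  "conf_error_coupling": -5.8,
  "conf_noise_sd": 1.0
 },
 "model_weights": {
  "symbolic_beta_std": 0.51,
  "cnn_beta_std": 0.28
 }
}
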