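{
  "descriptor_names": ["IC5", "GATS5e", "DISPp", "HATS3u"],
  "coefficients": [-2.89, 1.01, -3.17, -12.99],
  "intercept": 27.13,
  "n_train": 29,
  "training_stats": {
    "r2": 0.760,
    "q2_loo": 0.656,
    "q2_lmo": 0.662,
    "q2_f1": 0.739,
    "q2_f2": 0.731,
    "q2_f3": 0.876,
    "ccc": 0.891,
    "rmse_train": 0.226,
    "rmse_prediction": 0.270
  }
}
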