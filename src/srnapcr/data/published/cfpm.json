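{
  "name": "CF-PM",
  "description": "Clinical-factor predictive model for pathologic complete response: overall clinical complete response, %-decrease in SUVmax, post-treatment CEA, post-treatment biopsy.",
  "version": "1",
  "intercept": -0.02913,
  "coefficients": {
    "overall_cCR": 0.478113,
    "pct_delta_suvmax": 0.017915,
    "post_CEA": -0.51754,
    "biopsy_positive": -1.83105
  },
  "predictor_kinds": {
    "overall_cCR": "binary",
    "pct_delta_suvmax": "continuous",
    "post_CEA": "continuous",
    "biopsy_positive": "binary"
  },
  "reported_cutoff": 0.074
}
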