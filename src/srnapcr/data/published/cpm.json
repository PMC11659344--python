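{
  "name": "C-PM",
  "description": "Combined predictive model for pathologic complete response: four clinical factors plus three serum small-RNA features.",
  "version": "1",
  "intercept": -1.20176,
  "coefficients": {
    "overall_cCR": 0.30144,
    "pct_delta_suvmax": 0.011833,
    "let7b_isomir": 0.003975,
    "tsrna_gly_group": 0.002576,
    "mir93_isomir": 0.000149,
    "post_CEA": -0.44751,
    "biopsy_positive": -2.43116
  },
  "predictor_kinds": {
    "overall_cCR": "binary",
    "pct_delta_suvmax": "continuous",
    "let7b_isomir": "continuous",
    "tsrna_gly_group": "continuous",
    "mir93_isomir": "continuous",
    "post_CEA": "continuous",
    "biopsy_positive": "binary"
  },
  "reported_cutoff": -0.589
}
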