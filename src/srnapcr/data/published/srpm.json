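{
  "name": "SR-PM",
  "description": "Small-RNA predictive model for pathologic complete response: linear score over three serum small-RNA features (normalized reads per million).",
  "version": "1",
  "intercept": -1.7445,
  "coefficients": {
    "let7b_isomir": 0.003717,
    "tsrna_gly_group": 0.003414,
    "mir93_isomir": 0.000343
  },
  "predictor_kinds": {
    "let7b_isomir": "continuous",
    "tsrna_gly_group": "continuous",
    "mir93_isomir": "continuous"
  },
  "reported_cutoff": -0.112
}
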