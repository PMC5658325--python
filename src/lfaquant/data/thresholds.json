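{
  "threshold_sets": {
    "endocrine_society": {
      "deficient_below": 50.0,
      "sufficient_above": 75.0,
      "note": "25(OH)D < 50 nmol/L deficient, 50-75 insufficient, > 75 sufficient"
    }
  },
  "binary_cutoffs": {
    "iom_50": 50.0,
    "iom_30": 30.0
  }
}
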