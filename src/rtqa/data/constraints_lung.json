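{
  "source_label": "rtqa illustrative lung constraint set (placeholder values, not a clinical protocol)",
  "constraints": [
    {"structure": "Lungs", "metric": "V20Gy", "comparator": "LE", "pass_limit": 35.0, "variation_limit": 37.0},
    {"structure": "Lungs", "metric": "Dmean", "comparator": "LE", "pass_limit": 20.0, "variation_limit": 21.0},
    {"structure": "SpinalCord", "metric": "Dmax", "comparator": "LE", "pass_limit": 45.0, "variation_limit": 50.0},
    {"structure": "Esophagus", "metric": "Dmean", "comparator": "LE", "pass_limit": 34.0, "variation_limit": null},
    {"structure": "Heart", "metric": "V40Gy", "comparator": "LE", "pass_limit": 35.0, "variation_limit": 40.0},
    {"structure": "PTV", "metric": "D95%", "comparator": "GE", "pass_limit": 57.0, "variation_limit": 54.0}
  ]
}
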