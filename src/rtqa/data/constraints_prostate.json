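{
  "source_label": "rtqa illustrative prostate constraint set (placeholder values, not a clinical protocol)",
  "constraints": [
    {"structure": "Rectum", "metric": "V70Gy", "comparator": "LE", "pass_limit": 25.0, "variation_limit": 30.0},
    {"structure": "Rectum", "metric": "V65Gy", "comparator": "LE", "pass_limit": 35.0, "variation_limit": 40.0},
    {"structure": "Bladder", "metric": "V70Gy", "comparator": "LE", "pass_limit": 30.0, "variation_limit": 35.0},
    {"structure": "Bladder", "metric": "V65Gy", "comparator": "LE", "pass_limit": 40.0, "variation_limit": 50.0},
    {"structure": "Femur_Head_L", "metric": "Dmax", "comparator": "LE", "pass_limit": 50.0, "variation_limit": 52.0},
    {"structure": "Femur_Head_R", "metric": "Dmax", "comparator": "LE", "pass_limit": 50.0, "variation_limit": 52.0},
    {"structure": "PTV", "metric": "D95%", "comparator": "GE", "pass_limit": 74.1, "variation_limit": 70.2},
    {"structure": "PTV", "metric": "Dmax", "comparator": "LE", "pass_limit": 83.5, "variation_limit": 85.8}
  ]
}
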