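{
  "version": "NCCN clinically-localized prostate, three-tier, v1",
  "t_order": ["T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4"],
  "high": {"t_min": "T3a", "gleason_sum_min": 8, "psa_gt": 20},
  "low": {"t_max": "T2a", "gleason_sum_max": 6, "psa_lt": 10}
}
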