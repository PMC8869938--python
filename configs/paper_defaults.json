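{
  "n_patients": 293,
  "mode": "group_anchored",
  "group_scheme": "c2020",
  "accrual_months": 144.0,
  "followup_cutoff_months": 147.0,
  "post_relapse_median_months": 24.0,
  "seed": 0
}
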