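# Four-dose TiTE-CRM design: 24-week DLT window, 25% target toxicity level.
design:
  skeleton: [0.05, 0.12, 0.22, 0.35]
  ttl: 0.25
  dlt_window: 168
  n_max: 21
  prior_mean: 0.0
  prior_sd: 1.34
  mtd_rule: highest_below
  starting_dose_index: 1
weights:
  kind: linear
rules:
  no_skip: true
  initial_cohort_size: 3
  min_exposed_participants: 3
  min_exposure_days: 91
  safety_stop_enabled: true
  safety_stop_threshold: 0.9
partial_treatment:
  enabled: false
  threshold: 0.8
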