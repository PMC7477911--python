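# Variant with a 1-year DLT window and the piecewise weight scheme used when
# acute (e.g. haematological) and late (e.g. pneumonitis) toxicities are
# expected in roughly equal measure: the first 3 months carry half the total
# weight.  The partial-treatment rule reduces the weighting of DLT-free
# participants who received less than 80% of the planned drug.
design:
  skeleton: [0.05, 0.12, 0.22, 0.35]
  ttl: 0.25
  dlt_window: 365
  n_max: 21
weights:
  kind: piecewise
  segments:
    - [91, 0.5]
    - [274, 0.5]
partial_treatment:
  enabled: true
  threshold: 0.8
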