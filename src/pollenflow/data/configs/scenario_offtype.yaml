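# Scenario: within-row off-type trees plus strongly along-row foraging.
# Both orchards pooled; off-type replacement trees (10% of trees) are the
# dominant, distance-independent cross-pollen source, while row switching
# is rare, so cross-pollen carriage is substantial at every row distance
# and the distance effect is near zero.  Netting jitter spreads each
# sampling point's bees over neighbouring trees along the row.
orchards:
  - preset: wide
    offtype_rate: 0.10
    offtype_pool: ["741", "849"]
  - preset: narrow
    offtype_rate: 0.10
    offtype_pool: ["741", "849"]
bees_per_point: 6
foraging:
  p_row_switch: 0.05
  n_visits: 30
  carryover_retention: 0.8
  pickup_grains: 1.0
  capture_visit: uniform
  capture_jitter_sd: 10
assay:
  theta_detect: 0.02
  fn_rate: 0.01
  fp_rate: 0.001
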