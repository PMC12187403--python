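# Wide-block study design: two wide single-cultivar blocks (42 rows of 816
# beside 48 rows of Daddow), 8 transects at rows 1/2/3/11 from the block
# boundary, 6 bees per sampling point.  A small rate of off-type
# replacement trees stands in for the storm-damage replacements.
orchards:
  - preset: wide
    offtype_rate: 0.01
    offtype_pool: ["741", "849"]
bees_per_point: 6
foraging:
  p_row_switch: 0.1
  n_visits: 30
  carryover_retention: 0.7
  pickup_grains: 1.0
  capture_visit: uniform
  capture_jitter_sd: 10
assay:
  theta_detect: 0.02
  fn_rate: 0.01
  fp_rate: 0.001
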