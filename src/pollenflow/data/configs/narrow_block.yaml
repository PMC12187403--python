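# Narrow-block study design: five-row single-cultivar blocks
# (A203 | 842 | 816 | A4 | 741), 4 transects on 816 hosts and 3 on A4
# hosts at rows 1-4, 6 bees per sampling point.
orchards:
  - preset: narrow
    offtype_rate: 0.01
    offtype_pool: ["849"]
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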