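# Demo: full synthetic run with validation enabled.
#   dasypop run-all --config examples/synthetic_demo.yaml --out demo_output
seed: 7
region:
  n_counties: 2
  blocks_per_county: 100
  n_persons: 5000
  census_years: [1990, 2000, 2010, 2020]
  placement_bias: 0.7
z_thresholds: [1.0]
methods: [uniform, building]
bfe_m: 2.0
emigration_flag_pct: 1.0
validate: true
log_level: INFO
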