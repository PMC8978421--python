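# Example experiment configuration for `rddframes <subcommand> --config`.
# Any omitted key falls back to the package defaults (50,000 persons,
# 4,000 landline + 6,000 cell numbers dialed, joint sex-by-age raking).
population:
  population_size: 20000
fieldwork:
  n_landline: 2000
  n_cell: 3000
  max_call_attempts: 12
nonworking_rate_ll: 0.50
nonworking_rate_cell: 0.33
margin_spec: joint        # or "marginal" to rake sex and age separately
subgroups:
  18-30: [18, 30]
  60-75: [60, 75]
output_dir: rddframes_output
seed: 2026
replicates: 20
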