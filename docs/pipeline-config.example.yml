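# Example configuration for `coturnix report --config <file>` /
# coturnix.reporting.run_pipeline. All keys optional; defaults shown.
seed: 20230526
mode: mechanistic          # direct | mechanistic
trait_pairs:               # bivariate runs, in order
  - [BW5, BW6]
  - [beta0, IPW]
n_iterations: 11000
burn_in: 1000
thin: 5
flock:                     # forwarded to FlockConfig
  n_sires: 40
  n_dams: 120
  n_offspring: 700
  feeder_group_var_frac: 0.2
  weight_noise_sd: 2.0
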