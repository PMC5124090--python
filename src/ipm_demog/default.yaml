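# Default run configuration (desk scale).
# Values here seed the CLI defaults; command-line options override them.
fit:
  chains: 4
  iterations: 20000
  burnin: 10000
  thin: 10
  sweeps: 10
simulate:
  years: 19
  nests_per_year: 150
  releases_per_year: 200
priors:
  brood_max: 10.0
  rho_max: 5.0
  sigma_scale: 1.0
surface:
  resolution: 50
  mode: expected
substitute:
  threshold: 1.0
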