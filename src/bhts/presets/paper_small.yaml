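# Desk-scale synthetic screen: 100 plates of 8x10 compound wells, 5% hits,
# default log-normal mixture constants, matrix-normal plate noise.
seed: 1
synthetic:
  n_plates: 100
  n_rows: 8
  n_cols: 10
  hit_fraction: 0.05
mcmc:
  n_iter: 3000
  burn_in: 1000
  thin: 2
fdr:
  target: 0.05
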