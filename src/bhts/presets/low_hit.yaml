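# Low-hit-rate scenario at reduced scale: 1250 plates x 80 wells = 1e5
# compounds with hit fraction 0.021% (21 true hits).
seed: 1
synthetic:
  n_plates: 1250
  n_rows: 8
  n_cols: 10
  hit_fraction: 0.00021
mcmc:
  n_iter: 1200
  burn_in: 400
  thin: 2
fdr:
  target: 0.05
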