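# bhts

Bayesian nonparametric hit identification for multi-plate high-throughput
compound screens.

The package fits a two-channel (active/inactive) hierarchical Dirichlet
process Gaussian mixture across all plates of a screen at once, using a
truncated stick-breaking blocked Gibbs sampler. Each plate carries local
mixture clusters that point at globally shared Gaussian atoms, so plates
selectively share statistical strength. The sampler yields a posterior hit
probability per compound well, from which hits are called at a target
Bayesian false discovery rate. Classical per-plate baselines (NPI, Z-score,
B-score via Tukey median polish, R-score via Huber IRLS), a synthetic
screen generator with matrix-normal row/column plate-effect noise, and
ROC/AUC evaluation utilities are included.

## Command-line pipeline

The `bhts` entry point chains five subcommands; all tabular artifacts are
CSV in a long format keyed by `plate_id,row,col`:

```bash
# 1. simulate a synthetic screen (truth labels included)
bhts simulate --config paper_small --out data.csv

# 2. classical per-plate scores (Z, B, R by default)
bhts score --in data.csv --out scores.csv

# 3. fit the Bayesian model -> posterior hit probabilities
bhts bhts --in data.csv --config paper_small --out probs.csv

# 4. call hits at a target Bayesian FDR
bhts call --in probs.csv --fdr 0.05 --out calls.csv

# 5. ROC/AUC tables against the truth column
bhts evaluate --in probs.csv --out-prefix eval
```

`--config` takes a YAML file or one of the bundled presets `paper_small`
(100 plates x 80 wells, 5% hits, 3000 iterations) and `low_hit`
(1e5 compounds, hit fraction 0.021%). Unknown configuration keys are
rejected by name. Every run logs its effective configuration, seed and
per-stage wall time to stderr; identical seeds reproduce outputs
byte-for-byte.

Input plate tables are CSVs with header
`plate_id,row,col,role,readout[,truth]`, 0-based row-major coordinates and
roles `compound`/`pos`/`neg`.

## Python API

```python
from bhts import (SyntheticSpec, simulate_screen, auto_hyperparameters,
                  run_sampler, select_threshold, roc)

ds = simulate_screen(SyntheticSpec(n_plates=100, hit_fraction=0.05, seed=1))
summary = run_sampler(ds, auto_hyperparameters(ds),
                      n_iter=3000, burn_in=1000, thin=2, seed=1)
calls = select_threshold(summary.hit_prob, target_fdr=0.05)
print(roc(summary.hit_prob, ds.truth).auc, calls.n_called)
```

`auto_hyperparameters` derives the prior mean anchors and the shared
inverse-gamma variance hyperparameters from the compound data (controls
are never used by the model); every constant can be overridden.

## Limitations

- Plates with missing wells are unsupported (B/R scores need a complete
  compound sub-grid).
- No variational or infinite-limit samplers; the truncation levels H and K
  are fixed configuration.
- No plotting; outputs are plot-ready CSV.
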