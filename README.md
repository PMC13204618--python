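# milsurv

Attention-based multiple-instance (MIL) and patch-level Cox survival
modelling on whole-slide patch-embedding bags, together with a synthetic
cohort generator and a complete survival-evaluation layer. Everything runs
on one CPU with numpy — the neural components (gated-attention MIL pooling,
per-patch MLP scorer, tissue-QC CNN) use hand-written gradients.

## What's inside

| module | contents |
| --- | --- |
| `milsurv.synthetic` | slide bags as Gaussian patch archetypes (low/high-grade tumor, necrosis, fibrosis, normal, artifact); latent grade drives a proportional-hazards log-hazard; exponential event/censor times; affine cross-cohort domain shift; QC tile fixtures; HDF5/CSV/YAML serialization |
| `milsurv.prep` | tile-grid geometry, tumor-area exclusion (3.24 mm² ↔ 100 patches of 360 px at 0.5 µm/px), all-tissue vs tumor-only patch selection, tissue/non-tissue QC CNN (12/24/24 filters, 5×5 kernels, 2×2 max pools) |
| `milsurv.mil` | Cox negative partial log-likelihood (Breslow ties, log-sum-exp stabilized), attention-MIL model (softmax attention → weighted-sum pooling → linear risk head), end-to-end training with early stopping, top-attention patch selection (top 10 %, capped at 200) |
| `milsurv.patch` | patch-level baseline: slide labels copied to every patch, instance-level Cox training, slide risk = mean patch risk |
| `milsurv.evaluate` | fold-wise z-scoring, Harrell's C, Kaplan–Meier curves, quantile stratification (25/50/75 %), binary-group Cox hazard ratios (safeguarded Newton), IPCW cumulative/dynamic AUC at 1/3/5-year horizons, bootstrap ΔC (1000 iterations, 95 % CI, p-value) |
| `milsurv.experiments` | 5-fold CV, cross-cohort transfer, combined-cohort training, visualization-case selection, attention-heatmap export, CLI |
| `milsurv.bench` | the fixed synthetic scenarios behind the acceptance checks |

## CLI

```bash
milsurv simulate --config cohort.yaml --seed 0 --out runs/cohort
milsurv qc --n 600 --seed 0 --out runs/qc
milsurv cv --cohort runs/cohort --paradigm mil --tissue all --folds 5 --seed 0 --out runs/cv
milsurv transfer --train runs/cohortA --test runs/cohortB --paradigm mil --out runs/tr --seed 0
milsurv combined --cohort runs/cohortA --cohort runs/cohortB --out runs/comb --seed 0
milsurv evaluate --predictions runs/cv/predictions.csv --survival runs/cohort/survival.csv --out runs/eval
milsurv heatmap --cohort runs/cohort --model mil.npz --slide synthetic-0001 --out runs/hm
```

Every run writes `manifest.json` (arguments + seed) next to its outputs;
prediction CSVs use the schema `slide_id,fold,risk_raw,risk_std` for both
paradigms, so the evaluation layer is paradigm-agnostic.

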