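# mixedae

Mixed-effects deep autoencoders for modeling — not just removing —
batch effects in single-cell RNA-seq.

Batch effects (donor, protocol, acquisition run) confound single-cell
analyses, and most correction methods simply discard them, losing
biology that rides along with the batch structure. `mixedae` instead
*decomposes* expression, in the spirit of a linear mixed model, into:

* a **fixed-effects** latent space: a weight-tied autoencoder trained
  against an adversarial batch classifier, minimizing
  `λ_recon·L_MSE(X, X̂) − λ_A·L_CCE(Z, Ẑ_A)`, so the embedding keeps
  what reconstructs expression but drops what predicts batch;
* a **random-effects** latent space: a Bayesian autoencoder whose
  dense blocks are rescaled and shifted per batch,
  `activation((1+γ(z))⊙d + b(z))`, with variational Gaussian posteriors
  over γ and b learned by minimizing
  `λ_recon·L_MSE + λ_L·L_CCE(Z, Ẑ_L) + λ_K·KL(q‖p)`.

Because the random-effects model is generative over batches, swapping a
cell's one-hot batch vector before decoding yields counterfactual
projections ("what would this cell look like from another donor?"),
which can be visualized as genomap images and tested per gene with
Mann-Whitney contrasts. Concatenating the two latents ("fusion") feeds
a Random-Forest harness that quantifies how much predictive signal
batch modeling preserves over batch removal. A negative-binomial
simulator with known cell-type and per-batch effects makes the whole
pipeline testable offline.

Intended users: computational biologists studying batch-confounded
scRNA-seq atlases, and methods developers who need a transparent,
dependency-light reference implementation (networks are dense NumPy
models trained by a small built-in reverse-mode autodiff engine — no
GPU or deep-learning framework required).

## Worked example

```python
import numpy as np
from mixedae import (SimConfig, simulate, PreprocessConfig, preprocess,
                     stratified_kfold, fit_standardizer, make_batch_design,
                     FixedEffectsAutoencoder, RandomEffectsAutoencoder,
                     separability_metrics, project_to_batch)

ds, truth = simulate(SimConfig(n_cells=900, n_genes=120, n_batches=4,
                               n_cell_types=3, seed=0))
pp = preprocess(ds, PreprocessConfig(min_counts_per_cell=100,
                                     min_cells_per_gene=3, n_hvg=100))
fold = stratified_kfold(pp, k=5, seed=0)[0]
scaler = fit_standardizer(pp, fold.train_cells)
X = scaler.transform(pp.counts)
design = make_batch_design(pp)

net = dict(encoder_sizes=(64, 32), latent_dim=2, learning_rate=1e-3,
           max_epochs=200, patience=25, batch_size=128, seed=0)
fe = FixedEffectsAutoencoder(lambda_a=90.0, **net)
fe.fit(X, design=design, train_idx=fold.train_cells, val_idx=fold.val_cells)
re = RandomEffectsAutoencoder(lambda_l=40.0, lambda_k=0.02, **net)
re.fit(X, design=design, train_idx=fold.train_cells, val_idx=fold.val_cells)

test = fold.test_cells
batch = pp.batch_labels[test]
ctype = pp.cell_type_labels[test]
print("FE batch ASW:", round(separability_metrics(fe.transform(X)[test], batch)["asw"], 3))
print("RE batch ASW:", round(separability_metrics(re.transform(X, design)[test], batch)["asw"], 3))
print("FE cell-type ASW:", round(separability_metrics(fe.transform(X)[test], ctype)["asw"], 3))

proj = project_to_batch(re, X[:5], "batch2")   # counterfactual: 5 cells in batch2
print("projection shape:", proj.shape)
```

Output:

```
FE batch ASW: -0.06
RE batch ASW: 0.302
FE cell-type ASW: 0.759
projection shape: (5, 100)
```

Read: the adversarially trained fixed-effects embedding shows
essentially no batch clustering (ASW ≈ −0.06; 0 is "indistinguishable")
while keeping the cell types well separated (ASW ≈ 0.76); the
random-effects embedding clusters strongly by batch (ASW ≈ 0.30), i.e.
it has captured the batch structure the fixed-effects model suppressed.
The projection matrix holds the five cells' expression as the model
believes it would appear had they been acquired in `batch2`.

The same experiment end to end, from the shell:

```bash
mixedae run-all --outdir runs/demo --seed 0          # full synthetic study
mixedae evaluate --config my_config.yaml --seed 1    # separability only
```

which writes tidy CSV reports (`separability.csv`, `classification.csv`,
`projection_contrast.csv`, …), genomap montages, and a JSON manifest
with per-stage checksums; reruns with the same config and seed are
byte-identical.

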