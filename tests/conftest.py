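"""Shared fixtures: small simulated datasets and compact trained models.

The "compact scenario" used by the slower tests is the package's
documented desk-scale study setting: 900 cells, 120 genes reduced to
100 highly variable ones, 4 batches x 3 cell types with strong batch
effects (sigma_gamma 0.3, sigma_b 0.5), (64, 32) -> 2 networks with
loss weights set by the balancing heuristic.
"""

from __future__ import annotations

import numpy as np
import pytest

from mixedae.data_model import make_batch_design, make_cell_type_labels, stratified_kfold
from mixedae.preprocessing import PreprocessConfig, fit_standardizer, preprocess
from mixedae.synthetic import SimConfig, simulate

COMPACT_NET = dict(encoder_sizes=(64, 32), latent_dim=2, learning_rate=1e-3,
                   max_epochs=200, patience=25, batch_size=128)
COMPACT_LAMBDA_A = 90.0
COMPACT_LAMBDA_L = 40.0
COMPACT_LAMBDA_K = 0.02


def compact_sim_config(seed: int, confounding: float = 0.0) -> SimConfig:
    return SimConfig(n_cells=900, n_genes=120, n_batches=4, n_cell_types=3,
                     sigma_gamma_true=0.3, sigma_b_true=0.5,
                     celltype_effect_sd=0.6, confounding=confounding, seed=seed)


def compact_prep_config() -> PreprocessConfig:
    return PreprocessConfig(min_counts_per_cell=100, min_cells_per_gene=3, n_hvg=100)


def prepare(seed: int, confounding: float = 0.0):
    """Simulate, preprocess, split and standardize the compact scenario."""
    ds, truth = simulate(compact_sim_config(seed, confounding))
    pp = preprocess(ds, compact_prep_config())
    folds = stratified_kfold(pp, k=5, seed=seed)
    fold = folds[0]
    scaler = fit_standardizer(pp, fold.train_cells)
    X = scaler.transform(pp.counts)
    design = make_batch_design(pp)
    return dict(dataset=pp, truth=truth, folds=folds, fold=fold,
                scaler=scaler, X=X, design=design)


@pytest.fixture(scope="session")
def tiny():
    """A small preprocessed dataset for fast unit tests (no training)."""
    ds, truth = simulate(SimConfig(n_cells=240, n_genes=60, n_batches=3,
                                   n_cell_types=2, seed=11))
    pp = preprocess(ds, PreprocessConfig(min_counts_per_cell=10,
                                         min_cells_per_gene=1, n_hvg=50))
    fold = stratified_kfold(pp, k=4, seed=11)[0]
    scaler = fit_standardizer(pp, fold.train_cells)
    return dict(raw=ds, truth=truth, dataset=pp, fold=fold, scaler=scaler,
                X=scaler.transform(pp.counts), design=make_batch_design(pp),
                labels=make_cell_type_labels(pp))


@pytest.fixture(scope="session")
def tiny_fe(tiny):
    """A quickly trained fixed-effects model on the tiny dataset."""
    from mixedae.fe import FixedEffectsAutoencoder

    model = FixedEffectsAutoencoder(encoder_sizes=(24, 12), latent_dim=2,
                                    lambda_a=10.0, learning_rate=1e-3,
                                    max_epochs=15, patience=10, batch_size=64,
                                    seed=3)
    model.fit(tiny["X"], design=tiny["design"],
              train_idx=tiny["fold"].train_cells, val_idx=tiny["fold"].val_cells)
    return model


@pytest.fixture(scope="session")
def tiny_re(tiny):
    """A quickly trained random-effects model on the tiny dataset."""
    from mixedae.re import RandomEffectsAutoencoder

    model = RandomEffectsAutoencoder(encoder_sizes=(24, 12), latent_dim=2,
                                     lambda_l=10.0, lambda_k=0.02,
                                     learning_rate=1e-3, max_epochs=15,
                                     patience=10, batch_size=64, seed=3)
    model.fit(tiny["X"], design=tiny["design"],
              train_idx=tiny["fold"].train_cells, val_idx=tiny["fold"].val_cells)
    return model
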