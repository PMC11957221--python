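"""Standard scRNA-seq preparation: filtering, normalization, log
transform, highly-variable-gene selection, and per-gene standardization.

The pipeline is deliberately spelled out rather than delegated, so its
contracts are exact and fold-aware: cell/gene filters on raw counts,
library-size normalization to ``target_sum``, ``log1p``, then the
``n_hvg`` most variable genes by mean-binned normalized dispersion
(the common single-cell recipe).  When a training index is given, gene
ranking uses only training cells, so test cells never influence gene
selection.  Standardization (:class:`GeneScaler`) uses the population
standard deviation, fit on training cells only.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .data_model import ExpressionDataset

__all__ = ["PreprocessConfig", "GeneScaler", "preprocess", "fit_standardizer"]


@dataclass
class PreprocessConfig:
    min_counts_per_cell: int = 500
    min_cells_per_gene: int = 3
    target_sum: float = 1e4
    n_hvg: int = 2916  # default square 54 x 54 genomap
    log_offset: float = 1.0
    n_dispersion_bins: int = 20

    def __post_init__(self):
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")


def _normalized_dispersion(normed: np.ndarray, n_bins: int) -> np.ndarray:
    """Dispersion (var/mean) z-scored within mean-quantile bins.

    Computed on the library-size-normalized (pre-log) matrix.  Genes
    with zero variance score ``-inf`` so a constant gene can never be
    ranked into the HVG set.
    """
    mean = normed.mean(axis=0)
    var = normed.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    n_bins = min(n_bins, max(1, len(mean)))
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    bins = np.searchsorted(quantiles[1:-1], mean, side="right")
    score = np.empty_like(disp)
    for b in np.unique(bins):
        members = bins == b
        mu, sd = disp[members].mean(), disp[members].std()
        score[members] = (disp[members] - mu) / sd if sd > 0 else 0.0
    score[var == 0] = -np.inf
    return score


def preprocess(dataset: ExpressionDataset, config: PreprocessConfig | None = None,
               train_cells: np.ndarray | None = None) -> ExpressionDataset:
    """Filter, normalize, log-transform and reduce to highly variable genes.

    Parameters
    ----------
    train_cells
        Optional index array (into the *input* dataset's rows) enabling
        fold-aware mode: HVG ranking statistics are computed on these
        cells only.  All cells are still returned.
    """
    config = config or PreprocessConfig()
    counts = dataset.counts

    cell_totals = counts.sum(axis=1)
    keep_cells = cell_totals >= config.min_counts_per_cell
    if not keep_cells.any():
        raise ValueError("all cells removed by min_counts_per_cell filter")
    kept_idx = np.flatnonzero(keep_cells)
    counts = counts[kept_idx]

    gene_cells = (counts > 0).sum(axis=0)
    keep_genes = gene_cells >= config.min_cells_per_gene
    counts = counts[:, keep_genes]
    gene_ids = [g for g, k in zip(dataset.gene_ids, keep_genes) if k]
    if counts.shape[1] == 0:
        raise ValueError("all genes removed by min_cells_per_gene filter")

    totals = counts.sum(axis=1, keepdims=True)
    normed = counts / totals * config.target_sum
    logged = np.log1p(normed) if config.log_offset == 1.0 \
        else np.log(normed + config.log_offset)

    if config.n_hvg > counts.shape[1]:
        raise ValueError(
            f"n_hvg={config.n_hvg} exceeds the {counts.shape[1]} genes that "
            f"survived filtering")
    if train_cells is not None:
        old_to_new = {int(o): i for i, o in enumerate(kept_idx)}
        rows = np.array([old_to_new[int(i)] for i in np.asarray(train_cells)
                         if int(i) in old_to_new], dtype=int)
        if len(rows) == 0:
            raise ValueError("no training cells survive filtering")
        score = _normalized_dispersion(normed[rows], config.n_dispersion_bins)
        score[counts[rows].var(axis=0) == 0] = -np.inf
    else:
        score = _normalized_dispersion(normed, config.n_dispersion_bins)
        score[counts.var(axis=0) == 0] = -np.inf
    # stable ranking: score descending, gene index ascending on ties
    order = np.lexsort((np.arange(len(score)), -score))
    hvg = np.sort(order[: config.n_hvg])

    meta = dict(dataset.meta)
    meta["preprocess"] = {**asdict(config),
                          "n_cells_removed": int((~keep_cells).sum()),
                          "n_genes_removed": int((~keep_genes).sum()),
                          "fold_aware": train_cells is not None}
    return ExpressionDataset(
        counts=logged[:, hvg],
        gene_ids=[gene_ids[i] for i in hvg],
        cell_ids=[dataset.cell_ids[i] for i in kept_idx],
        annotations=dataset.annotations.iloc[kept_idx],
        meta=meta,
    )


@dataclass
class GeneScaler:
    """Per-gene z-score parameters, fit on training cells only.

    Uses the population standard deviation; a zero standard deviation
    (constant gene on the training cells) is replaced by 1 so constant
    genes standardize to 0 rather than NaN.
    """

    means: np.ndarray
    sds: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.means):
            raise ValueError("gene count does not match scaler")
        return (X - self.means) / self.sds

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) * self.sds + self.means


def fit_standardizer(dataset: ExpressionDataset | np.ndarray,
                     train_cells: np.ndarray) -> GeneScaler:
    """Fit per-gene mean/sd on the given training cells."""
    X = dataset.counts if isinstance(dataset, ExpressionDataset) else np.asarray(dataset)
    train_cells = np.asarray(train_cells, dtype=int)
    if train_cells.size == 0:
        raise ValueError("train_cells is empty")
    Xt = X[train_cells]
    means = Xt.mean(axis=0)
    sds = Xt.std(axis=0)  # population sd
    sds = np.where(sds > 0, sds, 1.0)
    return GeneScaler(means=means, sds=sds)
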