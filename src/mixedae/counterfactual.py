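"""Counterfactual batch projection and projection contrasts.

The random-effects autoencoder is generative over batches: replacing a
cell's one-hot batch row with another batch's before decoding yields
the model's answer to "what would this cell's expression look like had
it been acquired in batch j?".  This module assembles standardized
projection panels (original rows, fixed-effects reconstructions, and
one projected row per target batch for each sampled cell) and runs
per-gene two-sided Mann-Whitney U contrasts between groups of
projections, reporting raw p-values (with a Benjamini-Hochberg
adjusted column always included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import BATCH_KEY, CELLTYPE_KEY, BatchDesign, ExpressionDataset
from .fe import FixedEffectsAutoencoder
from .re import RandomEffectsAutoencoder

__all__ = ["ProjectionPanel", "project_to_batch", "build_projection_panel",
           "projection_contrast"]


@dataclass
class ProjectionPanel:
    """Stacked projection matrix with row metadata and its scaling record.

    Rows hold, for each sampled cell: the original (standardized input)
    expression, optionally the fixed-effects reconstruction, and one
    random-effects projection per target batch.  The whole stack is
    standardized per gene over all rows jointly; ``row_means`` /
    ``row_sds`` record that transform.
    """

    matrix: np.ndarray
    metadata: pd.DataFrame  # columns: cell_id, source_batch, target
    gene_ids: list[str]
    row_means: np.ndarray = field(default=None)
    row_sds: np.ndarray = field(default=None)

    def rows_for(self, targets: set[str] | list[str]) -> np.ndarray:
        mask = self.metadata["target"].isin(list(targets)).to_numpy()
        return self.matrix[mask]

    def to_csv(self, path, sidecar_path=None) -> None:
        df = pd.DataFrame(self.matrix, columns=self.gene_ids)
        df.insert(0, "cell_id", self.metadata["cell_id"].to_numpy())
        df.insert(1, "source_batch", self.metadata["source_batch"].to_numpy())
        df.insert(2, "target", self.metadata["target"].to_numpy())
        df.to_csv(path, index=False)
        if sidecar_path is not None:
            import json

            with open(sidecar_path, "w") as fh:
                json.dump({"n_rows": int(self.matrix.shape[0]),
                           "genes": self.gene_ids,
                           "targets": sorted(self.metadata["target"].unique().tolist())},
                          fh, indent=2)


def _onehot_for(vocab: list[str], batch: str, n: int) -> BatchDesign:
    if batch not in vocab:
        raise ValueError(f"unknown target batch {batch!r}; trained on {vocab}")
    Z = np.zeros((n, len(vocab)))
    Z[:, vocab.index(batch)] = 1.0
    return BatchDesign(Z, list(vocab))


def project_to_batch(re_model: RandomEffectsAutoencoder, X: np.ndarray,
                     target_batch: str) -> np.ndarray:
    """Posterior-mean reconstruction of every cell as if from ``target_batch``.

    Projecting a cell to its own batch returns exactly its ordinary
    reconstruction (the operation only swaps the one-hot row).
    """
    X = np.asarray(X, dtype=np.float64)
    design = _onehot_for(re_model.batch_vocab_, target_batch, X.shape[0])
    return re_model.reconstruct(X, design, mode="posterior_mean")


def build_projection_panel(re_model: RandomEffectsAutoencoder,
                           fe_model: FixedEffectsAutoencoder | None,
                           dataset: ExpressionDataset, X: np.ndarray,
                           cell_type: str | None = None, n: int = 300,
                           seed: int = 0,
                           target_batches: list[str] | None = None
                           ) -> ProjectionPanel:
    """Sample cells, project them into every target batch, and standardize.

    Parameters
    ----------
    dataset
        Carries annotations and ids for the rows of ``X``.
    X
        Standardized expression aligned with ``dataset`` (model input).
    cell_type
        Restrict sampling to this cell type (all cells when None).
    n
        Number of cells to sample; when fewer are available all are
        taken with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    if target_batches is None:
        target_batches = list(re_model.batch_vocab_)
    ann = dataset.annotations
    if cell_type is not None:
        pool = np.flatnonzero((ann[CELLTYPE_KEY] == cell_type).to_numpy())
    else:
        pool = np.arange(dataset.n_cells)
    if len(pool) == 0:
        raise ValueError(f"no cells available for cell type {cell_type!r}")
    rng = np.random.default_rng(seed)
    if len(pool) < n:
        warnings.warn(f"requested {n} cells but only {len(pool)} available; taking all",
                      stacklevel=2)
        chosen = np.sort(pool)
    else:
        chosen = np.sort(rng.choice(pool, size=n, replace=False))

    ids = [dataset.cell_ids[i] for i in chosen]
    src = ann[BATCH_KEY].to_numpy()[chosen]
    Xs = X[chosen]

    blocks = [Xs]
    meta = [pd.DataFrame({"cell_id": ids, "source_batch": src, "target": "original"})]
    if fe_model is not None:
        blocks.append(fe_model.reconstruct(Xs))
        meta.append(pd.DataFrame({"cell_id": ids, "source_batch": src, "target": "FE"}))
    for tb in target_batches:
        blocks.append(project_to_batch(re_model, Xs, tb))
        meta.append(pd.DataFrame({"cell_id": ids, "source_batch": src, "target": tb}))

    matrix = np.vstack(blocks)
    metadata = pd.concat(meta, ignore_index=True)
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    matrix = (matrix - means) / sds
    return ProjectionPanel(matrix, metadata, list(dataset.gene_ids), means, sds)


def projection_contrast(panel: ProjectionPanel, group_a: list[str] | set[str],
                        group_b: list[str] | set[str],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U between two groups of panel rows.

    Groups are sets of target labels (batch names, ``"original"`` or
    ``"FE"``).  Exact p-values are used when both groups have at most 8
    rows and no ties; otherwise the normal approximation with mid-ranks
    and continuity correction.  ``significant`` flags raw ``p < alpha``;
    a Benjamini-Hochberg column is always included.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError(f"groups overlap: {sorted(group_a & group_b)}")
    A = panel.rows_for(group_a)
    B = panel.rows_for(group_b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both groups must select at least one panel row")

    method = "exact" if max(A.shape[0], B.shape[0]) <= 8 else "asymptotic"
    stats_u = np.empty(len(panel.gene_ids))
    pvals = np.empty(len(panel.gene_ids))
    for gi in range(len(panel.gene_ids)):
        a, b = A[:, gi], B[:, gi]
        m = method
        if m == "exact" and (len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)):
            m = "asymptotic"  # scipy's exact method does not handle ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=m,
                                 use_continuity=True)
        stats_u[gi], pvals[gi] = res.statistic, res.pvalue
    p_bh = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": panel.gene_ids,
        "U": stats_u,
        "p": pvals,
        "p_bh": p_bh,
        "significant": pvals < alpha,
    })
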