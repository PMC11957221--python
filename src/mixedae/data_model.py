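"""Core data containers, IO, and stratified cross-validation.

The central container is :class:`ExpressionDataset`, a thin wrapper
around a dense cells x genes count matrix with gene/cell identifiers and
per-cell annotations (at minimum a batch label).  Readers accept Matrix
Market, delimited text and AnnData ``.h5ad`` containers; all IO goes
through scipy / pandas / anndata.

Cross-validation follows the study design: k folds stratified jointly
by batch and (when present) cell type, with a stratified validation
hold-out carved from each training portion for early stopping.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

BATCH_KEY = "batch_label"
CELLTYPE_KEY = "cell_type_label"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Cells x genes expression matrix with identifiers and annotations.

    Parameters
    ----------
    counts
        Non-negative matrix, one row per cell, one column per gene.
    gene_ids, cell_ids
        Unique string identifiers matching the matrix dimensions.
    annotations
        Per-cell table indexed like ``cell_ids``; must contain a
        ``batch_label`` column.  A ``cell_type_label`` column is optional.
    meta
        Free-form provenance (preprocessing thresholds etc.).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    annotations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError(
                f"id lengths ({len(self.cell_ids)} cells, {len(self.gene_ids)} genes) "
                f"do not match counts shape {self.counts.shape}"
            )
        dup = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene ids: {list(dup)}")
        if pd.Index(self.cell_ids).has_duplicates:
            raise ValueError("duplicate cell ids")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative entries")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite entries")
        if self.annotations is None:
            raise ValueError("annotations with a batch_label column are required")
        self.annotations = self.annotations.copy()
        self.annotations.index = pd.Index(self.cell_ids)
        if BATCH_KEY not in self.annotations.columns:
            raise ValueError(f"annotations must contain a '{BATCH_KEY}' column")
        missing = self.annotations.index[self.annotations[BATCH_KEY].isna()]
        if len(missing):
            raise ValueError(f"cells with missing batch label: {list(missing)}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def batch_labels(self) -> np.ndarray:
        return self.annotations[BATCH_KEY].to_numpy()

    @property
    def cell_type_labels(self) -> np.ndarray | None:
        if CELLTYPE_KEY in self.annotations.columns:
            return self.annotations[CELLTYPE_KEY].to_numpy()
        return None

    def subset_cells(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            annotations=self.annotations.iloc[idx],
            meta=dict(self.meta),
        )

    def subset_genes(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=self.cell_ids,
            annotations=self.annotations,
            meta=dict(self.meta),
        )


@dataclass
class BatchDesign:
    """One-hot cell x batch membership matrix with its label vocabulary."""

    onehot: np.ndarray
    batch_vocab: list[str]

    def __post_init__(self):
        self.onehot = np.asarray(self.onehot, dtype=np.float64)
        if self.onehot.ndim != 2 or self.onehot.shape[1] != len(self.batch_vocab):
            raise ValueError("onehot columns must match batch_vocab length")
        rows = self.onehot.sum(axis=1)
        if not np.allclose(rows, 1.0):
            raise ValueError("each one-hot row must sum to exactly 1")

    @property
    def n_batches(self) -> int:
        return len(self.batch_vocab)

    def labels(self) -> np.ndarray:
        return np.array(self.batch_vocab, dtype=object)[self.onehot.argmax(axis=1)]


@dataclass
class CellTypeLabels:
    """One-hot cell x type matrix with its vocabulary."""

    onehot: np.ndarray
    type_vocab: list[str]

    def __post_init__(self):
        self.onehot = np.asarray(self.onehot, dtype=np.float64)
        if self.onehot.shape[1] != len(self.type_vocab):
            raise ValueError("onehot columns must match type_vocab length")
        if not np.allclose(self.onehot.sum(axis=1), 1.0):
            raise ValueError("each one-hot row must sum to exactly 1")


@dataclass
class FoldSplit:
    """Train/validation/test cell indices of one cross-validation fold."""

    fold_index: int
    train_cells: np.ndarray
    val_cells: np.ndarray
    test_cells: np.ndarray

    def __post_init__(self):
        self.train_cells = np.asarray(self.train_cells, dtype=int)
        self.val_cells = np.asarray(self.val_cells, dtype=int)
        self.test_cells = np.asarray(self.test_cells, dtype=int)
        pools = [set(self.train_cells), set(self.val_cells), set(self.test_cells)]
        if (pools[0] & pools[1]) or (pools[0] & pools[2]) or (pools[1] & pools[2]):
            raise ValueError("train/val/test index lists overlap")

    def to_json(self, cell_ids: Sequence[str]) -> str:
        return json.dumps({
            "fold": self.fold_index,
            "train": [cell_ids[i] for i in self.train_cells],
            "val": [cell_ids[i] for i in self.val_cells],
            "test": [cell_ids[i] for i in self.test_cells],
        })


@dataclass
class LatentSpace:
    """Per-cell low-dimensional embedding with provenance."""

    embedding: np.ndarray
    cell_ids: list[str]
    source: str  # one of {"FE", "RE", "PCA", "AE", "FEC", "fused"}
    fold_index: int | None = None
    seed: int | None = None

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        if self.embedding.ndim != 2:
            raise ValueError("embedding must be 2-D")
        if len(self.cell_ids) != self.embedding.shape[0]:
            raise ValueError("cell_ids do not align with embedding rows")
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError("embedding contains non-finite values")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_index_tsv(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    return df.iloc[:, 0].astype(str).tolist()


def load_expression(path: str | Path, format: str | None = None,
                    annotations: pd.DataFrame | None = None) -> ExpressionDataset:
    """Read an expression matrix from MTX, CSV/TSV, or h5ad.

    For ``mtx``, companion index files ``<stem>_genes.tsv`` and
    ``<stem>_cells.tsv`` must sit next to the matrix.  Matrices stored
    genes x cells are transposed automatically when the index-file
    lengths identify that orientation.  CSV/TSV files carry gene ids in
    the header row and cell ids in the first column.
    """
    path = Path(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv", ".h5ad": "h5ad"}.get(
            path.suffix, "csv")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx":
        genes_f = path.with_name(path.stem + "_genes.tsv")
        cells_f = path.with_name(path.stem + "_cells.tsv")
        if not genes_f.exists() or not cells_f.exists():
            raise ValueError(
                f"missing companion index files for {path.name}: "
                f"expected {genes_f.name} and {cells_f.name}")
        mat = spio.mmread(path)
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        gene_ids = _read_index_tsv(genes_f)
        cell_ids = _read_index_tsv(cells_f)
        if mat.shape == (len(gene_ids), len(cell_ids)) and mat.shape[0] != mat.shape[1]:
            mat = mat.T  # stored genes x cells
        if mat.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError("matrix shape does not match index files")
    elif format == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=np.float64)
        gene_ids = [str(c) for c in df.columns]
        cell_ids = [str(i) for i in df.index]
    elif format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        mat = X.toarray() if sparse.issparse(X) else np.asarray(X)
        gene_ids = adata.var_names.tolist()
        cell_ids = adata.obs_names.tolist()
        if annotations is None and len(adata.obs.columns):
            annotations = adata.obs.copy()
    else:
        raise ValueError(f"unknown format {format!r}")

    if annotations is None:
        sidecar = path.with_name(path.stem + "_annotations.csv")
        if sidecar.exists():
            annotations = pd.read_csv(sidecar, index_col=0)
        else:
            raise ValueError(
                f"no annotations supplied and no sidecar {sidecar.name}; "
                f"a '{BATCH_KEY}' column is required")
    return ExpressionDataset(mat, gene_ids, cell_ids, annotations)


def save_expression(dataset: ExpressionDataset, path: str | Path,
                    format: str | None = None) -> None:
    """Write a dataset as MTX (+index/annotation sidecars), CSV/TSV, or h5ad."""
    path = Path(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv", ".h5ad": "h5ad"}.get(
            path.suffix, "csv")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx":
        spio.mmwrite(str(path), sparse.csr_matrix(dataset.counts))
        pd.DataFrame({"id": dataset.gene_ids, "name": dataset.gene_ids}).to_csv(
            path.with_name(path.stem + "_genes.tsv"), sep="\t", header=False, index=False)
        pd.DataFrame({"id": dataset.cell_ids, "name": dataset.cell_ids}).to_csv(
            path.with_name(path.stem + "_cells.tsv"), sep="\t", header=False, index=False)
        dataset.annotations.to_csv(path.with_name(path.stem + "_annotations.csv"))
    elif format == "csv":
        sep = "\t" if path.suffix == ".tsv" else ","
        pd.DataFrame(dataset.counts, index=dataset.cell_ids,
                     columns=dataset.gene_ids).to_csv(path, sep=sep)
        dataset.annotations.to_csv(path.with_name(path.stem + "_annotations.csv"))
    elif format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=dataset.counts.copy(),
            obs=dataset.annotations.copy(),
            var=pd.DataFrame(index=pd.Index(dataset.gene_ids)),
        )
        adata.obs_names = pd.Index(dataset.cell_ids)
        adata.uns["mixedae_meta"] = json.dumps(dataset.meta, default=str)
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# encodings and folds
# ---------------------------------------------------------------------------

def make_batch_design(dataset: ExpressionDataset, batch_key: str = BATCH_KEY) -> BatchDesign:
    """One-hot encode a categorical annotation column.

    The vocabulary is the lexicographically sorted set of observed
    labels, so column meaning is reproducible across runs.
    """
    if batch_key not in dataset.annotations.columns:
        raise KeyError(f"annotation column {batch_key!r} not found")
    labels = dataset.annotations[batch_key]
    missing = labels.index[labels.isna()]
    if len(missing):
        raise ValueError(f"cells with missing {batch_key}: {list(missing)}")
    labels = labels.astype(str).to_numpy()
    vocab = sorted(set(labels))
    lut = {v: j for j, v in enumerate(vocab)}
    onehot = np.zeros((len(labels), len(vocab)))
    onehot[np.arange(len(labels)), [lut[v] for v in labels]] = 1.0
    return BatchDesign(onehot, vocab)


def make_cell_type_labels(dataset: ExpressionDataset,
                          type_key: str = CELLTYPE_KEY) -> CellTypeLabels:
    design = make_batch_design(dataset, batch_key=type_key)
    return CellTypeLabels(design.onehot, design.batch_vocab)


def stratified_kfold(dataset: ExpressionDataset, k: int = 5,
                     val_fraction: float = 0.1, seed: int = 0) -> list[FoldSplit]:
    """k-fold split stratified by batch x cell type.

    Every stratum's cells are spread across the k test folds as evenly
    as integer division allows; strata smaller than ``k`` are
    distributed round-robin with a warning.  Within each training
    portion, ``val_fraction`` of the cells (same stratification) are
    held out for early stopping.
    """
    if k <= 1:
        raise ValueError("k must be at least 2")
    n = dataset.n_cells
    if n == 0:
        raise ValueError("empty dataset")
    batches = dataset.batch_labels.astype(str)
    types = dataset.cell_type_labels
    if types is not None:
        strata = np.array([f"{b}||{t}" for b, t in zip(batches, types.astype(str))])
    else:
        strata = batches
    rng = np.random.default_rng(seed)

    test_members: list[list[int]] = [[] for _ in range(k)]
    for s in sorted(set(strata)):
        idx = np.flatnonzero(strata == s)
        idx = idx[rng.permutation(len(idx))]
        if len(idx) < k:
            warnings.warn(
                f"stratum {s!r} has {len(idx)} cells (< k={k}); distributing round-robin",
                stacklevel=2)
        for pos, cell in enumerate(idx):
            test_members[pos % k].append(int(cell))

    folds = []
    for f in range(k):
        test = np.array(sorted(test_members[f]), dtype=int)
        pool = np.array(sorted(set(range(n)) - set(test.tolist())), dtype=int)
        # stratified validation hold-out inside the training portion
        val: list[int] = []
        pool_strata = strata[pool]
        for s in sorted(set(pool_strata)):
            sidx = pool[pool_strata == s]
            sidx = sidx[rng.permutation(len(sidx))]
            n_val = int(round(val_fraction * len(sidx)))
            val.extend(int(i) for i in sidx[:n_val])
        val_arr = np.array(sorted(val), dtype=int)
        train = np.array(sorted(set(pool.tolist()) - set(val)), dtype=int)
        folds.append(FoldSplit(f, train, val_arr, test))
    return folds
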