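"""Latent-space evaluation: clustering separability, latent fusion,
Random-Forest classification, and UMAP figures.

Separability is measured on latent coordinates (never on UMAP
coordinates) with three standard indices: average silhouette width
(ASW, in [-1, 1]), Calinski-Harabasz (CH), and the reciprocal of
Davies-Bouldin (1/DB), all Euclidean.  ASW is the primary metric:
high ASW by cell type means preserved biology; low ASW by batch on a
batch-corrected space means suppressed batch structure, while high ASW
by batch on the random-effects space means successfully modeled batch
structure.  Fold-level values are aggregated as mean with a
t-distribution 95% confidence interval.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, balanced_accuracy_score,
                             calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)
from sklearn.preprocessing import LabelEncoder

from .data_model import FoldSplit, LatentSpace

__all__ = ["separability_metrics", "report_across_folds", "fuse_latents",
           "classify_latent", "umap_figure"]


def separability_metrics(embedding: LatentSpace | np.ndarray,
                         labels: np.ndarray) -> dict[str, float]:
    """ASW, CH and 1/DB of a labeling on latent coordinates.

    Labels with a single member are dropped with a warning.  Degenerate
    geometry (all points identical) is defined as ASW = 0, CH = 0 and
    1/DB = 0 rather than an error.
    """
    X = embedding.embedding if isinstance(embedding, LatentSpace) else np.asarray(embedding)
    labels = np.asarray(labels)
    if X.shape[0] != len(labels):
        raise ValueError("labels do not align with embedding rows")
    values, counts = np.unique(labels, return_counts=True)
    singles = values[counts < 2]
    if len(singles):
        warnings.warn(f"dropping singleton labels: {list(singles)}", stacklevel=2)
        keep = ~np.isin(labels, singles)
        X, labels = X[keep], labels[keep]
        values = values[counts >= 2]
    if len(values) < 2:
        raise ValueError("at least 2 labels with >= 2 members are required")
    if np.allclose(X, X[0]):
        return {"asw": 0.0, "ch": 0.0, "inv_db": 0.0}
    asw = float(silhouette_score(X, labels, metric="euclidean"))
    ch = float(calinski_harabasz_score(X, labels))
    db = float(davies_bouldin_score(X, labels))
    return {"asw": asw, "ch": ch, "inv_db": (1.0 / db if db > 0 else np.inf)}


def report_across_folds(values) -> dict[str, float]:
    """Mean and t-based 95% CI of per-fold metric values."""
    v = np.asarray(list(values), dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError("need at least 2 folds")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = float(stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k))
    return {"mean": mean, "ci_lower": mean - half, "ci_upper": mean + half, "n_folds": k}


def fuse_latents(fe: LatentSpace, re: LatentSpace,
                 fit_idx: np.ndarray | None = None) -> LatentSpace:
    """Standardize each latent per dimension and concatenate column-wise.

    Standardization statistics are fit on ``fit_idx`` (training cells)
    when given, else on all cells.
    """
    if fe.cell_ids != re.cell_ids:
        raise ValueError("latent spaces carry different cells or orders")
    parts = []
    for ls in (fe, re):
        E = ls.embedding
        ref = E[np.asarray(fit_idx, dtype=int)] if fit_idx is not None else E
        mu, sd = ref.mean(axis=0), ref.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        parts.append((E - mu) / sd)
    return LatentSpace(np.hstack(parts), list(fe.cell_ids), source="fused",
                       fold_index=fe.fold_index, seed=fe.seed)


def classify_latent(latents: LatentSpace | list[LatentSpace], target: np.ndarray,
                    folds: list[FoldSplit], seed: int = 0,
                    n_trees: int = 100) -> pd.DataFrame:
    """Random-Forest classification of a per-cell target from latents.

    ``latents`` is one latent space covering all cells (then fold
    splits index into it) or one per fold (each fold's latent must come
    from that fold's trained models to avoid leakage).  Per fold, the
    forest is fit on train+val cells and evaluated on test cells;
    chance accuracy comes from a stratified dummy classifier that
    samples predictions from the training label distribution.  All
    accuracies are percentages in [0, 100].
    """
    target = np.asarray(target)
    per_fold = isinstance(latents, (list, tuple))
    rows = []
    for f, fold in enumerate(folds):
        ls = latents[f] if per_fold else latents
        X = ls.embedding
        fit_idx = np.concatenate([fold.train_cells, fold.val_cells])
        test_idx = fold.test_cells
        y_fit, y_test = target[fit_idx], target[test_idx]
        test_only = set(np.unique(y_test)) - set(np.unique(y_fit))
        if test_only:
            warnings.warn(f"classes only in test fold {f}: {sorted(test_only)}; "
                          "scored as zero recall", stacklevel=2)
        enc = LabelEncoder().fit(target)
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        rf.fit(X[fit_idx], enc.transform(y_fit))
        pred = rf.predict(X[test_idx])
        dummy = DummyClassifier(strategy="stratified", random_state=seed)
        dummy.fit(X[fit_idx], enc.transform(y_fit))
        chance = dummy.predict(X[test_idx])
        y_test_enc = enc.transform(y_test)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-recall classes
            bal = balanced_accuracy_score(y_test_enc, pred)
        rows.append({
            "fold": f,
            "source": ls.source,
            "accuracy": 100.0 * accuracy_score(y_test_enc, pred),
            "balanced_accuracy": 100.0 * bal,
            "chance_accuracy": 100.0 * accuracy_score(y_test_enc, chance),
        })
    return pd.DataFrame(rows)


def umap_figure(latent: LatentSpace, colorings: dict[str, np.ndarray],
                out_dir, seed: int = 0, prefix: str = "umap") -> list[str]:
    """UMAP scatter figures of a latent space, one file per coloring.

    Purely presentational: delegates to umap-learn with a fixed seed
    and returns the written file paths, never metric values.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    import umap

    X = latent.embedding
    if X.shape[0] == 0:
        raise ValueError("empty latent space")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, labels in colorings.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            m = labels == lab
            ax.scatter(coords[m, 0], coords[m, 1], s=4, label=str(lab), alpha=0.7)
        ax.legend(markerscale=3, fontsize=7, loc="best")
        ax.set_title(f"{latent.source} latent - colored by {name}")
        ax.set_xticks([])
        ax.set_yticks([])
        path = out_dir / f"{prefix}_{latent.source}_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths
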