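"""Genomap rendering: per-cell expression as 2D gene-placement images.

A genomap places every gene on a pixel of a square grid and writes the
cell's (standardized) expression value at that pixel.  Placement is
polar: each gene's interaction score is the mean absolute Pearson
correlation with all other genes over the panel rows, and genes are
laid onto pixels in order of distance rho from the image center.  By
default high-interaction genes sit at small rho (hub-centric, the more
legible orientation); ``orientation="proportional"`` places them at
large rho instead.  The angular position theta is a deterministic
tie-break, not meaningful.  One layout is fitted per panel and frozen,
so all projections of a panel share identical gene placement and
differ only in intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenomapLayout", "GenomapImage", "fit_genomap_layout",
           "render_genomap", "genomap_montage"]


@dataclass
class GenomapLayout:
    """Frozen gene -> pixel assignment for one panel."""

    grid_side: int
    rows: np.ndarray  # pixel row per gene
    cols: np.ndarray  # pixel col per gene
    interaction_score: np.ndarray
    radius: np.ndarray  # pixel-center distance from image center per gene
    gene_ids: list[str]
    orientation: str = "hub_center"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_ids, "row": self.rows,
                             "col": self.cols, "score": self.interaction_score,
                             "radius": self.radius})


@dataclass
class GenomapImage:
    grid: np.ndarray  # grid_side x grid_side float intensities
    cell_id: str
    meta: dict


def fit_genomap_layout(panel_matrix: np.ndarray, grid_side: int | None = None,
                       gene_ids: list[str] | None = None,
                       orientation: str = "hub_center") -> GenomapLayout:
    """Fit a shared gene -> pixel layout from a panel of expression rows.

    The interaction score of gene i is the mean over j != i of
    |Pearson correlation(gene_i, gene_j)| across panel rows (constant
    genes score 0).  Genes sorted by score are assigned to pixels
    sorted by distance from the image center (ties broken by angle),
    hub-centric by default.
    """
    M = np.asarray(panel_matrix, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] < 3:
        raise ValueError("panel must have at least 3 rows to estimate correlations")
    g = M.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(g)]
    if orientation not in ("hub_center", "proportional"):
        raise ValueError("orientation must be 'hub_center' or 'proportional'")
    side = grid_side if grid_side is not None else int(np.ceil(np.sqrt(g)))
    if side * side < g:
        raise ValueError(f"grid_side {side} too small for {g} genes")

    sd = M.std(axis=0)
    score = np.zeros(g)
    ok = sd > 0
    if ok.sum() >= 2:
        C = np.corrcoef(M[:, ok], rowvar=False)
        np.fill_diagonal(C, np.nan)
        score[ok] = np.nanmean(np.abs(C), axis=1)
    if g == 1:
        score[:] = 0.0

    # pixels ordered by distance from the image center, angle as tie-break
    center = (side - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    dist = np.hypot(rr - center, cc - center)
    ang = np.mod(np.arctan2(rr - center, cc - center), 2 * np.pi)
    pixel_order = np.lexsort((ang, np.round(dist, 9)))

    gene_order = np.lexsort((np.arange(g), -score))
    if orientation == "proportional":
        gene_order = gene_order[::-1]  # high interaction at large rho

    rows = np.empty(g, dtype=int)
    cols = np.empty(g, dtype=int)
    radius = np.empty(g)
    for rank, gi in enumerate(gene_order):
        px = pixel_order[rank]
        rows[gi], cols[gi] = rr[px], cc[px]
        radius[gi] = dist[px]
    return GenomapLayout(side, rows, cols, score, radius, list(gene_ids), orientation)


def render_genomap(layout: GenomapLayout, cell_row: np.ndarray,
                   cell_id: str = "", background: float = np.nan,
                   meta: dict | None = None) -> GenomapImage:
    """Write one cell's expression onto the layout's grid.

    Invertible: reading the assigned pixels back in gene order recovers
    the input vector exactly.
    """
    v = np.asarray(cell_row, dtype=np.float64).ravel()
    if v.size != layout.n_genes:
        raise ValueError(f"expected {layout.n_genes} values, got {v.size}")
    grid = np.full((layout.grid_side, layout.grid_side), background)
    grid[layout.rows, layout.cols] = v
    return GenomapImage(grid, cell_id, meta or {})


def read_back(layout: GenomapLayout, image: GenomapImage) -> np.ndarray:
    """Recover the expression vector from an image (exact inverse of render)."""
    return image.grid[layout.rows, layout.cols]


def save_png(image: GenomapImage, path, vmin: float | None = None,
             vmax: float | None = None) -> None:
    """Write a single genomap as a grayscale PNG (min-max scaled).

    Pass the panel-wide ``vmin``/``vmax`` to keep a shared intensity
    scale across images of the same panel.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.nan_to_num(image.grid, nan=np.nanmin(image.grid))
    plt.imsave(path, grid, cmap="gray", vmin=vmin, vmax=vmax)


def genomap_montage(layout: GenomapLayout, panel_matrix: np.ndarray,
                    metadata: pd.DataFrame, out_path, cell_ids: list[str] | None = None,
                    max_cells: int = 6) -> None:
    """Figure of genomaps: rows = cells, columns = original/FE/projections.

    The column matching each cell's own source batch is outlined in red,
    mirroring the panel layout used for visual batch-effect inspection.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    targets = list(dict.fromkeys(metadata["target"]))
    cells = list(dict.fromkeys(metadata["cell_id"]))[:max_cells]
    if cell_ids is not None:
        cells = [c for c in cell_ids if c in set(metadata["cell_id"])][:max_cells]
    vmin = np.nanmin(panel_matrix)
    vmax = np.nanmax(panel_matrix)
    fig, axes = plt.subplots(len(cells), len(targets),
                             figsize=(2 * len(targets), 2 * len(cells)),
                             squeeze=False)
    for i, cid in enumerate(cells):
        for j, tgt in enumerate(targets):
            ax = axes[i][j]
            sel = (metadata["cell_id"] == cid) & (metadata["target"] == tgt)
            ridx = np.flatnonzero(sel.to_numpy())
            ax.set_xticks([])
            ax.set_yticks([])
            if len(ridx) == 0:
                ax.axis("off")
                continue
            img = render_genomap(layout, panel_matrix[ridx[0]], cell_id=cid)
            ax.imshow(img.grid, cmap="viridis", vmin=vmin, vmax=vmax)
            src = metadata.loc[sel, "source_batch"].iloc[0]
            if tgt == src:  # highlight the cell's own batch
                for spine in ax.spines.values():
                    spine.set_edgecolor("red")
                    spine.set_linewidth(2.5)
            if i == 0:
                ax.set_title(str(tgt), fontsize=9)
        axes[i][0].set_ylabel(str(cid), fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
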