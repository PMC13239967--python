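"""Normalization, variable-gene selection, PCA, and batch centering.

The preprocessing chain follows standard single-cell practice: counts are
depth-normalized to a fixed target sum per cell (10 000 by default) and
log1p-transformed; the top 3000 highly variable genes are selected by
binned normalized dispersion; the HVG submatrix is standardized per gene
(clipped at 10 standard deviations) and reduced to 30 principal components.

Donor integration is a deterministic batch-centering step in PC space:
each batch's centroid is moved onto the global centroid, which removes
between-batch location shifts while preserving within-batch geometry
exactly. It deliberately does nothing more; swap in a full integration
method here when batch effects go beyond location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA

from kerastate.errors import KerastateError

__all__ = [
    "EmbeddingResult",
    "normalize_log",
    "select_hvg",
    "run_pca",
    "center_batches",
]


@dataclass
class EmbeddingResult:
    """Cell x component coordinates with explained-variance fractions."""

    coordinates: np.ndarray = field(repr=False)
    explained_variance_ratio: np.ndarray = field(repr=False)
    hvg_indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def normalize_log(counts, target_sum: float = 1e4) -> sp.csr_matrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Zero cells stay zero; the sparsity pattern is preserved.
    """
    if target_sum <= 0:
        raise KerastateError(f"normalize_log: target_sum must be > 0, got {target_sum}")
    X = (counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(np.asarray(counts))).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return X.tocsr()


def select_hvg(normalized, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Rank genes by binned normalized dispersion; return the top ``n_top``.

    Dispersion is var/mean of the log-normalized values per gene; genes are
    cut into ``n_bins`` equal-width mean bins and dispersions z-scored
    within each bin. The bin count is capped so each bin averages at least
    ten genes — z-scores in near-empty bins are meaningless. Ties break by
    gene index, so the selection is fully deterministic. Returned indices
    are sorted by rank (best first).
    """
    n_cells, n_genes = normalized.shape
    if n_top > n_genes:
        raise KerastateError(f"select_hvg: n_top={n_top} exceeds n_genes={n_genes}")
    X = normalized.tocsr() if sp.issparse(normalized) else sp.csr_matrix(np.asarray(normalized))
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = np.maximum(ex2 - mean**2, 0.0) * (n_cells / max(n_cells - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    n_bins = max(1, min(n_bins, n_genes // 10))
    bins = pd.cut(mean, bins=n_bins, labels=False, duplicates="drop")
    bins = np.asarray(pd.Series(bins).fillna(0), dtype=int)
    norm_disp = np.zeros(n_genes)
    for b in np.unique(bins):
        members = bins == b
        d = dispersion[members]
        sd = d.std()
        norm_disp[members] = (d - d.mean()) / sd if sd > 0 else 0.0
    order = np.lexsort((np.arange(n_genes), -norm_disp))
    return order[:n_top]


def run_pca(
    matrix,
    n_components: int,
    scale: bool = True,
    clip: float = 10.0,
) -> EmbeddingResult:
    """PCA on (optionally standardized) log-normalized expression.

    Columns are centered, and scaled to unit variance with values clipped
    at ``clip`` when ``scale`` is set. Components are ordered by decreasing
    variance with a fixed sign convention: each component's
    largest-magnitude gene loading is positive.
    """
    X = np.asarray(matrix.todense() if sp.issparse(matrix) else matrix, dtype=float)
    n_cells, n_genes = X.shape
    if n_cells < 2:
        raise KerastateError("run_pca: need at least 2 cells")
    if n_components > min(n_cells, n_genes):
        raise KerastateError(
            f"run_pca: n_components={n_components} exceeds min(n_cells, n_genes)="
            f"{min(n_cells, n_genes)}"
        )
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd > 0, sd, 1.0)
        np.clip(X, -clip, clip, out=X)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| gene positive per component
    for j in range(n_components):
        loading = pca.components_[j]
        top = int(np.argmax(np.abs(loading)))
        if loading[top] < 0:
            coords[:, j] *= -1.0
    return EmbeddingResult(
        coordinates=coords,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def center_batches(embedding: EmbeddingResult, batch_labels) -> EmbeddingResult:
    """Move each batch centroid onto the global centroid, per component.

    Within-batch geometry is preserved exactly; the operation is idempotent
    and reduces to the identity for a single batch.
    """
    labels = pd.Series(batch_labels)
    if labels.isna().any():
        raise KerastateError("center_batches: every cell needs a batch label")
    coords = embedding.coordinates
    if len(labels) != coords.shape[0]:
        raise KerastateError(
            f"center_batches: {len(labels)} labels for {coords.shape[0]} cells"
        )
    out = coords.copy()
    global_centroid = coords.mean(axis=0)
    for batch in labels.unique():
        members = (labels == batch).to_numpy()
        out[members] += global_centroid - coords[members].mean(axis=0)
    return EmbeddingResult(
        coordinates=out,
        explained_variance_ratio=embedding.explained_variance_ratio.copy(),
        hvg_indices=embedding.hvg_indices,
    )
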