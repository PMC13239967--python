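"""Per-cell quality control metrics and threshold filtering.

Four filters are applied jointly, all boundaries inclusive: minimum
expressed genes per cell (default 200), minimum total UMIs (default 500),
maximum ribosomal percentage (default 50%) and maximum mitochondrial
percentage (default 20%). Percentages are computed on raw UMIs before any
normalization; a cell with zero total UMIs gets 0% for both by convention.

Mitochondrial and ribosomal genes are identified by case-insensitive
feature-name prefix ("MT-" for mitochondrial; "RPS"/"RPL" for ribosomal,
which excludes the mitochondrial ribosomal MRPS/MRPL families), with
explicit mask overrides available when the gene sets are known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from kerastate.errors import DimensionError

__all__ = [
    "QCThresholds",
    "QCReport",
    "mito_mask_from_names",
    "ribo_mask_from_names",
    "compute_cell_qc",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive filtering cut-offs."""

    min_genes: int = 200
    min_umis: int = 500
    max_ribo_pct: float = 50.0
    max_mito_pct: float = 20.0

    def __post_init__(self):
        for name in ("min_genes", "min_umis", "max_ribo_pct", "max_mito_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"QCThresholds.{name} must be non-negative")

    def to_dict(self) -> dict:
        return {
            "min_genes": self.min_genes,
            "min_umis": self.min_umis,
            "max_ribo_pct": self.max_ribo_pct,
            "max_mito_pct": self.max_mito_pct,
        }


@dataclass
class QCReport:
    pass_mask: np.ndarray = field(repr=False)
    n_fail_genes: int = 0
    n_fail_umis: int = 0
    n_fail_ribo: int = 0
    n_fail_mito: int = 0

    @property
    def n_pass(self) -> int:
        return int(self.pass_mask.sum())

    @property
    def n_cells(self) -> int:
        return int(self.pass_mask.size)

    def summary(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_pass": self.n_pass,
            "n_fail_genes": self.n_fail_genes,
            "n_fail_umis": self.n_fail_umis,
            "n_fail_ribo": self.n_fail_ribo,
            "n_fail_mito": self.n_fail_mito,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def mito_mask_from_names(names) -> np.ndarray:
    return np.array([str(n).upper().startswith("MT-") for n in names])


def ribo_mask_from_names(names) -> np.ndarray:
    return np.array([str(n).upper().startswith(("RPS", "RPL")) for n in names])


def compute_cell_qc(counts, mito_mask=None, ribo_mask=None) -> pd.DataFrame:
    """Per-cell metrics: n_genes, n_umis, mito_pct, ribo_pct.

    ``counts`` is cells x genes raw UMIs; the masks are boolean over genes
    (missing mask = all-False, yielding 0% content).
    """
    n_cells, n_genes = counts.shape
    masks = {}
    for name, mask in (("mito_mask", mito_mask), ("ribo_mask", ribo_mask)):
        if mask is None:
            mask = np.zeros(n_genes, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_genes,):
            raise DimensionError(f"{name} has length {mask.size}, expected {n_genes}")
        masks[name] = mask
    X = (counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(np.asarray(counts))).copy()
    X.eliminate_zeros()
    n_umis = np.asarray(X.sum(axis=1)).ravel()
    n_expressed = np.diff(X.indptr)
    denom = np.where(n_umis > 0, n_umis, 1)  # zero-cell convention: 0%
    mito = np.asarray(X[:, masks["mito_mask"]].sum(axis=1)).ravel()
    ribo = np.asarray(X[:, masks["ribo_mask"]].sum(axis=1)).ravel()
    return pd.DataFrame(
        {
            "n_genes": n_expressed.astype(int),
            "n_umis": n_umis.astype(int),
            "mito_pct": 100.0 * mito / denom,
            "ribo_pct": 100.0 * ribo / denom,
        }
    )


def apply_qc(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Evaluate the four-filter conjunction; all boundaries inclusive."""
    ok_genes = metrics["n_genes"].to_numpy() >= thresholds.min_genes
    ok_umis = metrics["n_umis"].to_numpy() >= thresholds.min_umis
    ok_ribo = metrics["ribo_pct"].to_numpy() <= thresholds.max_ribo_pct
    ok_mito = metrics["mito_pct"].to_numpy() <= thresholds.max_mito_pct
    return QCReport(
        pass_mask=ok_genes & ok_umis & ok_ribo & ok_mito,
        n_fail_genes=int((~ok_genes).sum()),
        n_fail_umis=int((~ok_umis).sum()),
        n_fail_ribo=int((~ok_ribo).sum()),
        n_fail_mito=int((~ok_mito).sum()),
    )
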