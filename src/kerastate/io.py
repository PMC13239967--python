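"""Readers and writers for the 10x-style on-disk exchange formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from kerastate.errors import KerastateError

__all__ = ["read_counts_10x", "write_embedding_tsv", "write_fraction_table_tsv"]


def read_counts_10x(directory) -> tuple[sp.csr_matrix, pd.DataFrame, pd.DataFrame | None]:
    """Read matrix.mtx + features.tsv + barcodes.tsv (+ optional cells.tsv).

    Returns (counts as cells x genes CSR, features frame, cells frame or
    None). Orientation is auto-detected from the MTX dimensions against the
    TSV lengths; Cell Ranger's genes x cells layout is assumed when the
    matrix is square.
    """
    directory = Path(directory)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (directory / fname).exists():
            raise KerastateError(f"read_counts_10x: missing {fname} in {directory}")
    try:
        features = pd.read_csv(
            directory / "features.tsv", sep="\t", header=None, names=["id", "name"], dtype=str
        )
    except pd.errors.EmptyDataError:
        features = pd.DataFrame(columns=["id", "name"], dtype=str)
    if features["name"].isna().all():  # single-column features file
        features["name"] = features["id"]
    try:
        barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None, dtype=str)[0]
    except pd.errors.EmptyDataError:
        barcodes = pd.Series([], dtype=str)
    if barcodes.duplicated().any():
        dup = barcodes[barcodes.duplicated()].iloc[0]
        raise KerastateError(f"read_counts_10x: duplicate barcode {dup!r}")
    mat = sp.coo_matrix(scipy.io.mmread(directory / "matrix.mtx"))
    n_feat, n_bc = len(features), len(barcodes)
    if mat.shape == (n_feat, n_bc):
        counts = mat.T.tocsr()
    elif mat.shape == (n_bc, n_feat):
        counts = mat.tocsr()
    else:
        raise KerastateError(
            f"read_counts_10x: matrix shape {mat.shape} matches neither "
            f"(features={n_feat}, barcodes={n_bc}) orientation"
        )
    cells = None
    if (directory / "cells.tsv").exists():
        cells = pd.read_csv(directory / "cells.tsv", sep="\t", dtype=str)
        if "barcode" not in cells.columns:
            raise KerastateError("read_counts_10x: cells.tsv lacks a 'barcode' column")
        if len(cells) != n_bc or not (cells["barcode"].to_numpy() == barcodes.to_numpy()).all():
            raise KerastateError("read_counts_10x: cells.tsv does not align with barcodes.tsv")
    else:
        cells = pd.DataFrame({"barcode": barcodes})
    return counts.astype(np.int64), features, cells


def write_embedding_tsv(path, barcodes, coordinates) -> None:
    coords = np.asarray(coordinates)
    frame = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    frame.insert(0, "barcode", list(barcodes))
    frame.to_csv(path, sep="\t", index=False)


def write_fraction_table_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)
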