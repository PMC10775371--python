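"""Readers and writers for the tabular and matrix-market interchange formats.

Expression matrices travel as a matrix-market ``.mtx`` (cells x genes,
optionally gzipped) plus two TSVs of cell and gene annotations; marker
tables, spot tables and signature matrices are plain TSV; ground truth and
run manifests are JSON.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "read_expression",
    "write_expression",
    "read_table",
    "write_table",
    "file_sha256",
]


def _open_maybe_gz(path, mode="rb"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression(mtx_path, cells_path, genes_path) -> AnnData:
    """Load a cells x genes sparse matrix with aligned annotation tables.

    The TSVs must have one row per cell / gene with the identifier in the
    first column; dimension mismatches raise an error naming all three files.
    """
    try:
        with _open_maybe_gz(mtx_path) as fh:
            X = scipy.io.mmread(fh)
    except ValueError as e:
        raise ValueError(f"{mtx_path}: malformed matrix-market file: {e}") from e
    obs = read_table(cells_path, index_col=0)
    var = read_table(genes_path, index_col=0)
    if X.shape != (len(obs), len(var)):
        raise ValueError(
            f"dimension mismatch: {mtx_path} is {X.shape} but {cells_path} has "
            f"{len(obs)} cells and {genes_path} has {len(var)} genes"
        )
    adata = AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    return adata


def write_expression(adata: AnnData, mtx_path, cells_path, genes_path) -> None:
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    with _open_maybe_gz(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, X.tocoo())
    write_table(adata.obs, cells_path)
    write_table(adata.var, genes_path)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
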