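"""Gene-index S-scores: project a log-normalized expression matrix onto gene sets.

The transformation is deliberately simple and linear: gene expression is
converted to per-gene Z-scores across cells, and the Z-score matrix is
multiplied by a binary encoding matrix ``E`` (genes x indices).  The S-score
of index ``j`` in cell ``i`` is therefore the sum of cell ``i``'s Z-scores
over the member genes of ``j``.  A 21-gene Type I interferon-stimulated-gene
score is the one-index special case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "GeneIndexCatalog",
    "lognormalize",
    "zscore_genes",
    "compute_sscores",
    "score_ifn_signature",
    "cluster_on_sscores",
    "compare_labels",
    "read_gmt",
]


@dataclass
class GeneIndexCatalog:
    """Named gene sets encoded as a binary gene x index membership matrix."""

    encoding: pd.DataFrame  # genes x indices, entries 0/1

    def __post_init__(self):
        E = self.encoding
        vals = E.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("encoding matrix must be binary")
        empty = E.columns[vals.sum(axis=0) == 0]
        if len(empty):
            warnings.warn(f"dropping {len(empty)} empty index(es): {list(empty)}")
            self.encoding = E.drop(columns=empty)

    @classmethod
    def from_dict(cls, sets: dict[str, list[str]]) -> "GeneIndexCatalog":
        genes = sorted({g for gs in sets.values() for g in gs})
        E = pd.DataFrame(0, index=genes, columns=list(sets), dtype=np.int8)
        for name, gs in sets.items():
            E.loc[list(set(gs)), name] = 1
        return cls(E)

    @classmethod
    def from_gmt(cls, path) -> "GeneIndexCatalog":
        return cls.from_dict(read_gmt(path))

    @property
    def index_names(self) -> list[str]:
        return list(self.encoding.columns)

    def to_dict(self) -> dict[str, list[str]]:
        E = self.encoding
        return {c: E.index[E[c] == 1].tolist() for c in E.columns}


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (name, description, then member genes)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln} has fewer than 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def _dense(matrix) -> tuple[np.ndarray, pd.Index, pd.Index]:
    if isinstance(matrix, AnnData):
        X = matrix.X
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)
        return X.astype(float), matrix.obs_names, matrix.var_names
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), matrix.index, matrix.columns
    X = np.asarray(matrix, dtype=float)
    return X, pd.RangeIndex(X.shape[0]), pd.RangeIndex(X.shape[1])


def lognormalize(matrix, scale_total: float = 10_000.0):
    """Scale each cell's counts to ``scale_total`` then apply log1p.

    Zero-count cells come out all-zero (with a warning); gating should have
    removed them.  Accepts AnnData (returns a new AnnData with dense
    normalized X), DataFrame, or array.
    """
    X, cells, genes = _dense(matrix)
    total = X.sum(axis=1)
    if (total == 0).any():
        warnings.warn(f"{int((total == 0).sum())} zero-count cell(s); rows left at 0")
    scale = np.divide(scale_total, total, out=np.zeros_like(total), where=total > 0)
    out = np.log1p(X * scale[:, None])
    if isinstance(matrix, AnnData):
        res = matrix.copy()
        res.X = out
        return res
    return pd.DataFrame(out, index=cells, columns=genes)


def zscore_genes(matrix, ddof: int = 0) -> pd.DataFrame:
    """Standardize each gene column to mean 0, SD 1 across cells.

    Population SD (``ddof=0``) by default; zero-variance genes map to all-zero
    columns rather than being dropped, so index membership counts are stable.
    """
    X, cells, genes = _dense(matrix)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    # columns constant up to float rounding count as zero-variance too
    flat = sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)
    Z = (X - mu) / np.where(flat, 1.0, sd)
    Z[:, flat] = 0.0
    return pd.DataFrame(Z, index=cells, columns=genes)


def compute_sscores(Z: pd.DataFrame, catalog: GeneIndexCatalog) -> pd.DataFrame:
    """S = Z x E over the genes shared between Z and the catalog.

    Alignment is an inner join on gene identifier, so gene order is
    irrelevant. Indices left without any member gene in the data are dropped
    with a warning; an empty gene intersection is an error.
    """
    shared = Z.columns.intersection(catalog.encoding.index)
    if len(shared) == 0:
        raise ValueError(
            f"no genes shared between expression matrix and catalog "
            f"({list(catalog.index_names)[:5]}...)"
        )
    E = catalog.encoding.loc[shared]
    kept = E.columns[(E.to_numpy().sum(axis=0)) > 0]
    if len(kept) < E.shape[1]:
        dropped = sorted(set(E.columns) - set(kept))
        warnings.warn(f"indices with no member genes in data dropped: {dropped}")
    E = E[kept]
    S = Z[shared].to_numpy() @ E.to_numpy(dtype=float)
    return pd.DataFrame(S, index=Z.index, columns=kept)


def score_ifn_signature(
    Z: pd.DataFrame, genes: list[str], labels: pd.Series | None = None,
    name: str = "IFN_score",
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Score a user-supplied interferon-stimulated-gene list per cell.

    This is the one-index catalog case (e.g. the 21-gene Type I IFN score).
    When per-cell ``labels`` are given, also returns the per-label mean score.
    """
    catalog = GeneIndexCatalog.from_dict({name: list(genes)})
    score = compute_sscores(Z, catalog)[name]
    if labels is not None:
        means = score.groupby(pd.Series(labels, index=score.index)).mean()
        return score, means
    return score


def cluster_on_sscores(S: pd.DataFrame, clusterer, embedder=None):
    """Pluggable hook: treat S-scores as a new feature space and re-cluster.

    ``clusterer`` is any callable mapping an (n_cells, n_features) array to
    per-cell labels (e.g. a community-detection wrapper); ``embedder``
    optionally maps the S-score matrix to a lower-dimensional array first.
    The embedding/clustering algorithms themselves are external.
    """
    X = S.to_numpy()
    if embedder is not None:
        X = embedder(X)
    labels = clusterer(X)
    return pd.Series(np.asarray(labels), index=S.index, name="sscore_cluster")


def compare_labels(new: pd.Series, old: pd.Series) -> pd.DataFrame:
    """Cross-tabulate a re-clustering against prior labels."""
    return pd.crosstab(pd.Series(new, name="new"), pd.Series(old, name="old"))
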