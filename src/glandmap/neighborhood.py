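"""Delaunay cell-contact graphs and disease/healthy interaction fold changes.

Each tissue's segmented cells become nodes of an undirected graph whose edges
are the Delaunay triangulation edges; edges longer than the tissue's own
99th-percentile edge length are pruned as improbable contacts, and cells
labeled ``Unknown`` are excluded before triangulation.  Per condition, a
symmetric type x type interaction matrix counts edges between cell types
aggregated over tissues; the column-normalized disease matrix divided
elementwise by the column-normalized healthy matrix gives the fold-change
matrix, with values above 1 marking interactions more pronounced in disease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial import Delaunay, QhullError

from .tacit import UNKNOWN_LABEL

__all__ = [
    "CellGraph",
    "build_delaunay",
    "prune_edges",
    "interaction_matrix",
    "column_normalize",
    "normalize_and_fold_change",
    "InteractionModel",
    "InteractionResults",
]


@dataclass
class CellGraph:
    """Labeled cells of one tissue with undirected Delaunay proximity edges."""

    cells: pd.DataFrame  # cell_id, x, y, cell_type (index = positional)
    edges: pd.DataFrame  # i, j (positional into cells), length
    tissue_id: str = ""

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_types(self) -> pd.DataFrame:
        t = self.cells["cell_type"].to_numpy()
        return pd.DataFrame(
            {"type_i": t[self.edges["i"]], "type_j": t[self.edges["j"]]}
        )


def build_delaunay(
    cells: pd.DataFrame, tissue_id: str = "", drop_unknown: bool = True
) -> CellGraph | None:
    """Delaunay graph of one tissue's cells (columns cell_id, x, y, cell_type).

    Unknown-labeled (non-deconvoluted) cells are removed before
    triangulation; duplicate coordinates are deduplicated with a warning.
    Tissues with fewer than 3 usable cells, or with all cells collinear, are
    skipped (returns None) with a warning.
    """
    df = cells.reset_index(drop=True)
    if drop_unknown and "cell_type" in df:
        df = df[df["cell_type"] != UNKNOWN_LABEL].reset_index(drop=True)
    dup = df.duplicated(subset=["x", "y"])
    if dup.any():
        warnings.warn(
            f"tissue {tissue_id!r}: {int(dup.sum())} duplicate coordinate(s) dropped"
        )
        df = df[~dup].reset_index(drop=True)
    if len(df) < 3:
        warnings.warn(f"tissue {tissue_id!r}: fewer than 3 cells, skipped")
        return None
    pts = df[["x", "y"]].to_numpy(dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError:
        warnings.warn(f"tissue {tissue_id!r}: degenerate (collinear) geometry, skipped")
        return None
    simplex_edges = np.vstack(
        [tri.simplices[:, [0, 1]], tri.simplices[:, [1, 2]], tri.simplices[:, [0, 2]]]
    )
    simplex_edges.sort(axis=1)
    uniq = np.unique(simplex_edges, axis=0)
    lengths = np.linalg.norm(pts[uniq[:, 0]] - pts[uniq[:, 1]], axis=1)
    edges = pd.DataFrame({"i": uniq[:, 0], "j": uniq[:, 1], "length": lengths})
    return CellGraph(cells=df, edges=edges, tissue_id=tissue_id)


def prune_edges(graph: CellGraph, percentile: float = 99.0) -> CellGraph:
    """Remove edges longer than the tissue's own edge-length percentile.

    The threshold is the linear-interpolation quantile of this graph's edge
    lengths; edges strictly longer are removed, so ``percentile=100`` is the
    identity.
    """
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    thr = float(np.percentile(graph.edges["length"], percentile))
    kept = graph.edges[graph.edges["length"] <= thr].reset_index(drop=True)
    return CellGraph(cells=graph.cells, edges=kept, tissue_id=graph.tissue_id)


def interaction_matrix(
    graphs: list[CellGraph], cell_types: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric type x type edge-count matrix aggregated over tissues.

    Entry (i, j) counts edges whose endpoint types are {i, j}; a same-type
    edge adds 1 to the diagonal, a cross-type edge adds 1 to both (i, j) and
    (j, i).
    """
    if cell_types is None:
        cell_types = sorted(
            {t for g in graphs for t in g.cells["cell_type"].unique()}
        )
    M = pd.DataFrame(0, index=cell_types, columns=cell_types, dtype=float)
    for g in graphs:
        et = g.edge_types()
        for (a, b), n in et.value_counts().items():
            if a == b:
                M.loc[a, a] += n
            else:
                M.loc[a, b] += n
                M.loc[b, a] += n
    return M


def column_normalize(M: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to sum 1; all-zero columns stay zero."""
    sums = M.sum(axis=0)
    out = M.divide(sums.where(sums > 0, 1.0), axis=1)
    out.loc[:, sums == 0] = 0.0
    return out


def normalize_and_fold_change(
    healthy: pd.DataFrame, disease: pd.DataFrame, pseudocount: float = 0.0
) -> pd.DataFrame:
    """Column-normalize both matrices and divide disease by healthy.

    Matrices are aligned on the union of cell types (missing types get zero
    rows/columns).  Entries with a zero healthy denominator are reported as
    missing (NaN), never infinity; a positive ``pseudocount`` added to the
    raw counts before normalization yields dense output instead.
    """
    types = sorted(set(healthy.index) | set(disease.index))
    H = healthy.reindex(index=types, columns=types, fill_value=0.0) + pseudocount
    D = disease.reindex(index=types, columns=types, fill_value=0.0) + pseudocount
    Hn, Dn = column_normalize(H), column_normalize(D)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = Dn.to_numpy() / Hn.to_numpy()
    fc = np.where(Hn.to_numpy() > 0, fc, np.nan)
    return pd.DataFrame(fc, index=types, columns=types)


@dataclass
class InteractionResults:
    """Per-condition interaction matrices, their normalized forms and FC."""

    raw: dict[str, pd.DataFrame]
    normalized: dict[str, pd.DataFrame]
    fold_change: pd.DataFrame
    condition_pair: tuple[str, str]  # (disease, healthy)
    graphs: dict[str, list[CellGraph]] = field(default_factory=dict)
    percentile: float = 99.0
    cluster_order: list[str] | None = None

    def summary(self) -> str:
        d, h = self.condition_pair
        n_edges = {c: sum(g.n_edges for g in gs) for c, gs in self.graphs.items()}
        fc = self.fold_change
        finite = fc.to_numpy()[np.isfinite(fc.to_numpy())]
        lines = [
            "Delaunay interaction analysis",
            f"  conditions: disease={d!r} healthy={h!r}   "
            f"edge-length pruning: {self.percentile:g}th percentile per tissue",
            f"  edges after pruning: "
            + ", ".join(f"{c}: {n}" for c, n in n_edges.items()),
            f"  fold-change entries > 1: {int((finite > 1).sum())} / {finite.size} "
            f"defined",
        ]
        if self.cluster_order:
            lines.append(f"  hierarchical ordering: {self.cluster_order}")
        return "\n".join(lines)


class InteractionModel:
    """Interaction fold-change model over tissues of two conditions.

    Parameters
    ----------
    cells : DataFrame with columns cell_id, x, y, tissue_id, condition,
        cell_type (one row per segmented cell).
    condition_pair : (disease_label, healthy_label); fold change is
        disease / healthy after column normalization.
    """

    def __init__(self, cells: pd.DataFrame, condition_pair: tuple[str, str]):
        required = {"x", "y", "tissue_id", "condition", "cell_type"}
        missing = required - set(cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns: {sorted(missing)}")
        self.cells = cells
        self.condition_pair = tuple(condition_pair)

    def fit(
        self, percentile: float = 99.0, pseudocount: float = 0.0
    ) -> InteractionResults:
        disease_label, healthy_label = self.condition_pair
        graphs: dict[str, list[CellGraph]] = {}
        for (tissue, condition), sub in self.cells.groupby(
            ["tissue_id", "condition"], sort=True
        ):
            g = build_delaunay(sub, tissue_id=str(tissue))
            if g is None or g.n_edges == 0:
                continue
            graphs.setdefault(str(condition), []).append(
                prune_edges(g, percentile=percentile)
            )
        types = sorted(
            t
            for t in self.cells["cell_type"].unique()
            if t != UNKNOWN_LABEL
        )
        raw = {
            c: interaction_matrix(gs, cell_types=types) for c, gs in graphs.items()
        }
        for label in self.condition_pair:
            raw.setdefault(
                label, pd.DataFrame(0.0, index=types, columns=types)
            )
        normalized = {c: column_normalize(M) for c, M in raw.items()}
        fc = normalize_and_fold_change(
            raw[healthy_label], raw[disease_label], pseudocount=pseudocount
        )
        order = _cluster_order(fc)
        return InteractionResults(
            raw=raw,
            normalized=normalized,
            fold_change=fc,
            condition_pair=self.condition_pair,
            graphs=graphs,
            percentile=percentile,
            cluster_order=order,
        )


def _cluster_order(fc: pd.DataFrame) -> list[str] | None:
    """Euclidean hierarchical-clustering leaf order of the FC rows.

    Provided as ordering metadata only (no rendering).  Undefined entries are
    imputed at 1 (no change) purely for the ordering; returns None for
    matrices too small to cluster.
    """
    if len(fc) < 3:
        return None
    X = np.nan_to_num(fc.to_numpy(), nan=1.0)
    link = sch.linkage(X, method="average", metric="euclidean")
    leaves = sch.leaves_list(link)
    return [fc.index[i] for i in leaves]
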