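"""TACIT: threshold-based cell-type annotation for multiplex marker intensities.

Given a cell x marker intensity table and a marker x cell-type signature
matrix, TACIT scores each cell for each type with a Cell Type Relevance (CTR)
score — the dot product of the cell's Z-normalized intensities with the
type's signature column — and then discovers, per type, a data-driven CTR
cutoff:

1. cells are grouped into many small seed clusters (k-means, averaging 0.5%
   of cells each);
2. the cluster-median CTR scores are sorted ascending into a ranked curve;
3. segmented (piecewise-linear) regression with up to three breakpoints is
   fitted to the curve, the breakpoint count chosen by AIC;
4. clusters ranking at or below the lowest breakpoint form the low-relevance
   group (LRG), clusters above the highest breakpoint the high-relevance
   group (HRG);
5. the CTR value minimizing the cell-level classification error between LRG
   and HRG cells becomes the type's cutoff.

A binary cell-type matrix (CTM) marks every type whose cutoff a cell passes.
Subtype columns carrying level>=2 markers in the signature (e.g. CD4 for
helper T within T cells) are refined with an AND gate against single-marker
positivity, whose cutoff is derived by the same steps 2-5 run on that one
marker.  Cells left with multiple identities are reassigned by majority vote
of their k nearest "clean" neighbors in the subspace of the contending
types' defining markers; cells passing no cutoff are labeled ``Unknown``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .segmented import SegmentedRegression, SegmentedRegressionResults

__all__ = [
    "SignatureMatrix",
    "TACITModel",
    "TACITResults",
    "znormalize_intensities",
    "compute_ctr",
    "seed_cluster",
    "fit_breakpoints",
    "classify_lrg_hrg",
    "find_cutoff",
    "assign_primary",
    "UNKNOWN_LABEL",
]

UNKNOWN_LABEL = "Unknown"


class SignatureMatrix:
    """Marker x cell-type matrix with integer granularity levels.

    Entry 0 means the marker does not define the type; 1 marks a defining
    marker at the base hierarchy level; an integer L >= 2 marks a marker that
    splits a parent type at granularity level L (CD4/CD8 within T cells being
    the canonical example).
    """

    def __init__(self, table: pd.DataFrame):
        vals = table.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(vals != vals.astype(int)):
            raise ValueError("signature entries must be integers")
        if np.any(vals < 0):
            raise ValueError("signature levels must be non-negative integers")
        if np.any((vals >= 1).sum(axis=0) == 0):
            bad = table.columns[(vals >= 1).sum(axis=0) == 0].tolist()
            raise ValueError(f"cell types without any defining marker: {bad}")
        self.table = table.astype(int)

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @property
    def markers(self) -> pd.Index:
        return self.table.index

    @property
    def cell_types(self) -> pd.Index:
        return self.table.columns

    def binarized(self) -> pd.DataFrame:
        """0/1 form used for CTR scoring: any level >= 1 counts as defining."""
        return (self.table >= 1).astype(float)

    def defining_markers(self, cell_type: str) -> list[str]:
        col = self.table[cell_type]
        return col.index[col >= 1].tolist()

    def level_markers(self, cell_type: str, min_level: int = 2) -> list[str]:
        """Markers gating this type at deeper granularity (level >= 2)."""
        col = self.table[cell_type]
        return col.index[col >= min_level].tolist()

    @property
    def subtype_columns(self) -> list[str]:
        return [t for t in self.cell_types if self.level_markers(t)]


def znormalize_intensities(table: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each marker column (mean 0, SD 1) across cells.

    Zero-variance markers become all-zero columns with a warning; non-numeric
    columns are an error naming the column.
    """
    for col in table.columns:
        if not np.issubdtype(table[col].dtype, np.number):
            raise ValueError(f"non-numeric intensity column: {col!r}")
    X = table.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    flat = sd <= 1e-12 * np.maximum(np.abs(mu), 1.0)
    if flat.any():
        warnings.warn(f"zero-variance marker(s): {table.columns[flat].tolist()}")
    Z = (X - mu) / np.where(flat, 1.0, sd)
    Z[:, flat] = 0.0
    return pd.DataFrame(Z, index=table.index, columns=table.columns)


def compute_ctr(Z: pd.DataFrame, signature: SignatureMatrix) -> pd.DataFrame:
    """CTR = Z x binarized(signature), aligned on marker names."""
    shared = Z.columns.intersection(signature.markers)
    if len(shared) == 0:
        raise ValueError("no markers shared between intensities and signature")
    B = signature.binarized().loc[shared]
    ctr = Z[shared].to_numpy() @ B.to_numpy()
    return pd.DataFrame(ctr, index=Z.index, columns=signature.cell_types)


def seed_cluster(
    Z: pd.DataFrame, target_fraction: float = 0.005, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Group cells into ~round(1/target_fraction) small k-means seed clusters.

    When ``k`` would exceed the cell count it is reduced to ``n_cells``
    (singleton clusters) with a warning.
    """
    n = len(Z)
    if n < 1 or not 0 < target_fraction <= 1:
        raise ValueError("need cells and a target_fraction in (0, 1]")
    k = int(round(1.0 / target_fraction))
    if k > n:
        warnings.warn(f"k={k} exceeds n_cells={n}; reducing to n_cells")
        k = n
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=1)
    labels = km.fit_predict(Z.to_numpy())
    return labels, k


def fit_breakpoints(
    curve: np.ndarray, max_bp: int = 3, min_seg: int | None = None
) -> SegmentedRegressionResults:
    """AIC-selected segmented fit to an ascending-sorted cluster-median curve."""
    curve = np.asarray(curve, dtype=float)
    if np.any(np.diff(curve) < 0):
        raise ValueError("curve must be sorted ascending")
    return SegmentedRegression(curve, max_breakpoints=max_bp, min_seg=min_seg).fit()


def classify_lrg_hrg(
    fit: SegmentedRegressionResults, ranked_clusters: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split ranked clusters into LRG / HRG around the outermost breakpoints.

    ``ranked_clusters`` lists cluster ids in ascending median-CTR order (rank
    1..n).  LRG = ranks at or below the lowest breakpoint (ties join the
    lower group), HRG = ranks strictly above the highest breakpoint; clusters
    in between stay unassigned at this stage.
    """
    if fit.n_breakpoints == 0:
        raise ValueError("no breakpoints: type is non-separable, no cutoff derivable")
    ranks = np.arange(1, len(ranked_clusters) + 1)
    lo, hi = fit.breakpoints[0], fit.breakpoints[-1]
    lrg = ranked_clusters[ranks <= lo]
    hrg = ranked_clusters[ranks > hi]
    return lrg, hrg


def find_cutoff(values: np.ndarray, is_hrg: np.ndarray) -> float:
    """CTR cutoff minimizing cell-level LRG/HRG classification error.

    Candidates are the midpoints between consecutive distinct sorted values;
    error(c) = (#HRG cells with value < c + #LRG cells with value >= c) / n.
    The lowest error-minimizing candidate is returned.
    """
    values = np.asarray(values, dtype=float)
    is_hrg = np.asarray(is_hrg, dtype=bool)
    if not is_hrg.any() or is_hrg.all():
        raise ValueError("both LRG and HRG must be non-empty")
    distinct = np.unique(values)
    if distinct.size == 1:
        return float(distinct[0])
    cands = 0.5 * (distinct[:-1] + distinct[1:])
    hrg_sorted = np.sort(values[is_hrg])
    lrg_sorted = np.sort(values[~is_hrg])
    n = values.size
    # hrg below c  +  lrg at-or-above c
    err = (
        np.searchsorted(hrg_sorted, cands, side="left")
        + (lrg_sorted.size - np.searchsorted(lrg_sorted, cands, side="left"))
    ) / n
    return float(cands[int(np.argmin(err))])  # argmin takes the first (lowest) tie


def assign_primary(ctr: pd.DataFrame, cutoffs: dict[str, float]) -> pd.DataFrame:
    """Binary CTM: 1 where a cell's CTR passes the type's cutoff (inclusive).

    Types without a derivable cutoff get an all-zero column.
    """
    ctm = pd.DataFrame(0, index=ctr.index, columns=ctr.columns, dtype=np.int8)
    for t, c in cutoffs.items():
        if c is not None:
            ctm[t] = (ctr[t] >= c).astype(np.int8)
    return ctm


@dataclass
class TACITResults:
    """Per-cell labels plus every intermediate TACIT artifact."""

    labels: pd.Series
    ctm: pd.DataFrame  # refined binary cell-type matrix
    ctm_primary: pd.DataFrame
    ctr: pd.DataFrame
    cutoffs: dict[str, float | None]
    marker_cutoffs: dict[str, float | None]
    fits: dict[str, SegmentedRegressionResults]
    marker_fits: dict[str, SegmentedRegressionResults] = field(default_factory=dict)
    seed_labels: np.ndarray = None
    non_separable: list[str] = field(default_factory=list)

    @property
    def n_unknown(self) -> int:
        return int((self.labels == UNKNOWN_LABEL).sum())

    def label_counts(self) -> pd.Series:
        return self.labels.value_counts()

    def summary(self) -> str:
        lines = [
            "TACIT cell-type annotation",
            f"  cells: {len(self.labels)}   types: {self.ctr.shape[1]}"
            f"   seed clusters: {len(np.unique(self.seed_labels))}",
            f"  unknown cells: {self.n_unknown}",
        ]
        if self.non_separable:
            lines.append(f"  non-separable types (no breakpoint): {self.non_separable}")
        lines.append("  cutoffs:")
        for t in self.ctr.columns:
            c = self.cutoffs.get(t)
            fit = self.fits.get(t)
            bp = fit.n_breakpoints if fit is not None else "-"
            cut = f"{c:.4f}" if c is not None else "none"
            lines.append(f"    {t}: cutoff={cut} (breakpoints={bp})")
        lines.append("  label counts:")
        for t, n in self.label_counts().items():
            lines.append(f"    {t}: {n}")
        return "\n".join(lines)


class TACITModel:
    """TACIT annotation model for one intensity table and signature matrix.

    Parameters
    ----------
    intensities : cell x marker table of raw intensities (index = cell ids);
        coordinate columns listed in ``coord_cols`` are split off if present.
    signature : SignatureMatrix (or markers x types DataFrame).
    target_fraction : mean seed-cluster size as a fraction of cells (0.005).
    max_breakpoints : cap on segmented-regression knots (3).
    knn_k : neighbor count for mixed-identity resolution (15).
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        signature: SignatureMatrix | pd.DataFrame,
        target_fraction: float = 0.005,
        max_breakpoints: int = 3,
        min_seg: int | None = None,
        knn_k: int = 15,
        coord_cols: tuple[str, ...] = ("x", "y"),
    ):
        if isinstance(signature, pd.DataFrame):
            signature = SignatureMatrix(signature)
        self.signature = signature
        drop = [c for c in coord_cols if c in intensities.columns]
        self.coords = intensities[drop].copy() if drop else None
        self.intensities = intensities.drop(columns=drop)
        self.target_fraction = target_fraction
        self.max_breakpoints = max_breakpoints
        self.min_seg = min_seg
        self.knn_k = knn_k

    # -- stages -------------------------------------------------------------

    def _derive_cutoff(
        self, cell_values: pd.Series, seed_labels: np.ndarray
    ) -> tuple[float | None, SegmentedRegressionResults]:
        """Steps 2-5 for one score vector (a CTR column or a single marker)."""
        medians = (
            pd.Series(cell_values.to_numpy(), name="v")
            .groupby(seed_labels)
            .median()
            .sort_values(kind="mergesort")
        )
        fit = fit_breakpoints(
            medians.to_numpy(), max_bp=self.max_breakpoints, min_seg=self.min_seg
        )
        if fit.n_breakpoints == 0:
            return None, fit
        lrg, hrg = classify_lrg_hrg(fit, medians.index.to_numpy())
        in_lrg = np.isin(seed_labels, lrg)
        in_hrg = np.isin(seed_labels, hrg)
        mask = in_lrg | in_hrg
        cutoff = find_cutoff(cell_values.to_numpy()[mask], in_hrg[mask])
        return cutoff, fit

    def _refine_granularity(
        self, ctm: pd.DataFrame, Z: pd.DataFrame, seed_labels: np.ndarray
    ) -> tuple[pd.DataFrame, dict, dict]:
        """AND-gate subtype columns with single-marker positivity.

        Each level>=2 marker of a subtype receives its own cutoff (steps 2-5
        on that marker alone); a cell keeps the subtype only if it passed the
        subtype's CTR gate (parent membership) AND every deep marker is at or
        above its cutoff.  Markers whose curve yields no breakpoint leave the
        column unrefined, with a warning.
        """
        ctm = ctm.copy()
        marker_cutoffs: dict[str, float | None] = {}
        marker_fits: dict[str, SegmentedRegressionResults] = {}
        for t in self.signature.subtype_columns:
            positive = np.ones(len(ctm), dtype=bool)
            refinable = True
            for m in self.signature.level_markers(t):
                if m not in marker_cutoffs:
                    cutoff, fit = self._derive_cutoff(Z[m], seed_labels)
                    marker_cutoffs[m] = cutoff
                    marker_fits[m] = fit
                    if cutoff is None:
                        warnings.warn(
                            f"marker {m!r}: no breakpoint on its ranked curve; "
                            f"subtype columns using it are left unrefined"
                        )
                cutoff = marker_cutoffs[m]
                if cutoff is None:
                    refinable = False
                    break
                positive &= Z[m].to_numpy() >= cutoff
            if refinable:
                ctm[t] = (ctm[t].to_numpy().astype(bool) & positive).astype(np.int8)
        return ctm, marker_cutoffs, marker_fits

    def _resolve_mixed(self, ctm: pd.DataFrame, Z: pd.DataFrame) -> pd.Series:
        """Final single label per cell via KNN among clean cells.

        Mixed cells are projected onto the union of the contending types'
        defining markers; the majority label of the k nearest clean cells of
        those types wins, ties going to the single nearest neighbor.
        """
        M = ctm.to_numpy().astype(bool)
        n_types_hit = M.sum(axis=1)
        labels = pd.Series(UNKNOWN_LABEL, index=ctm.index, dtype=object)
        clean = n_types_hit == 1
        type_names = np.asarray(ctm.columns)
        labels[clean] = type_names[np.argmax(M[clean], axis=1)]

        clean_by_type = {
            t: np.flatnonzero(clean & M[:, j]) for j, t in enumerate(type_names)
        }
        mixed_idx = np.flatnonzero(n_types_hit >= 2)
        if mixed_idx.size == 0:
            return labels
        if not clean.any():
            warnings.warn("no clean cells at all; every mixed cell labeled Unknown")
            return labels

        # group mixed cells by their contending type set to share KNN models
        groups: dict[tuple[str, ...], list[int]] = {}
        for i in mixed_idx:
            key = tuple(type_names[M[i]])
            groups.setdefault(key, []).append(i)

        Zv = Z.to_numpy()
        marker_pos = {m: j for j, m in enumerate(Z.columns)}
        for key, rows in groups.items():
            contenders = [t for t in key if clean_by_type[t].size > 0]
            if len(contenders) < len(key):
                missing = sorted(set(key) - set(contenders))
                warnings.warn(f"types without clean cells excluded for KNN: {missing}")
            if not contenders:
                continue  # stays Unknown
            feats = sorted(
                {m for t in contenders for m in self.signature.defining_markers(t)}
            )
            fcols = [marker_pos[m] for m in feats if m in marker_pos]
            ref_rows = np.concatenate([clean_by_type[t] for t in contenders])
            ref_labels = np.concatenate(
                [np.repeat(t, clean_by_type[t].size) for t in contenders]
            )
            k = min(self.knn_k, ref_rows.size)
            nn = NearestNeighbors(n_neighbors=k).fit(Zv[np.ix_(ref_rows, fcols)])
            _, nbr = nn.kneighbors(Zv[np.ix_(rows, fcols)])
            for r, nb in zip(rows, nbr):
                votes = pd.Series(ref_labels[nb]).value_counts()
                top = votes.max()
                winners = votes.index[votes == top]
                labels.iloc[r] = (
                    winners[0] if len(winners) == 1 else ref_labels[nb[0]]
                )
        return labels

    # -- public -------------------------------------------------------------

    def fit(self, seed: int = 0) -> TACITResults:
        Z = znormalize_intensities(self.intensities)
        ctr = compute_ctr(Z, self.signature)
        seed_labels, _ = seed_cluster(Z, self.target_fraction, seed=seed)

        cutoffs: dict[str, float | None] = {}
        fits: dict[str, SegmentedRegressionResults] = {}
        non_separable: list[str] = []
        for t in ctr.columns:
            cutoff, fit = self._derive_cutoff(ctr[t], seed_labels)
            cutoffs[t] = cutoff
            fits[t] = fit
            if cutoff is None:
                non_separable.append(t)
                warnings.warn(f"cell type {t!r} non-separable (0 breakpoints); "
                              f"its CTM column is zeroed")

        ctm_primary = assign_primary(ctr, cutoffs)
        ctm, marker_cutoffs, marker_fits = self._refine_granularity(
            ctm_primary, Z, seed_labels
        )
        labels = self._resolve_mixed(ctm, Z)
        return TACITResults(
            labels=labels,
            ctm=ctm,
            ctm_primary=ctm_primary,
            ctr=ctr,
            cutoffs=cutoffs,
            marker_cutoffs=marker_cutoffs,
            fits=fits,
            marker_fits=marker_fits,
            seed_labels=seed_labels,
            non_separable=non_separable,
        )
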