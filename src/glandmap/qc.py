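"""Per-cell (and per-spot) quality-control gating of expression matrices.

Cells are gated on mitochondrial, ribosomal and hemoglobin read fractions and
on minimum detected-gene and total-count thresholds.  The defaults —
mito < 15%, ribo < 50%, hemoglobin < 5%, genes >= 10, counts >= 100 — are the
standard gates for salivary-gland single-cell data; spatial spots are gated
identically.  Percent gates are strict upper bounds (a cell at exactly 15%
mitochondrial reads is removed), count gates are inclusive lower bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QCThresholds",
    "QCReport",
    "compute_qc_metrics",
    "gate_cells",
    "infer_gene_classes",
    "DEFAULT_HEMOGLOBIN_GENES",
]

DEFAULT_HEMOGLOBIN_GENES = frozenset(
    {"HBA1", "HBA2", "HBB", "HBD", "HBE1", "HBG1", "HBG2", "HBM", "HBQ1", "HBZ"}
)

_PCT_RULES = {"mito": "max_mito_pct", "ribo": "max_ribo_pct", "hb": "max_hb_pct"}


@dataclass(frozen=True)
class QCThresholds:
    """Gate thresholds. Percents are strict upper bounds, counts inclusive."""

    max_mito_pct: float = 15.0
    max_ribo_pct: float = 50.0
    max_hb_pct: float = 5.0
    min_genes: int = 10
    min_counts: int = 100

    def __post_init__(self):
        for name in ("max_mito_pct", "max_ribo_pct", "max_hb_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.min_genes < 0 or self.min_counts < 0:
            raise ValueError("count thresholds must be >= 0")


@dataclass
class QCReport:
    """Per-cell QC metrics, pass flags and per-rule exclusion tallies."""

    metrics: pd.DataFrame  # total_counts, n_genes, pct_<class> per cell
    passed: pd.Series  # overall boolean flag per cell
    rule_pass: pd.DataFrame  # per-rule boolean flags
    tally: pd.Series = field(default=None)  # per-rule failure counts

    @property
    def n_failed(self) -> int:
        return int((~self.passed).sum())


def infer_gene_classes(gene_names) -> dict[str, list[str]]:
    """Default symbol-based gene classes for human data.

    ``MT-`` prefix for mitochondrial, ``RPS``/``RPL`` for ribosomal, and an
    explicit hemoglobin symbol list. Synthetic fixtures instead carry their
    class lists explicitly, so nothing here depends on prefixes downstream.
    """
    names = pd.Index(gene_names)
    return {
        "mito": names[names.str.startswith("MT-")].tolist(),
        "ribo": names[names.str.startswith(("RPS", "RPL"))].tolist(),
        "hb": names[names.isin(DEFAULT_HEMOGLOBIN_GENES)].tolist(),
    }


def _counts(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    if sp.issparse(X):
        return X.tocsr()
    return sp.csr_matrix(np.asarray(X))


def compute_qc_metrics(
    adata: AnnData, gene_classes: dict[str, list[str]] | None = None,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Compute per-cell QC percentages/counts and evaluate each gate.

    ``pct_<class>`` is 100 x (counts over class genes) / (total counts); a
    zero-count cell gets pct 0 (it fails the min_counts gate instead of
    raising a division error).  Class genes missing from the matrix are
    allowed and warned about.
    """
    thresholds = thresholds or QCThresholds()
    if gene_classes is None:
        gene_classes = infer_gene_classes(adata.var_names)
    X = _counts(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()

    metrics = pd.DataFrame(
        {"total_counts": total, "n_genes": n_genes}, index=adata.obs_names
    )
    safe_total = np.where(total > 0, total, 1.0)
    for cls, genes in gene_classes.items():
        present = adata.var_names.isin(genes)
        n_missing = len(set(genes)) - int(present.sum())
        if n_missing:
            warnings.warn(
                f"gene class {cls!r}: {n_missing} listed gene(s) absent from matrix"
            )
        class_sum = (
            np.asarray(X[:, present].sum(axis=1)).ravel() if present.any() else 0.0
        )
        pct = 100.0 * class_sum / safe_total
        metrics[f"pct_{cls}"] = np.where(total > 0, pct, 0.0)

    rule_pass = pd.DataFrame(index=adata.obs_names)
    for cls, attr in _PCT_RULES.items():
        col = f"pct_{cls}"
        if col in metrics:
            rule_pass[cls] = metrics[col] < getattr(thresholds, attr)
    rule_pass["min_genes"] = metrics["n_genes"] >= thresholds.min_genes
    rule_pass["min_counts"] = metrics["total_counts"] >= thresholds.min_counts

    passed = rule_pass.all(axis=1)
    tally = (~rule_pass).sum(axis=0)
    return QCReport(metrics=metrics, passed=passed, rule_pass=rule_pass, tally=tally)


def gate_cells(
    adata: AnnData,
    gene_classes: dict[str, list[str]] | None = None,
    thresholds: QCThresholds | None = None,
    report: QCReport | None = None,
) -> tuple[AnnData, pd.DataFrame]:
    """Remove cells failing any gate; returns (filtered matrix, exclusion table).

    The retained subset preserves cell order. Removing every cell is a
    warning, not an error.
    """
    if report is None:
        report = compute_qc_metrics(adata, gene_classes, thresholds)
    keep = report.passed.to_numpy()
    excluded = report.metrics.loc[~report.passed].copy()
    failed_rules = (~report.rule_pass.loc[~report.passed]).apply(
        lambda r: ",".join(r.index[r]), axis=1
    )
    excluded["failed_rules"] = failed_rules if len(excluded) else pd.Series(dtype=object)
    if not keep.any():
        warnings.warn("QC gating removed every cell")
    return adata[keep].copy(), excluded
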