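"""Synthetic fixtures with known ground truth for every pipeline stage.

The generators emulate the shapes of the real inputs — multi-patient
single-cell count matrices with mitochondrial/ribosomal/hemoglobin gene
classes and planted QC violations, multiplex marker-intensity tables with
type-clustered coordinates, hexagonal-grid spot proportion tables with
planted cell-type colocalization, and ranked piecewise-linear curves with
known breakpoints — without simulating real salivary-gland biology (no
ambient RNA, doublets or segmentation artifacts).

Background counts follow a negative binomial with mean 1 and dispersion 0.5
so log-normalization downstream is meaningful; defining marker genes are
elevated in their type.  All randomness flows through one ``numpy`` generator
seeded from the config, so identical config + seed reproduces every fixture
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .tacit import SignatureMatrix

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "synth_expression",
    "synth_marker_table",
    "synth_spot_table",
    "synth_piecewise_curve",
    "example_signature",
    "DEFAULT_CELL_TYPES",
    "GROUP_LABELS",
]

GROUP_LABELS = ("SjD", "nonSjD")
QC_VIOLATION_KINDS = ("mito", "ribo", "hb", "low_genes", "low_counts")

# 8 salivary-gland populations with 3 defining genes each (expression space);
# Tex/Th share a lineage split mirrored by the CD4/CD8 protein signature
DEFAULT_CELL_TYPES: dict[str, list[str]] = {
    "SMAC": ["PRR4", "ZG16B", "LPO"],
    "Ductal": ["KRT19", "SLPI", "WFDC2"],
    "Tex": ["CD8A", "GZMK", "PDCD1"],
    "Th": ["CD4G", "IL7R", "CCR7"],
    "B": ["MS4A1", "CD79A", "CD19G"],
    "NK": ["NKG7", "KLRD1", "GNLY"],
    "Macrophage": ["CD68G", "C1QA", "LYZ"],
    "Endothelial": ["PECAM1", "VWF", "CLDN5"],
}

_CLASS_SIZES = {"mito": 10, "ribo": 10, "hb": 5}


def example_signature() -> SignatureMatrix:
    """Protein signature matching DEFAULT_CELL_TYPES, with a CD4/CD8 split.

    CD3 defines both T populations at level 1; CD4 and CD8 are level-2
    markers splitting helper (Th) from exhausted cytotoxic (Tex) T cells.
    """
    types = list(DEFAULT_CELL_TYPES)
    markers = [
        "AQP5", "PIP",          # SMAC
        "KRT7", "KRT19p",       # Ductal
        "CD3", "CD8", "CD4",    # T lineage + split
        "CD19", "CD20",         # B
        "CD56", "NCR1",         # NK
        "CD68", "CD163",        # Macrophage
        "CD31", "CD34",         # Endothelial
    ]
    S = pd.DataFrame(0, index=markers, columns=types, dtype=int)
    S.loc[["AQP5", "PIP"], "SMAC"] = 1
    S.loc[["KRT7", "KRT19p"], "Ductal"] = 1
    S.loc["CD3", ["Tex", "Th"]] = 1
    S.loc["CD8", "Tex"] = 2
    S.loc["CD4", "Th"] = 2
    S.loc[["CD19", "CD20"], "B"] = 1
    S.loc[["CD56", "NCR1"], "NK"] = 1
    S.loc[["CD68", "CD163"], "Macrophage"] = 1
    S.loc[["CD31", "CD34"], "Endothelial"] = 1
    return SignatureMatrix(S)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for all synthetic fixtures.

    Defaults describe a balanced two-group cohort (11 patients per group,
    mirroring an 11 vs 14 SjD/nonSjD study design; 400 cells per patient,
    200 genes) with strong marker signal
    (``marker_effect`` = 2.5 SD), moderate patient-level compositional
    variability, one disease-shifted cell type, and no planted QC violations.
    """

    seed: int = 0
    n_patients_per_group: int = 11
    n_cells_per_patient: int = 400
    n_genes: int = 200
    cell_types: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CELL_TYPES.items()}
    )
    marker_effect: float = 2.5
    noise_sd: float = 1.0
    qc_violation_rates: dict[str, float] = field(default_factory=dict)
    # expression background: NB(mean, dispersion alpha) with var = mu + alpha mu^2
    nb_mean: float = 1.0
    nb_dispersion: float = 0.5
    # group composition: patient type proportions ~ Dirichlet(conc * base);
    # disease shifts shifted_type up at the expense of donor_type (one-to-one
    # replacement of acinar cells by infiltrating lymphocytes), leaving the
    # remaining types untouched in expectation
    base_composition: dict[str, float] | None = None
    shifted_type: str | None = "Tex"
    donor_type: str | None = "SMAC"
    proportion_shift: float = 0.10
    patient_concentration: float = 50.0
    # spot fixtures
    n_spots_per_group: int = 150
    spot_pitch: float = 1.0
    colocalized_pairs: tuple[tuple[str, str], ...] = (("Tex", "SMAC"),)
    coloc_strength: float = 6.0
    niche_fraction: float = 0.4
    spot_alpha: float = 1.0
    # marker-table coordinates
    blob_sd: float = 1.5

    def __post_init__(self):
        if self.n_patients_per_group < 1 or self.n_cells_per_patient < 1:
            raise ValueError("counts must be positive")
        if self.n_genes < 1 or self.n_spots_per_group < 1:
            raise ValueError("counts must be positive")
        for kind, frac in self.qc_violation_rates.items():
            if kind not in QC_VIOLATION_KINDS:
                raise ValueError(f"unknown QC violation kind {kind!r}")
            if not 0 <= frac <= 1:
                raise ValueError(f"violation rate for {kind!r} outside [0, 1]")
        if self.niche_fraction < 0 or self.niche_fraction > 1:
            raise ValueError("niche_fraction outside [0, 1]")
        if self.shifted_type is not None and self.shifted_type not in self.cell_types:
            raise ValueError(f"shifted_type {self.shifted_type!r} not a cell type")
        if self.donor_type is not None and self.donor_type not in self.cell_types:
            raise ValueError(f"donor_type {self.donor_type!r} not a cell type")
        if self.base_composition is not None:
            if set(self.base_composition) != set(self.cell_types):
                raise ValueError("base_composition keys must match cell_types")
            if abs(sum(self.base_composition.values()) - 1.0) > 1e-9:
                raise ValueError("base_composition must sum to 1")
        for a, b in self.colocalized_pairs:
            if a not in self.cell_types or b not in self.cell_types:
                raise ValueError(f"colocalized pair ({a}, {b}) not in cell types")

    @property
    def n_cells(self) -> int:
        return 2 * self.n_patients_per_group * self.n_cells_per_patient

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted truth for one generated fixture."""

    cell_types: pd.Series | None = None  # per-cell true label
    qc_violations: pd.Series | None = None  # per-cell violation kind or "none"
    spot_proportions: pd.DataFrame | None = None  # per-spot true proportion rows
    colocalized_pairs: tuple[tuple[str, str], ...] = ()
    breakpoints: tuple[float, ...] = ()
    shifted_type: str | None = None
    donor_type: str | None = None
    proportion_shift: float = 0.0

    @property
    def shifted_types(self) -> set[str]:
        """Types whose group frequency was planted to differ (gainer + donor)."""
        if self.proportion_shift == 0:
            return set()
        return {t for t in (self.shifted_type, self.donor_type) if t is not None}


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------

def _gene_names(config: SynthConfig) -> tuple[list[str], dict[str, list[str]]]:
    classes = {
        cls: [f"{cls}_gene_{i+1}" for i in range(n)] for cls, n in _CLASS_SIZES.items()
    }
    marker_genes = [g for gs in config.cell_types.values() for g in gs]
    class_all = {g for gs in classes.values() for g in gs}
    overlap = class_all & set(marker_genes)
    if overlap:
        raise ValueError(f"marker genes overlap QC gene classes: {sorted(overlap)}")
    if len(set(marker_genes)) != len(marker_genes):
        raise ValueError("marker gene sets must be disjoint between cell types")
    n_special = sum(_CLASS_SIZES.values()) + len(marker_genes)
    n_bg = config.n_genes - n_special
    if n_bg < 1:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {n_special} class/marker genes"
        )
    background = [f"gene_{i+1:04d}" for i in range(n_bg)]
    names = (
        [g for gs in classes.values() for g in gs] + marker_genes + background
    )
    return names, classes


def _nb_counts(rng, mean, dispersion, size):
    """Negative binomial via its (n, p) parameterization; var = mu + a mu^2."""
    n = 1.0 / dispersion
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


# gland-like baseline: epithelium dominates, exhausted CD8 T cells are rare
_DEFAULT_COMPOSITION = {
    "SMAC": 0.30, "Ductal": 0.18, "Tex": 0.04, "Th": 0.12,
    "B": 0.08, "NK": 0.05, "Macrophage": 0.08, "Endothelial": 0.15,
}


def _group_composition(config: SynthConfig, group: str) -> np.ndarray:
    """Expected type composition for one group.

    In the disease group the shifted type gains ``proportion_shift`` taken
    entirely from the donor type (one-to-one replacement), so every other
    type keeps its baseline expectation.
    """
    types = list(config.cell_types)
    if config.base_composition is not None:
        base = np.array([config.base_composition[t] for t in types])
    elif set(types) == set(_DEFAULT_COMPOSITION):
        base = np.array([_DEFAULT_COMPOSITION[t] for t in types])
    else:
        base = np.full(len(types), 1.0 / len(types))
    if (
        config.shifted_type is not None
        and config.donor_type is not None
        and config.proportion_shift != 0
        and group == GROUP_LABELS[0]
    ):
        i = types.index(config.shifted_type)
        j = types.index(config.donor_type)
        if base[j] - config.proportion_shift <= 0:
            raise ValueError("proportion_shift exceeds the donor type's baseline")
        base = base.copy()
        base[i] += config.proportion_shift
        base[j] -= config.proportion_shift
    return base


def _patient_type_probs(rng, config: SynthConfig, group: str) -> np.ndarray:
    base = _group_composition(config, group)
    return rng.dirichlet(config.patient_concentration * base)


def _plant_qc_violations(rng, X: np.ndarray, config, classes, gene_index):
    """Overwrite disjoint cell subsets so each violates exactly one gate."""
    n_cells = X.shape[0]
    kinds, counts = [], []
    for kind in QC_VIOLATION_KINDS:
        rate = config.qc_violation_rates.get(kind, 0.0)
        c = int(round(rate * n_cells))
        if c:
            kinds.append(kind)
            counts.append(c)
    total = sum(counts)
    violations = pd.Series("none", index=range(n_cells), dtype=object)
    if total == 0:
        return violations
    if total > n_cells:
        raise ValueError("QC violation rates sum past 1")
    chosen = rng.choice(n_cells, size=total, replace=False)
    cls_cols = {c: [gene_index[g] for g in gs] for c, gs in classes.items()}
    class_all = sorted({j for cols in cls_cols.values() for j in cols})
    plain = [j for j in range(X.shape[1]) if j not in set(class_all)]
    # target class fractions comfortably past the 15/50/5 percent gates
    frac = {"mito": 0.25, "ribo": 0.65, "hb": 0.12}
    pos = 0
    for kind, c in zip(kinds, counts):
        for cell in chosen[pos : pos + c]:
            row = X[cell]
            if kind in frac:
                cols = cls_cols[kind]
                rest = row.sum() - row[cols].sum()
                target = frac[kind] * rest / (1 - frac[kind])
                per_gene = int(np.ceil(target / len(cols)))
                row[cols] = per_gene
            elif kind == "low_genes":
                keep = rng.choice(plain, size=5, replace=False)
                row[:] = 0
                row[keep] = 30  # 5 genes, 150 counts: fails only the gene gate
            elif kind == "low_counts":
                keep = rng.choice(plain, size=12, replace=False)
                row[:] = 0
                row[keep] = 4  # 12 genes, 48 counts: fails only the count gate
            violations.iloc[cell] = kind
        pos += c
    return violations


def synth_expression(config: SynthConfig) -> tuple[AnnData, GroundTruth]:
    """Multi-patient cell x gene count matrix with planted structure.

    Counts are NB(mean 1, dispersion 0.5) background with each type's marker
    genes elevated by ``marker_effect`` (added to the NB mean).  Patients are
    balanced across the SjD / nonSjD groups; the configured ``shifted_type``
    is more frequent in SjD patients by ``proportion_shift``.  A configured
    fraction of cells is overwritten to violate each QC gate; gene classes
    are carried explicitly in ``adata.uns['gene_classes']``.
    """
    rng = np.random.default_rng(config.seed)
    gene_names, classes = _gene_names(config)
    gene_index = {g: j for j, g in enumerate(gene_names)}
    types = list(config.cell_types)

    obs_rows = []
    for group in GROUP_LABELS:
        for p in range(config.n_patients_per_group):
            patient = f"{group}_p{p+1}"
            probs = _patient_type_probs(rng, config, group)
            tt = rng.choice(types, size=config.n_cells_per_patient, p=probs)
            for t in tt:
                obs_rows.append((patient, group, t))
    obs = pd.DataFrame(obs_rows, columns=["patient", "group", "true_type"])
    obs.index = [f"cell_{i+1:05d}" for i in range(len(obs))]

    n_cells, n_genes = len(obs), len(gene_names)
    mean = np.full((n_cells, n_genes), config.nb_mean)
    # hemoglobin lowly expressed in gland tissue so clean cells sit far from
    # the 5% gate
    hb_cols = [gene_index[g] for g in classes["hb"]]
    mean[:, hb_cols] = 0.2 * config.nb_mean
    for t, genes in config.cell_types.items():
        cols = [gene_index[g] for g in genes]
        rows = np.flatnonzero((obs["true_type"] == t).to_numpy())
        mean[np.ix_(rows, cols)] = config.nb_mean + config.marker_effect
    X = _nb_counts(rng, mean, config.nb_dispersion, (n_cells, n_genes)).astype(
        np.int64
    )

    violations = _plant_qc_violations(rng, X, config, classes, gene_index)
    violations.index = obs.index
    obs["qc_violation"] = violations

    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    var["gene_class"] = "none"
    for cls, gs in classes.items():
        var.loc[gs, "gene_class"] = cls
    marker_of = {
        g: t for t, gs in config.cell_types.items() for g in gs
    }
    var["marker_of"] = [marker_of.get(g, "") for g in gene_names]

    adata = AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    adata.uns["gene_classes"] = {c: list(gs) for c, gs in classes.items()}
    truth = GroundTruth(
        cell_types=obs["true_type"].copy(),
        qc_violations=obs["qc_violation"].copy(),
        shifted_type=config.shifted_type,
        donor_type=config.donor_type,
        proportion_shift=config.proportion_shift,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# marker-intensity fixtures
# ---------------------------------------------------------------------------

def synth_marker_table(
    config: SynthConfig,
    signature: SignatureMatrix,
    n_cells: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cell x marker intensity table with type-clustered 2-D coordinates.

    Each cell gets a true type drawn uniformly from the signature columns
    (which must be a subset of the configured cell types); markers defining
    that type (signature >= 1, so level-2 subtype markers are elevated only
    in their subtype) are N(marker_effect, 1), all others N(0, 1).
    Coordinates are Gaussian blobs per type on a grid so neighborhood
    analyses see planted spatial structure.
    """
    unknown = set(signature.cell_types) - set(config.cell_types)
    if unknown:
        raise ValueError(f"signature types not in config: {sorted(unknown)}")
    if n_cells is None:
        n_cells = config.n_cells
    rng = np.random.default_rng(config.seed)
    types = list(signature.cell_types)
    markers = list(signature.markers)
    cols = ["x", "y", *markers]
    if n_cells == 0:
        empty = pd.DataFrame(columns=cols, dtype=float)
        return empty, GroundTruth(cell_types=pd.Series(dtype=object))

    tt = rng.choice(types, size=n_cells)
    X = rng.normal(0.0, 1.0, size=(n_cells, len(markers)))
    B = signature.binarized().to_numpy()  # markers x types
    for j, t in enumerate(types):
        rows = np.flatnonzero(tt == t)
        on = np.flatnonzero(B[:, j] >= 1)
        X[np.ix_(rows, on)] += config.marker_effect

    # blob centers on a square grid spaced well apart relative to blob_sd
    side = int(np.ceil(np.sqrt(len(types))))
    centers = {
        t: (10.0 * (i % side), 10.0 * (i // side)) for i, t in enumerate(types)
    }
    ctr = np.array([centers[t] for t in tt])
    xy = ctr + rng.normal(0.0, config.blob_sd, size=(n_cells, 2))

    table = pd.DataFrame(
        np.column_stack([xy, X]),
        columns=cols,
        index=[f"cell_{i+1:05d}" for i in range(n_cells)],
    )
    truth = GroundTruth(cell_types=pd.Series(tt, index=table.index, name="true_type"))
    return table, truth


# ---------------------------------------------------------------------------
# spot fixtures
# ---------------------------------------------------------------------------

def _hex_grid(n: int, pitch: float) -> np.ndarray:
    """First n points of a hexagonally packed grid (unit = pitch)."""
    cols = int(np.ceil(np.sqrt(n)))
    pts = []
    r = 0
    while len(pts) < n:
        for c in range(cols):
            pts.append((pitch * (c + 0.5 * (r % 2)), pitch * r * np.sqrt(3) / 2))
        r += 1
    return np.array(pts[:n])


def synth_spot_table(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Hexagonal-grid spot x cell-type proportion table with planted niches.

    Proportions are Dirichlet(spot_alpha) per spot; in the disease group a
    ``niche_fraction`` of spots multiplies the concentration of each planted
    colocalized pair by ``coloc_strength``, coupling those two types within
    the same spots.  Rows sum to 1 exactly.
    """
    types = list(config.cell_types)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types for spot tables")
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in GROUP_LABELS:
        xy = _hex_grid(config.n_spots_per_group, config.spot_pitch)
        for i in range(config.n_spots_per_group):
            alpha = np.full(len(types), config.spot_alpha)
            if group == GROUP_LABELS[0] and rng.uniform() < config.niche_fraction:
                for a, b in config.colocalized_pairs:
                    alpha[types.index(a)] *= config.coloc_strength
                    alpha[types.index(b)] *= config.coloc_strength
            props = rng.dirichlet(alpha)
            rows.append(
                {
                    "spot_id": f"{group}_s{i+1:04d}",
                    "x": xy[i, 0],
                    "y": xy[i, 1],
                    "group": group,
                    **dict(zip(types, props)),
                }
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        spot_proportions=table.set_index("spot_id")[types].copy(),
        colocalized_pairs=tuple(config.colocalized_pairs),
    )
    return table, truth


# ---------------------------------------------------------------------------
# piecewise-curve fixtures
# ---------------------------------------------------------------------------

def synth_piecewise_curve(
    n_points: int,
    breakpoints: tuple[float, ...],
    slopes: tuple[float, ...],
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 0.0,
) -> np.ndarray:
    """Continuous piecewise-linear curve over ranks 1..n plus Gaussian noise.

    ``slopes`` gives one slope per segment (len(breakpoints) + 1 of them);
    breakpoints must be strictly increasing inside (1, n_points), at most 3.
    """
    breakpoints = tuple(float(b) for b in breakpoints)
    if not 0 <= len(breakpoints) <= 3:
        raise ValueError("0 to 3 breakpoints supported")
    if len(slopes) != len(breakpoints) + 1:
        raise ValueError("need one slope per segment")
    if any(b2 <= b1 for b1, b2 in zip(breakpoints, breakpoints[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    if any(not (1 < b < n_points) for b in breakpoints):
        raise ValueError("breakpoints must lie strictly inside (1, n_points)")
    x = np.arange(1, n_points + 1, dtype=float)
    y = intercept + slopes[0] * (x - 1)
    for b, (s_prev, s_next) in zip(breakpoints, zip(slopes, slopes[1:])):
        y += (s_next - s_prev) * np.maximum(x - b, 0.0)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    return y
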