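"""End-to-end pipeline: configuration, stage orchestration and run manifests.

A single ``PipelineConfig`` (YAML/JSON serializable, unknown keys rejected)
carries every stage toggle and threshold with the standard defaults
(QC gates 15/50/5/10/100, 0.5% seed-cluster fraction, up to 3 breakpoints,
k = 15 neighbors, 99th-percentile edge pruning, q < 0.05).  When input paths
are omitted the synthetic generators supply fixtures, so a full run is
possible from a config and a seed alone; every run emits a manifest with
config/input hashes sufficient to reproduce it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as gio
from . import synthetic
from .cooccurrence import CooccurrenceModel
from .neighborhood import InteractionModel
from .proportions import ProportionTest, proportion_table
from .qc import QCThresholds, compute_qc_metrics, gate_cells
from .sscore import GeneIndexCatalog, compute_sscores, lognormalize, zscore_genes
from .synthetic import SynthConfig, synth_expression, synth_marker_table, synth_spot_table
from .tacit import SignatureMatrix, TACITModel

__version__ = "0.1.0"

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    qc: bool = True
    sscore: bool = True
    tacit: bool = True
    cooccur: bool = True
    neighborhood: bool = True
    proportions: bool = True


class InputPaths(BaseModel):
    """Optional real-data entry points; synthetic fixtures fill any gaps."""

    model_config = ConfigDict(extra="forbid")
    expression_mtx: str | None = None
    expression_cells: str | None = None
    expression_genes: str | None = None
    markers_tsv: str | None = None
    signature_tsv: str | None = None
    spots_tsv: str | None = None
    neighborhood_cells_tsv: str | None = None
    gmt: str | None = None


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients_per_group: int = 11
    n_cells_per_patient: int = 400
    n_genes: int = 200
    marker_effect: float = 2.5
    proportion_shift: float = 0.15
    n_spots_per_group: int = 150
    tacit_cells: int = 5000


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "glandmap_out"
    stages: StageToggles = StageToggles()
    inputs: InputPaths = InputPaths()
    synth: SynthSection = SynthSection()
    # QC gates
    max_mito_pct: float = 15.0
    max_ribo_pct: float = 50.0
    max_hb_pct: float = 5.0
    min_genes: int = 10
    min_counts: int = 100
    # S-scores
    scale_total: float = 10_000.0
    # TACIT
    target_fraction: float = 0.005
    max_breakpoints: int = 3
    knn_k: int = 15
    # co-occurrence / neighborhood / proportions
    n_permutations: int = 1000
    percentile: float = 99.0
    alpha: float = 0.05
    annotation_col: str = "true_type"
    group_col: str = "group"
    patient_col: str = "patient"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_file(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            max_mito_pct=self.max_mito_pct,
            max_ribo_pct=self.max_ribo_pct,
            max_hb_pct=self.max_hb_pct,
            min_genes=self.min_genes,
            min_counts=self.min_counts,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class RunManifest(dict):
    """Run provenance: versions, hashes, timings, warnings, output hashes."""

    def write(self, path) -> None:
        gio.write_json(dict(self), path)


def _synth_config(cfg: PipelineConfig) -> SynthConfig:
    return SynthConfig(
        seed=cfg.seed,
        n_patients_per_group=cfg.synth.n_patients_per_group,
        n_cells_per_patient=cfg.synth.n_cells_per_patient,
        n_genes=cfg.synth.n_genes,
        marker_effect=cfg.synth.marker_effect,
        proportion_shift=cfg.synth.proportion_shift,
        n_spots_per_group=cfg.synth.n_spots_per_group,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write outputs.

    Order: QC gating, then S-scores (on the gated matrix), TACIT annotation,
    spot co-occurrence, neighborhood interaction fold change, and per-patient
    proportion tests.  A failing stage aborts with its name after persisting
    the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config=config.model_dump(),
        config_hash=config.config_hash(),
        input_hashes={},
        timings={},
        warnings=[],
        outputs={},
    )
    for name, path in config.inputs.model_dump().items():
        if path:
            manifest["input_hashes"][name] = gio.file_sha256(path)

    scfg = _synth_config(config)
    current = None

    def _stage(name):
        def deco(fn):
            if not getattr(config.stages, name):
                return
            t0 = time.perf_counter()
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                try:
                    fn()
                except Exception as e:
                    manifest["failed_stage"] = name
                    manifest.write(out / "manifest.json")
                    raise RuntimeError(f"stage {name!r} failed: {e}") from e
            manifest["warnings"].extend(f"{name}: {w.message}" for w in wlist)
            manifest["timings"][name] = round(time.perf_counter() - t0, 3)

        return deco

    # ---- expression input ----
    inp = config.inputs
    if inp.expression_mtx:
        adata = gio.read_expression(
            inp.expression_mtx, inp.expression_cells, inp.expression_genes
        )
    else:
        adata, _ = synth_expression(scfg)
    gene_classes = adata.uns.get("gene_classes")

    @_stage("qc")
    def _qc():
        nonlocal current
        report = compute_qc_metrics(adata, gene_classes, config.qc_thresholds())
        gated, excluded = gate_cells(
            adata, gene_classes, config.qc_thresholds(), report=report
        )
        current = gated
        gio.write_expression(
            gated, out / "gated.mtx", out / "gated_cells.tsv", out / "gated_genes.tsv"
        )
        gio.write_table(excluded, out / "qc_excluded.tsv")
        manifest["outputs"]["qc_retained"] = gated.n_obs
        manifest["outputs"]["qc_tally"] = report.tally.to_dict()

    if current is None:
        current = adata

    @_stage("sscore")
    def _sscore():
        logn = lognormalize(current, config.scale_total)
        Z = zscore_genes(logn)
        if inp.gmt:
            catalog = GeneIndexCatalog.from_gmt(inp.gmt)
        else:
            catalog = GeneIndexCatalog.from_dict(scfg.cell_types)
        S = compute_sscores(Z, catalog)
        gio.write_table(S, out / "sscores.tsv")
        manifest["outputs"]["sscore_indices"] = list(S.columns)

    # ---- marker-intensity input ----
    if inp.signature_tsv:
        signature = SignatureMatrix.from_tsv(inp.signature_tsv)
    else:
        signature = synthetic.example_signature()
    if inp.markers_tsv:
        markers = gio.read_table(inp.markers_tsv, index_col=0)
        marker_truth = None
    else:
        markers, marker_truth = synth_marker_table(
            scfg, signature, n_cells=config.synth.tacit_cells
        )

    tacit_res = None

    @_stage("tacit")
    def _tacit():
        nonlocal tacit_res
        model = TACITModel(
            markers,
            signature,
            target_fraction=config.target_fraction,
            max_breakpoints=config.max_breakpoints,
            knn_k=config.knn_k,
        )
        tacit_res = model.fit(seed=config.seed)
        gio.write_table(tacit_res.labels.to_frame("cell_type"), out / "tacit_labels.tsv")
        gio.write_table(tacit_res.ctm, out / "tacit_ctm.tsv")
        fits = {
            t: {
                "curve": f.y.tolist(),
                "aic_by_count": f.aic_by_count,
                "breakpoints": f.breakpoints.tolist(),
                "cutoff": tacit_res.cutoffs[t],
            }
            for t, f in tacit_res.fits.items()
        }
        gio.write_json(fits, out / "tacit_fits.json")
        manifest["outputs"]["tacit_label_counts"] = (
            tacit_res.label_counts().to_dict()
        )
        if marker_truth is not None:
            acc = float(
                (tacit_res.labels == marker_truth.cell_types).mean()
            )
            manifest["outputs"]["tacit_accuracy_vs_truth"] = round(acc, 4)

    @_stage("cooccur")
    def _cooccur():
        if inp.spots_tsv:
            spots = gio.read_table(inp.spots_tsv)
        else:
            spots, _ = synth_spot_table(scfg)
        res = CooccurrenceModel(
            spots, group_pair=synthetic.GROUP_LABELS
        ).fit(n_permutations=config.n_permutations, seed=config.seed)
        gio.write_table(res.differential, out / "cooccurrence_differential.tsv",
                        index=False)
        gio.write_table(res.per_spot, out / "cooccurrence_per_spot.tsv", index=False)
        top = res.top_pairs(1)
        if len(top):
            manifest["outputs"]["cooccur_top_pair"] = [
                top.iloc[0]["type_a"], top.iloc[0]["type_b"],
            ]

    @_stage("neighborhood")
    def _neighborhood():
        if inp.neighborhood_cells_tsv:
            cells = gio.read_table(inp.neighborhood_cells_tsv)
            pair = tuple(pd.unique(cells["condition"]))[:2]
        else:
            # two synthetic tissues: one per condition, truth-labeled cells
            t_d, tr_d = synth_marker_table(scfg, signature, n_cells=1500)
            t_h, tr_h = synth_marker_table(
                scfg.with_(seed=scfg.seed + 1), signature, n_cells=1500
            )
            cells = pd.concat(
                [
                    pd.DataFrame(
                        {
                            "cell_id": t.index,
                            "x": t["x"],
                            "y": t["y"],
                            "tissue_id": tid,
                            "condition": cond,
                            "cell_type": tr.cell_types,
                        }
                    )
                    for t, tr, tid, cond in [
                        (t_d, tr_d, "tissue_d", "disease"),
                        (t_h, tr_h, "tissue_h", "healthy"),
                    ]
                ],
                ignore_index=True,
            )
            pair = ("disease", "healthy")
        res = InteractionModel(cells, condition_pair=pair).fit(
            percentile=config.percentile
        )
        gio.write_table(res.fold_change, out / "interaction_fold_change.tsv")
        for cond, M in res.raw.items():
            gio.write_table(M, out / f"interaction_raw_{cond}.tsv")
        manifest["outputs"]["interaction_types"] = list(res.fold_change.columns)

    @_stage("proportions")
    def _proportions():
        obs = current.obs
        table = proportion_table(
            obs, patient_col=config.patient_col, type_col=config.annotation_col
        )
        groups = obs.groupby(config.patient_col, observed=True)[
            config.group_col
        ].first()
        res = ProportionTest(
            table, groups, group_pair=synthetic.GROUP_LABELS
        ).fit(alpha=config.alpha)
        gio.write_table(res.table, out / "proportion_tests.tsv")
        manifest["outputs"]["significant_types"] = list(res.significant)

    # output hashes make determinism auditable
    for f in sorted(out.glob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"].setdefault("file_hashes", {})[f.name] = (
                gio.file_sha256(f)
            )
    manifest.write(out / "manifest.json")
    return manifest
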