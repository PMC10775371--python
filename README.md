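# glandmap

Cell-type annotation and spatial statistics for salivary-gland tissue in
Sjögren's Disease (SjD) studies.

Modern SjD tissue studies combine single-cell RNA-seq, spot-based spatial
transcriptomics and multiplex proteomic imaging of the same minor salivary
glands.  Several of the key computations in that workflow are bespoke rather
than off-the-shelf, and `glandmap` packages them as tested, reusable pieces
for analysts working with such cohorts:

* **QC gating** of cells and spots on mitochondrial / ribosomal / hemoglobin
  read fractions and minimum genes/counts (defaults 15% / 50% / 5% / 10 /
  100; percent gates strict, count gates inclusive).
* **Gene-index S-scores**: with per-gene Z-scores `Z` and a binary
  gene × index encoding matrix `E`, `S = Z · E` — each cell's score for an
  index is the sum of its member-gene Z-scores (the 21-gene Type I IFN score
  is the one-index case).
* **TACIT annotation** of multiplex marker intensities: Cell Type Relevance
  scores `CTR = Z · signature`, ~0.5%-of-cells seed clusters, segmented
  (piecewise-linear) regression with AIC-selected breakpoints (≤ 3) on the
  ranked cluster-median CTR curve, a cutoff minimizing the classification
  error between the low- and high-relevance cluster groups, AND-gated
  CD4/CD8-style subtype refinement, and KNN resolution of mixed identities.
* **Within-spot co-occurrence** of deconvolved cell-type proportions,
  `C(κ₁, κ₂) = (κ₁ + κ₂)·exp(−3(κ₁ − κ₂)²)`, with group differentials and
  permutation p-values, plus within- and next-spot Pearson correlations on
  hexagonal spot grids.
* **Delaunay interaction graphs** per tissue with 99th-percentile edge
  pruning, symmetric type × type edge-count matrices, column normalization
  and disease/healthy fold change.
* **Per-patient proportion tests**: Welch t-tests with Benjamini–Hochberg
  correction, significance at q < 0.05.
* **Synthetic generators** for all of the above with known ground truth
  (planted QC violations, marker effects, colocalized pairs, breakpoints,
  proportion shifts), so every stage is testable end to end.

The fit-like stages follow a statsmodels-style layout: a model object built
from data (`TACITModel`, `SegmentedRegression`, `CooccurrenceModel`,
`InteractionModel`, `ProportionTest`) whose `fit()` returns a results object
with estimates, diagnostics and a `summary()`.

## Worked example

Annotate 5,000 synthetic cells (8 gland cell types, including a CD4/CD8
split of T cells) from their marker intensities, then test per-patient
composition between SjD and nonSjD groups:

```python
import glandmap as gm

cfg = gm.SynthConfig(seed=0)
sig = gm.example_signature()
table, truth = gm.synth_marker_table(cfg, sig, n_cells=5000)
res = gm.TACITModel(table, sig).fit(seed=0)
print("accuracy vs truth:", round(float((res.labels == truth.cell_types).mean()), 3))
print(res.summary())

adata, _ = gm.synth_expression(cfg)
gated, _ = gm.gate_cells(adata, adata.uns["gene_classes"])
prop = gm.proportion_table(gated.obs, "patient", "true_type")
groups = gated.obs.groupby("patient")["group"].first()
print(gm.ProportionTest(prop, groups, ("SjD", "nonSjD")).fit().summary())
```

prints

```
accuracy vs truth: 0.923
TACIT cell-type annotation
  cells: 5000   types: 8   seed clusters: 200
  unknown cells: 87
  cutoffs:
    SMAC: cutoff=1.2812 (breakpoints=3)
    Ductal: cutoff=1.3354 (breakpoints=3)
    Tex: cutoff=2.2702 (breakpoints=3)
    ...
Cell-type proportion comparison
  groups: 'SjD' (n=11) vs 'nonSjD' (n=11)
  test: Welch two-sided t, BH-adjusted, q < 0.05
  significant types: ['SMAC', 'Tex']
    Tex: mean_SjD=0.1568 mean_nonSjD=0.0511 fc=3.07 t=+4.274 p=0.0003715 q=0.001486
    SMAC: mean_SjD=0.2032 mean_nonSjD=0.3045 fc=0.667 t=-4.319 p=0.0003687 q=0.001486
    Macrophage: mean_SjD=0.0466 mean_nonSjD=0.0675 fc=0.69 t=-1.952 p=0.06503 q=0.1734
    ...
```

92% of cells recover their planted type; each cutoff was discovered from the
breakpoints of that type's ranked cluster-median CTR curve.  The proportion
test flags exactly the planted disease effect — exhausted CD8 T cells (Tex)
enriched ~3-fold in SjD at the expense of seromucous acinar cells (SMAC) —
and nothing else.

A command-line interface mirrors the library
(`glandmap synth|qc|sscore|tacit|cooccur|neighborhood|proportions|run`);
`glandmap run` executes the whole pipeline from a YAML config and writes a
manifest with config/input/output hashes for reproducibility.

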