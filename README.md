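# mnprof

Single-cell disease profiling of spinal motor neurons from high-content
morphology measurement tables.

Histopathology quantifies disease one marker at a time and averages over all
cells of an animal or donor — but diseased tissue is a *mixture*: healthy
and sick cells coexist in the same section, which dilutes every
population-average statistic. `mnprof` implements the downstream analysis
for studies that instead profile each segmented cell with hundreds of
morphological measurements (CellProfiler-style exports: area/shape
descriptors such as Zernike moments, texture statistics, and stain
intensities for markers like FUS, SFPQ, ChAT, DAPI) and then ask, cell by
cell, *is this motor neuron sick, and how sick?*

It is aimed at quantitative neuropathology / image-analysis groups working
with ALS mouse models (SOD1, VCP) or human post-mortem tissue, but nothing
in the pipeline is specific to those conditions beyond the contrast
definitions.

## What it computes

Given a cells × measurements table **X** and per-cell animal/condition
annotations, the pipeline runs:

1. **Standardization & spectra** — column z-scores, SVD
   `X = U Σ Vᵀ`, explained-variance fractions `p_i = σ_i² / Σσ²`, and the
   normalized Shannon entropy `H = −(1/ln r) Σ p_i ln p_i ∈ [0,1]` of the
   spectrum (how spread the morphological information is across orthogonal
   profiles).
2. **PC–phenotype association** — for each leading component score `y`,
   the random-intercept linear mixed model
   `y_ic = β₀ + β₁ x_c + a_s(c) + ε_ic`, `a_s ~ N(0, σ_a²)`,
   fitted by profile maximum likelihood and tested by a likelihood-ratio
   χ²(1) on β₁. The animal-level random intercept is essential: cells of one
   animal are pseudo-replicates, and a naive per-cell regression inflates
   the type-I error several-fold (demonstrated in the test suite).
   Contrasts: `comALS` (sod1 + vcp vs control), `vcpALS` (vcp vs rest),
   `sALS` (human sporadic ALS vs control).
3. **Healthy/sick classifiers** — a label-independent 2-component Gaussian
   mixture (EM) on selected PC scores, plus label-dependent L2-logistic
   regression (IRLS) and a one-hidden-layer MLP, with condition-censored
   variants (sLR/sMLP trained without sod1 cells to learn the vcp-specific
   phenotype). Every model yields a per-cell **disease profile** `(P, S)`:
   probability `P = logistic(S)` and the raw log-odds severity `S`, which
   still ranks cells whose probabilities have saturated at 1.
4. **Scoring** — per-animal mean P, mean S and % sick cells (P > 0.5);
   Welch's unequal-variance t tests between condition groups at the animal
   level; and a **re-labeling analysis**: Welch-test a marker (e.g. the
   SFPQ N/C ratio) grouped by tissue origin vs grouped by classifier calls
   — removing healthy-cell contamination sharpens the p-value.
5. **Contributions** — per-measurement relative contributions of each
   classifier (|β| for LR, loading-mapped discriminant direction for the
   GMM, path-weight products for the MLP), category-level mixed-model and
   permutation-z tests, top-k contributor ranking, N/C-ratio extraction.
6. **Clustering** — UPGMA (Euclidean, average linkage) of cells and of
   classifiers, with cluster-composition tables.

A seeded synthetic-data generator (`mnprof.simulate`) produces feature
tables with the same structure — animal offset profiles, healthy/sick
mixtures, a dominant vcp-like effect nested over a subtle shared effect,
category-structured measurement names — plus ground truth, so the whole
pipeline is testable without any data download.

## Worked example

```python
from mnprof import RunConfig, run_pipeline, n_components_for

res = run_pipeline(RunConfig(outdir="demo", seed=1, simulate={}))
d = res["decomposition"]
print(f"cells x measurements: {res['table'].n_cells} x {res['table'].n_measurements}")
print(f"spectrum entropy: {d.entropy:.3f}; components for 90% variance: {n_components_for(d, 0.9)}")
for scheme, assoc in res["associations"].items():
    print(f"{scheme}: significant PCs {assoc.selected_components}")
for name, auc in res["aucs"].items():
    print(f"AUC[{name}] = {auc:.2f}")
comps = res["comparisons"]
lr = comps[(comps.classifier_id == "lr") & (comps.metric == "mean_P")]
for _, r in lr.iterrows():
    print(f"Welch p (LR, {r['group']} vs control, per-animal mean P): {r['p_value']:.2e}")
```

prints (default synthetic scenario, seed 1):

```
cells x measurements: 124 x 750
spectrum entropy: 0.946; components for 90% variance: 94
comALS: significant PCs [2]
vcpALS: significant PCs [1, 10]
AUC[lr] = 1.00
AUC[mlp] = 1.00
AUC[gmm_com] = 0.87
AUC[slr] = 1.00
AUC[smlp] = 1.00
AUC[gmm_vcp] = 0.76
Welch p (LR, sod1 vs control, per-animal mean P): 5.48e-09
Welch p (LR, vcp vs control, per-animal mean P): 1.04e-08
```

Reading this: the dominant vcp-like effect lands on one leading component
(vcpALS PC1) while the subtle shared disease effect associates with a
separate component (comALS PC2); label-dependent classifiers discriminate
best (AUC ordering LR/MLP > GMM); and per-animal mean disease probability
separates both mutant groups from controls. The same run writes every table
(scores, predictions, per-animal scores, comparisons, contributions,
cluster compositions, manifest) under `demo/`.

The same pipeline runs from the shell:

```bash
mnprof simulate --seed 1 --out run/          # or bring your own CSVs: mnprof ingest ...
mnprof run-all  --seed 1 --out run/
mnprof manifest --workdir run/
```

Real data enter through `read_feature_table(values.csv, annotations.csv)`
— comma- or tab-delimited, one row per cell, a `cell_id` column, and an
annotation table with `sample_id`, `condition` (control/sod1/vcp/sals) and
optional `stain_panel`.

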