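# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions and the open design choices behind `mnprof`.

## Input model

The unit of analysis is a segmented cell (a ChAT-positive motor neuron in
the motivating application) described by several hundred numeric
measurements exported by a CellProfiler-style pipeline. Measurement names
are parsed by a *naming dialect* (prefix/substring rules) into a taxonomy:
category (`area_shape`, `texture`, `intensity`, `other`), compartment
(nucleus / cytoplasm / whole cell) and stain channel (FUS, SFPQ, ChAT,
DAPI). The shipped dialect covers standard CellProfiler prefixes
(`AreaShape_`, `Texture_`, `Granularity_`, `RadialDistribution_`,
`Intensity_`, `Math_…NCRatio…`); deposits with other conventions can
register a dialect or pass a per-name JSON override. Unrecognized names
fall back to `other` with a logged warning rather than an error, since
stray bookkeeping columns are common in real exports.

Validation is strict where statistics are at stake: duplicate cell ids,
unannotated cells, non-numeric entries and samples mapped to two conditions
are errors; rows with missing measurements are rejected (dropped with a
warning), not imputed — no imputation rule is defensible for arbitrary
morphology features.

Cells are rows and measurements are columns everywhere.

## Spectra

Columns are z-scored with the sample (n−1) standard deviation; constant
columns are dropped with a logged list. The SVD is taken of the
(re-)centered standardized matrix — centering is the default and makes the
explained-variance fractions equal the covariance eigenvalue fractions, but
it is exposed as a flag because some deposited analyses decompose
uncentered data. All r = min(cells, measurements) components are retained.

Spectrum entropy uses natural logarithms normalized by ln r, so H ∈ [0, 1]
with H = 1 for a flat spectrum; zero-variance components contribute
nothing. Loading columns are sign-fixed (largest-magnitude entry positive)
for cross-platform determinism.

## Random-intercept mixed model

Animals/donors induce idiosyncratic offsets shared by their cells, so
per-cell responses are modelled as

    y_ic = b0 + b1 x_c + a_s(c) + e_ic,  a_s ~ N(0, sa^2), e ~ N(0, se^2).

For a single random intercept the ML problem profiles down to one
dimension: for a fixed variance ratio λ = sa²/se², V = I + λJ per group,
and the GLS coefficients and residual variance are closed-form via the
Woodbury identity on per-group sufficient statistics. The outer
maximization over log λ uses bounded scalar optimization plus an explicit
λ = 0 boundary candidate. The phenotype coefficient is tested by a
likelihood-ratio χ²(1) on ML fits (REML would not allow comparing models
with different fixed effects). With a single group the model degrades to
OLS with a warning.

Known behavior: with very few groups (~10) and a group-level phenotype the
χ²(1) reference is slightly anti-conservative (measured rejection ≈ 0.086
at α = 0.05 in the configuration of ten animals of twenty cells); at twenty
groups it calibrates (≈ 0.06). The calibration test therefore uses twenty
groups of ten. No Satterthwaite/Kenward–Roger correction is attempted —
out of scope.

Multiple testing across components defaults to unadjusted per-test α = 0.05
(matching the apparent selection behavior of the motivating study);
Benjamini–Hochberg is available via `adjust="bh"`. The number of
components tested defaults to the smallest k reaching 90% cumulative
variance.

## Classifiers

*GMM on PCs* (label-independent): 2-component full-covariance mixture on
1–3 selected component scores, EM to absolute log-likelihood tolerance
1e-6 (max 500 iterations), best of 10 seeded restarts with k-means++-style
initialization, ridge 1e-6 on covariance diagonals. Condition labels are
used only afterwards: the "sick" component is the one whose hard-assigned
members contain the larger fraction of disease-tissue cells (ties go to the
smaller-weight component, with a warning, on the prior that sick
subpopulations are minorities).

*LR*: penalized-likelihood logistic regression by IRLS/Newton with step
halving; L2 strength λ = 1.0 by default on standardized features, intercept
unpenalized, gradient-norm exit 1e-8.

*MLP*: one hidden layer (25 units), L2 1e-4, deterministic L-BFGS training
behind a thin wrapper (scikit-learn `MLPClassifier`); the same seed and
config reproduce identical weights. These hyperparameters are conventions
of this package (recorded in run metadata), chosen as unremarkable
small-sample defaults.

*Censored variants* (sLR/sMLP): identical fits on the row subset that
excludes a condition (typically sod1), learning the condition-specific
phenotype with label-dependent machinery.

*Disease profile*: every model outputs S on the log-odds scale (LR/MLP:
pre-link linear predictor / output pre-activation; GMM: weighted log
density ratio of sick vs healthy components) and P = logistic(S), which for
the GMM is identically the posterior. S is reported separately because P
saturates: two cells with P within 1e-12 of 1 can differ by many units of
severity.

*Evaluation*: ROC/AUC is pairwise concordance with ties counted ½,
computed in-sample over all cells by default (the protocol of the
motivating study). In-sample scoring of label-dependent models memorizes
animal-specific offsets, so for analyses where the per-cell *call* matters
(the re-labeling analysis) the package provides leave-one-animal-out
prediction (`fit_predict_loao`), which scores each animal's cells with a
model trained on the other animals.

## Scoring and group tests

Per-animal scores are unweighted means of P and S over the animal's cells
plus the percentage of cells with P above a threshold (default 0.5 — the
natural posterior cut; exposed as config). Group comparisons are two-sided
Welch unequal-variance t tests with Satterthwaite degrees of freedom, at
the animal level only. The re-labeling analysis Welch-tests one marker
measurement twice — grouped by tissue origin and grouped by classifier
calls — and reports both p-values with group sizes.

## Contributions

Per-measurement relative contributions c_j ≥ 0, Σc_j = 1:

* LR: c_j ∝ |β_j| — exact for a linear model on standardized inputs.
* GMM: Fisher discriminant direction w = Σ̄⁻¹(μ_sick − μ_healthy) in PC
  space with the mixture-weight-pooled covariance Σ̄ (pooling chosen for
  symmetry and stability in 1–3 dimensions), mapped to measurement space
  through the selected loading columns, c_j ∝ |(L w)_j|.
* MLP: path-weight heuristic c_j ∝ Σ_h |W1_jh W2_h|, the standard exact
  attribution for the linearized one-hidden-layer network.

No mathematical definition of "relative contribution" is canonical for
nonlinear models; these are the conventional choices and are recorded in
output metadata. SHAP-style attributions are out of scope.

Category-level analysis: (i) a random-intercept LMM of contribution on
classifier group (comALS = 1, so positive effects mean comALS-enriched)
with the classifier as grouping factor; (ii) a seeded permutation z-score
of the within-category mean against random category assignments (default
10,000 permutations). A near-uniform profile has a degenerate permutation
null; its z is reported as 0.

## Clustering

Agglomerative clustering with Euclidean distance and average (UPGMA)
linkage for both cells and classifiers; UPGMA on a metric is monotone, so
cutting the k−1 highest merges yields k clusters. Flat labels are
renumbered by first occurrence for determinism. With duplicated points
(zero-height merges) fewer than k clusters may exist. An ultrametric Newick
export is provided for interoperability.

## Synthetic-data generator

The generator emulates, on the standardized scale, exactly the structure
the analysis assumes:

    x_cj = a_{s(c),j} + z_c (d_com e_com,j + 1{vcp} d_vcp e_vcp,j) + eps_cj

* `a_{s,j} ~ N(0, sigma_sample^2)`: each animal draws a per-measurement
  offset profile shared by its cells — a staining/acquisition-batch-like
  idiosyncrasy. A profile (rather than a single scalar added to every
  measurement) spreads animal variation across many principal components,
  as in real data; it is what makes the mixed model demonstrably necessary
  and keeps single extreme animals from dominating Euclidean cell
  clustering.
* `z_c ~ Bernoulli(pi)`: sick status; disease conditions default to
  pi = 0.7 (30% healthy contamination), controls to 0.
* Effect directions `e` are ±1 on k affected measurements, so `d` is the
  per-affected-measurement shift in sd units (the stored `u` is the
  unit-norm direction; the applied vector is d·√k·u). The shared (com-like)
  support lives on area-shape measurements plus the SFPQ N/C ratio (forced
  negative: reduced N/C in disease); the vcp-like support on
  texture/intensity measurements plus the FUS N/C ratio — mirroring which
  markers mislocalize in which model.
* `eps ~ N(0, 1)` i.i.d.

Default scenario (the "study conditions" of the test suite): 3/4/3
control/sod1/vcp animals, ~12 cells per animal, 750 measurements split
300/250/200 across categories, d_vcp = 2.0 over k_vcp = 60, d_com = 0.8
over k_com = 40, sigma_sample = 0.5. This reproduces the qualitative
hierarchy of real mouse data: the vcp-like effect dominates unsupervised
clustering and one leading component, while the shared effect is invisible
to clustering but recoverable by the mixed-model association and the
label-dependent classifiers.

What the generator does **not** emulate: correlations among measurements
(real Zernike/texture families are strongly collinear), non-Gaussian
marginals, heteroscedastic animals, segmentation artifacts, or any image
physics. Passing tests therefore demonstrate the statistical machinery
under the assumed generative structure, not performance on real images.

A consequence worth knowing: with the default subtle shared effect, the
variance along the com direction sits below the Marchenko–Pastur noise
edge of a 120 × 750 matrix, so the comALS GMM (fit on noisy PCs) is the
weakest classifier — the same ordering the motivating study reports. The
contribution-clustering property (comALS-type vs vcpALS-type classifiers
separating by profile) is therefore exercised under a strongly nested,
fully penetrant scenario (d_com = 2, d_vcp = 4, pi = 1), and asserted as
recovery in a strict majority of seven replicate studies, since
single-study MLP attributions are unstable at n ≈ 120.

## Problem sizes in the test suite

Tests run simulations at the smallest sizes where the tested property is
expected to hold cleanly: mixture recovery at n = 1000, logistic recovery
at n = 5000, type-I calibration over 1000 null replicates at 20 × 10,
permutation calibration at 100 runs × 10,000 permutations × 100
measurements, re-labeling over 100 replicate studies of ~300 cells, and
end-to-end runs at the default ~120 × 750 scale. The full suite finishes
in well under five minutes on one core.

## Known limitations

* The LRT reference is asymptotic in the number of groups (see above).
* In-sample AUCs on ~120 cells with hundreds of features are optimistic by
  construction; use `fit_predict_loao` for honest per-cell calls.
* The GMM supports exactly two components; multi-modal phenotype mixtures
  are out of scope.
* Contribution definitions are model-specific conventions; comparing
  magnitudes *across* classifier families is only meaningful after the
  normalization applied here, and remains heuristic for the MLP.
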