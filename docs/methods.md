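# Methods

## Synthetic cohorts

The generator (`strokepwi.synth`) emulates the three statistical
properties the analysis relies on, not MR physics.

**Perfusion series.** Every voxel follows
`I(t) = baseline − A · g(t − t0) + ε`, clipped at zero, with a
gamma-variate bolus `g(t) = ((t−t0)/β)^α · exp(α − α(t−t0)/β)`
normalized to peak 1 at `t0 + β` — the standard parametric shape for a
contrast transit curve. Lesion voxels use a smaller amplitude and a later
onset than everything else (`A_LT ≤ A_NT`, `t0_LT = t0_NT + delay`), so
lesion tissue shows the smaller, delayed intensity dip that
distinguishes hypoperfused tissue. Defaults: baseline 300 a.u.,
`A_NT = 150`, `A_LT = 60`, onset 12, delay 4 timepoints, (α, β) =
(3, 2.5), 50 timepoints, Gaussian noise σ = 20 a.u. (≈ 7 % of baseline,
a realistic thermal-noise level for DSC-PWI). The lesion is an ellipsoid
in the left hemisphere; its mirror across the column midline is the NT
mask. Semi-axes default to shape-proportional values that always fit
strictly left of the midline; an explicit radius that crosses the
midline raises.

**Clinical table.** One row per scan with the usual admission fields.
Continuous fields are normal (age: 71.362 ± 10.91) or non-negative
truncated normal (admission NIHSS 9.919 ± 6.747, outcome NIHSS
6.275 ± 6.875, lesion volume 95.583 ± 72.304 mL); binary fields are
Bernoulli (female 26.8 %, right/left limb weakness 47.5/45 %, lisp
73.8 %, confusion 12.5 %, hypertension 73.8 %, diabetes 32.5 %, atrial
fibrillation 35 %, thrombectomy 27.5 %). All marginals are overridable.

**Outcome labels.** A latent score — a linear combination of
standardized covariates/imaging summaries (`effect_config`) plus
logistic noise — is bucketed into the 7 mRS levels at its own sample
quantiles, with bucket probabilities defaulting to the reference
7-category distribution (25, 11, 9, 4, 8, 9, 14)/80. Quantile bucketing
pins the marginal counts to the configured priors exactly while
preserving monotone dependence on the planted effects. Repeated scans of
one patient are not emulated: each row is independent (a
repeated-measures structure would only tighten, not change, the planted
associations).

What the generator does **not** capture: motion, partial-volume and
susceptibility artifacts, vendor-specific intensity scales, spatial
texture structure beyond noise (texture features on synthetic data are
noise-driven), and within-patient correlation. Passing tests therefore
demonstrate pipeline correctness and calibration, not clinical
performance.

## Preprocessing

Smoothing is a triple moving average: three successive passes of a 1×3
uniform kernel along time only (equivalently one pass of
(1,3,6,7,6,3,1)/27 in the interior), with replicate padding at the
edges so curve length is preserved. The normal-tissue ROI is the lesion
mask reflected across the image midline of the column axis,
`(s, r, c) ↔ (s, r, W−1−c)`; a reflection that intersects the lesion
(midline-crossing lesion) is rejected rather than silently truncated.
Brain-midline estimation and registration are out of scope; series are
assumed registered upstream. NIfTI-1 is the on-disk format (series
stored spatial-first/time-last; masks strict {0,1}).

## Temporal radiomics

Feature classes and per-class name lists are pinned in `FeatureConfig`
so the structural counts are stable by construction: Shape 14,
First-order 18, GLCM 24, GLRLM 16, GLSZM 16, NGTDM 5, GLDM 14 (107 base
features), plus the 93 non-shape features recomputed on 5
Laplacian-of-Gaussian images (σ = 1–5 mm, isotropic in physical units)
and 8 wavelet bands (level-1 undecimated separable coif1
decomposition, octants LLL…HHH in axis order slice/row/column):
107 + 465 + 744 = 1316 per timepoint.

The texture engine implements the standard gray-level matrix
definitions: intensities are discretized at a fixed bin width (default
25 a.u., edges anchored at the masked minimum); GLCM is symmetric at
distance 1 over the 13 unique 3D directions with feature values
averaged over directions; GLRLM runs are maximal same-level segments
per direction (averaged the same way); GLSZM zones are 26-connected
components per level; NGTDM and GLDM use the 26-neighbourhood inside
the mask (GLDM dependence = 1 + same-level neighbours, tolerance 0).
Shape features come from a marching-cubes mesh of the padded mask
(volume by divergence theorem, surface area from the mesh), PCA axis
lengths (4·√eigenvalue of the physical-coordinate covariance) and
boundary-voxel maximum diameters. Degenerate cases are defined, not
special-cased away: a constant region has entropy/variance 0, a
single-voxel ROI has zero GLCM features, correlation of a one-level
matrix is 1.

Filtered images are computed on the mask bounding box plus a
filter-support margin (4σ for LoG, minimum 4 voxels), which is
equivalent up to negligible boundary effects and keeps extraction fast
on large volumes. Shape features are computed once per mask and
replicated across timepoints, since the ROI does not change during the
bolus. The engine targets the standard definitions, not bit-parity
with any particular extractor release; the per-class counts and naming
scheme are the contract.

## Significance filter

Features are normalized as printed in the reference formula —
`(F − mean)/(max − min)` — with a z-score mode available
(`norm_mode="zscore"`) because the surrounding description says "unit
variance"; the printed formula is the default. Constant features map to
zeros. The Levene test (mean-centered) at the same α = 0.05 chooses
between the pooled-variance and Welch t branches; two-sided t p-values
below α keep the feature. No multiple-testing correction is applied —
raw p < 0.05 filtering is the procedure being reproduced. Under a null
simulation the retained fraction is ≈ α (checked within 3 binomial SE).

## The 13 selectors

Mutual information is plug-in (nats) after equal-width discretization
into `mi_bins = 10` bins. MIM scores marginal MI; MIFS
(β = 0.5), MRMR, JMI and CMIM run greedy forward selection, evaluating
the printed criterion for every candidate against the selected set at
each step (verified against exhaustive per-step evaluation); only
features chosen within the 20-step horizon carry scores. Fisher is the
population-weighted between/within variance ratio. The Laplacian score
uses a k-NN (k = 5) heat-kernel graph with bandwidth = squared mean
pairwise distance and is reported as 1 − LS so that higher is better
everywhere. ReliefF uses k = 5 near hits/misses, every sample as an
anchor, range-normalized Manhattan differences, miss contributions
weighted by class priors. F-score and T-score follow the two-class
formulas on class means and ddof-1 variances; the T-score denominator
is √(s₊² + s₋²) — the square root restores the scale invariance the
printed form loses. MCFS embeds the sample k-NN graph into
`mcfs_clusters = 2` generalized Laplacian eigenvectors and takes the
max |coefficient| over per-component L1 regressions. Alpha investing
streams features in table order, testing each by the deviance
reduction of a logistic fit at level `α_i = wealth_i/(2i)` (initial
wealth 0.5, admission bonus 0.25, test cost α_i/(1−α_i)); zero wealth
admits nothing. Lasso is L1-penalized logistic regression (λ = 1,
one-vs-rest for multi-class) scored by |coefficient|.

Selection rule: Lasso keeps |coef| > 0.02; every other method min-max
scales its scores to [0, 1] and keeps scores > 0.9 (raw scales are
incommensurable; the normalization makes one threshold meaningful
across methods). Both truncate to the top 20 by score, ties broken by
table column order. Constant score vectors select nothing — a method
that cannot rank features provides no selection signal.

## Composite-score benchmark

Ten classifier families (RBF SVM, decision tree, AdaBoost, MLP, random
forest, k-NN, logistic regression, LDA, gradient boosting, Gaussian
naive Bayes) under stratified tenfold cross-validation with a fixed
shuffle seed. Five indexes per fold: precision, accuracy, AUC, F1,
recall; multi-class uses macro averaging and one-vs-rest AUC. The
composite score is the grand mean of the 10 × 5 matrix; `cv_repeats`
(default 1) averages over repeated fold shuffles for the alternative
reading of "five tenfold cross-validations". Ties in CS go to the
alphabetically first method, logged. The "paper" registry profile uses
the reference settings (MLP(400, 100) with max_iter 10⁴,
cross-validated liblinear logistic regression, 200-tree forest); the
"fast" profile keeps the same ten families at smaller settings
(MLP(16,), plain liblinear LR, 50 trees, 20/30 boosting rounds) and is
the default in the bundled configuration, the tests and the acceptance
script — the package's problem-size choice for desk-scale,
single-process runs. An empty feature set scores CS = 0.

## Survival fusion

The survival feature is the output of a feed-forward Cox scorer: ReLU
hidden layers (default 32, 16; an empty layout gives the linear Cox
model), linear scalar risk output, trained by minibatch Adam
(lr 10⁻³, batch 20, default 4000 epochs) on the negative log partial
likelihood with Breslow handling of tied event times, averaged over
events. Age is the event time; the event indicator defaults to poor
outcome (mRS ≥ 3), configurable. One network is trained per label
situation (inputs: normalized clinical table + that situation's mRSRF).
Training quality is tracked with the concordance index (risk ties count
0.5; comparable pairs require the shorter time to be an event).
Batches without an event are skipped; non-finite loss raises rather
than continuing silently. The cohort-level risk vector is
range-normalized into SurvF.

To avoid outcome leakage, the evaluation fits the survival network on
the training rows of the 70/30 split only and predicts SurvF for
everyone (`survf_fit="full"` reproduces the alternative whole-cohort
fit for comparison).

## Outcome evaluation

7-level mRS regroups to 4 categories {0}, {1,2}, {3,4}, {5,6} and 2
categories {0–2}, {3–6}. Note the bucket maps are functions of the
7-level labels; re-applying a map to already-bucketed labels is not
meaningful (bucketed values reuse small integers). The
benchmark-winning method selects mRSRF per situation from the pooled
outstanding features of all 13 selectors, evaluated on the lesion-tissue
rows (one per scan, aligned with the per-scan labels); the two-class-only
scorers (FS, TS) fall back to the good/poor dichotomy when handed a
finer situation. Seven groups — CTI, mRSRF, SurvF, and the four
column-concatenations — are range-normalized and scored by all ten
models on a single stratified 70/30 split (a `--repeats` style rerun is
available by reseeding). An empty mRSRF leaves its groups degenerate
(reported as missing cells) and evaluation proceeds. A class with a
single sample cannot be stratified and fails loudly.

## Problem sizes

The test suite and acceptance script run the structural-count check on
one 8 × 32 × 32 scan at 50 timepoints under the full nine-class
configuration, and the end-to-end run on 80 scans at 6 × 16 × 16 with
first-order features, the fast model registry and 150 survival epochs —
sizes chosen so a complete verification is a coffee-break, not a
cluster job, while exercising every stage at the reference sample size
(80 scans, 160 LT/NT rows).

## Known limitations

* Texture features on the synthetic cohorts carry little signal (noise
  has no planted texture); the planted LT/NT contrast lives in
  first-order and filtered-intensity features.
* On well-separated synthetic data the composite score saturates near
  1.0 for many selectors, so the best-method choice can ride on the
  alphabetical tie-break; this mirrors what happens whenever a
  benchmark cannot discriminate between feature sets.
* The feature engine follows the standard matrix definitions but is not
  guaranteed bit-identical to any specific extractor implementation.
* The concordance index treats tied event times as non-comparable; with
  heavily discretized ages this discards pairs.
* Alpha investing's admissions depend on the stream (column) order by
  construction.
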