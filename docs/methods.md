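# Methods

This note documents the models, procedures and design choices behind
`subgrade`: a pipeline that predicts the binary WHO/ISUP grade (low =
grades 1–2, high = grades 3–4) of renal tumours from CT radiomics, with the
tumour volume of interest decomposed into sub-regions so the grade signal
can be localised within the tumour.

## Sub-region decomposition

The tumour VOI is a 3D binary mask with anisotropic voxel spacing. Depth is
defined as the Euclidean distance (in mm, honouring spacing) from each
tumour voxel to the nearest background voxel, computed with a distance
transform on the zero-padded mask, so voxels on the grid edge count as
boundary. The *core at fraction p* is the `round(p·|mask|)` deepest voxels
— "p% of the mask" is read as a volume (voxel-count) fraction, which makes
the complement exact: the *periphery at fraction p* is the set difference
`mask \ core(1−p)`, a hollow rim containing exactly the outermost p of the
tumour volume. Seven regions are analysed per tumour: the full mask, cores
at 25/50/75%, and peripheries at 25/50/75%.

Ties at the cut depth are admitted in lexicographic (z, y, x) order until
the target count is met, making the decomposition deterministic across
platforms. For multi-component masks the distance field is computed
globally; the core may then concentrate in the largest component, which is
flagged (`multi_component_parent`) rather than hidden. Regions whose
bounding box drops below 2 voxels on any axis are flagged
(`below_roi_minimum`), mirroring the extractor's minimum ROI dimension.

## Radiomics battery

Features follow the IBSI-style definitions of the standard feature classes,
computed on the 3D image restricted to a region mask, after cropping to the
bounding box plus a 5-voxel pad. There is no resampling, no outlier
removal, and no intensity normalisation. Grey levels use fixed-bin-width
discretisation (default 20 HU) anchored at the region minimum, which makes
every discretised texture feature invariant to constant intensity shifts.

Counts per class: first-order 19 (moments on raw intensities; entropy and
uniformity on the discretised histogram), GLCM 24 (13 unique unit offsets,
symmetrised, feature-averaged over offsets), GLRLM 16 (13 directions,
averaged), GLSZM 16 (26-connected zones), GLDM 14 (Chebyshev distance 1,
dependence tolerance 0; the dependence size counts the centre voxel plus
matching neighbours, keeping small-dependence emphases finite), NGTDM 5,
and 16 shape features — 110 features for the original image. Each enabled
filter image (gradient magnitude; rescaled exponential / logarithm /
square-root / square maps; Laplacian of Gaussian at σ ∈ {1, 2, 3} mm; the 8
sub-bands of a one-level coiflet-1 3D wavelet decomposition) re-contributes
the 94 intensity/texture features; shape is a property of the mask alone
and is computed once. A full battery is therefore 110 + 94 per filter
image (1614 with all 16 default filter images enabled).

Degenerate inputs take mathematically defined limits rather than NaN:
constant regions give zero variance/entropy/contrast, uniformity 1, GLCM
correlation 1; planar regions give zero least-axis length and flatness. Any
residual non-finite value would be replaced by 0 and flagged — with the
defined limits in place this path is never exercised by the tests.

Two implementation choices differ deliberately from naive formulations:

* **Surface meshing.** Marching cubes on a raw binary mask inflates surface
  area by roughly 9% through staircase facets (a radius-10 digital ball
  would score sphericity ≈ 0.91 instead of ≈ 1). The mask is smoothed with
  a one-voxel Gaussian before iso-surfacing at level 0.5 (falling back to
  the binary surface when smoothing would erase a thin structure), which
  brings ball sphericity above 0.97 while leaving volumes essentially
  unchanged.
* **Laplacian of Gaussian.** The sampled-kernel LoG has non-zero DC gain,
  so a constant image would not map to zero. The filter uses the
  recursive-Gaussian Laplacian (SimpleITK), scale-normalised, with σ in
  physical millimetres.

The total feature count tracks this package's own formula, not any specific
third-party extractor release; the local-binary-pattern filter is excluded
(its spherical-harmonic machinery is out of proportion to its role here).

## Feature preparation and selection

All fitting is restricted to the training partition by construction — the
operations only accept training rows, so test statistics cannot leak into
any fitted state:

1. **Z-scoring**: per-feature standardisation `(x − μ)/σ` with μ, σ from
   the training rows (population/n-denominator convention by default, with
   a sample-σ switch). Features constant on the training set transform to 0
   and are flagged.
2. **Correlation filter**: greedy scan in canonical feature order; a
   feature is dropped when its |Pearson r| with an earlier kept feature
   exceeds 0.8 (the later-ordered member of an offending pair always
   loses, making the filter deterministic).
3. **Importance selection**: a gradient-boosted tree ensemble (XGBoost,
   gain importance, seeded) ranks the surviving features; the top k are
   kept (default k = 30, clamped with a warning when fewer remain). Note
   that quadratic discriminant analysis requires fewer features than
   per-class training samples, so small studies should lower k.
4. **SMOTE**: the minority class is oversampled to the majority count with
   synthetic points `x_i + λ(x_nn − x_i)`, λ ~ U(0,1), x_nn one of the k = 5
   nearest minority neighbours (Euclidean); originals are preserved.
   Applied to training rows only.

## Classifier zoo and experiment grid

Eleven classifiers with the published tuned hyperparameters as defaults:
SVM (RBF, C = 0.01, γ = 0.2, probability output), random forest (401 trees,
depth 3), XGBoost (401 rounds, lr 0.01, γ = 0.52), Gaussian naive Bayes,
MLP (401×201, ReLU, Adam, max_iter 5), LSTM, logistic regression
(max_iter 4), QDA (reg 0.05), LightGBM (9 rounds), a 50-iteration
gradient-boosting classifier in the CatBoost slot, and AdaBoost over a
random-forest base (201 rounds, lr 0.01). The tiny iteration caps (MLP 5,
LR 4) are kept verbatim; their convergence warnings are expected and
suppressed as non-fatal. Seeds default to 42 throughout.

Notes on three slots:

* **CatBoost slot** — filled by scikit-learn's `GradientBoostingClassifier`
  with the 50 boosting iterations and seed of the published configuration;
  the ordered-boosting variant itself is not part of this package's stack.
* **LSTM** — an in-package NumPy implementation (single LSTM layer over the
  feature vector read as a length-F sequence of scalars, hidden width 16,
  Adam, binary cross-entropy, full BPTT). It is excluded from the default
  grid: orders of magnitude slower than the rest of the zoo with no
  benefit on tabular features; it can be enabled explicitly.
* **SVM probability guard** — with C = 0.01 the decision values are tiny
  and Platt calibration can fit an inverted sigmoid on small training
  sets, making `predict_proba` rank *below chance* while the margin
  classifier is accurate. After fitting, the training ROC of the
  calibrated probabilities is checked and the probability scale flipped if
  it is below 0.5.

Every model exposes a continuous score in [0, 1] and 0.5-threshold labels
(positive = high grade). The experiment grid draws one stratified 67/33
train/test split per cohort and reuses it across all 7 regions × all
classifiers, runs the preparation chain once per region, and scores every
cell; with 3 cohorts and the full zoo that is 231 fitted models. External
validation trains the whole chain on one cohort and only transforms and
scores the other. Summary rankings: *region average* = mean test AUC over
the classifier zoo; *classifier average* = (mean AUC over the three cores +
mean AUC over the three peripheries) / 2.

For batch runs on one CPU a scaled-down spec set shrinks only ensemble
sizes (AdaBoost to 15 rounds over 25-tree forests; LSTM to 60 epochs);
learning rates, depths and seeds are unchanged. The default full-size
AdaBoost (201 × 401 trees) is impractical in a grid and retained for
single-model use.

## Evaluation

From the confusion matrix (positive = high grade): ACC, SEN, SPE, MCC
(defined 0 with a flag when a marginal factor is 0), F1, and AUC — the
trapezoidal ROC area when continuous scores exist, otherwise the balanced
accuracy (SEN+SPE)/2, which is the ROC area of a single-threshold
predictor. Percentages carry Wald 95% half-widths `1.96·√(p(1−p)/m)` with
m = n for ACC and AUC, positives for SEN, negatives for SPE; this is the
only CI rule consistent with the published worked examples the suite
recomputes. McNemar's test is the χ² form `(FN−FP)²/(FN+FP)` on 1 df with
no continuity correction (again the only variant matching the published
p-values); FN = FP gives p = 1. The χ²-randomness test defaults to the 2×2
independence form without continuity correction; a goodness-of-fit mode
against a 50/50 predicted-label split is also provided. MCC is invariant
under a simultaneous class/prediction swap while F1 is not; the suite
pins that asymmetry.

The biopsy-comparison harness scores biopsy grading and ML predictions
against nephrectomy histology on the same subjects. An *indeterminate*
biopsy is resolved to the opposite of the nephrectomy grade before scoring:
it contributed no usable decision, so it always counts as an error.

Clinical covariates are tested per variable: Student's t for age, size and
volume by grade; χ² on the sex × grade table; point-biserial correlation as
the effect-size confirmation; significance at p < 0.05.

## Synthetic phantom cohorts

No patient images ship with the package; the phantom module generates the
study conditions. A subject is an ellipsoidal tumour (semi-axes from the
drawn clinical size with mild lognormal eccentricity) embedded in a −50 HU
background on a 3 mm isotropic grid, sized to the ellipsoid plus a 5-voxel
pad. Tumour texture is a stationary Gaussian random field per compartment:
white noise smoothed at the compartment's correlation length, rescaled to
its mean and sd. Independent Gaussian acquisition noise is added everywhere.
The mask is a pure function of the geometry; the image is a pure function
of (config, seed).

Default cohort conditions: the grade signal is a +20 HU mean shift
confined to the inner 50%-volume core (low-grade core 70 ± 20 HU,
high-grade 90 ± 20 HU, correlation length 5 mm); the peripheral shell
(70 ± 20 HU) and the acquisition noise (10 HU) are identical across
classes. Second-order texture is deliberately class-independent: giving
high-grade cores a different sd would leak class signal into *every* region
overlapping the core through mixture variance. Clinical tables draw
labels Bernoulli(prevalence), age and size from the published per-class
normal parameters truncated to physical bounds (age 18–100 y; size 2–10 cm
— the lower bound keeps the ellipsoid valid at 3 mm voxels, the upper
bound caps grid sizes at >1.2 sd above the high-grade mean), sex
Bernoulli per class, and volume from the ellipsoid relation with lognormal
scatter (σ_log = 0.15).

What the phantoms do *not* emulate: scanner- and protocol-dependent texture
(reconstruction kernels, slice thickness variation), contrast-enhancement
kinetics, segmentation variability, non-ellipsoidal growth, necrosis or
calcification. Passing the recovery study therefore shows that the pipeline
*localises a sub-regional intensity signal it is pointed at*, not that real
renal tumours carry their grade signal in the 50% core.

## The signal-recovery study

The recovery study asks whether the pipeline localises a grade signal that
lives *only* in the inner 50% tumour volume. Its construction
(`RECOVERY_CLINICAL` / `RECOVERY_TEXTURES`) confines the class signal
strictly to that support, which takes three deliberate choices:

* **Grade-independent clinical covariates.** Coupling tumour size to grade
  (as the cohort demographics do) injects shape-borne class signal into
  every region's feature table; the recovery cohort draws size, age and
  sex from a single distribution for both classes.
* **Symmetric core contrast.** The class signal is the core mean only:
  60 HU (low) vs 80 HU (high) around a 70 HU shell. Because both classes
  have the same |core − shell| gap (10 HU), regions straddling the core
  boundary have identical compartment-mixture variance in both classes —
  an asymmetric contrast (or a class-dependent core sd) would let larger
  regions read the grade off their own heterogeneity.
* **Class-free nuisance outside the core.** The shell mean varies between
  subjects (sd 12 HU, identically in both classes), emulating
  patient-to-patient rim enhancement; texture correlation length is 7 mm,
  so subject-level feature averages over a region carry appreciable
  sampling noise.

Under this construction the expected ordering is forced by geometry: the
25% core sees the full 20 HU contrast but over fewer independent texture
patches (noisier estimates); regions larger than the core dilute the
contrast *and* inherit the shell nuisance; the 50%/25% peripheries contain
no signal and sit near chance; the 50% core — the exact signal support —
wins. 200 subjects are generated per replicate, the seven region tables
extracted (original 110-feature battery), and the internal-validation grid
run with the scaled-down zoo (no LSTM). The suite requires the 50% core to
rank first with region-average AUC ≥ 85% in at least 8 of 10 seeded
replicates; one replicate takes roughly a minute and a half on one CPU.

## Problem sizes and numerical choices

Defaults used by the analysis scripts and checks: 120-subject cohorts for
the worked analyses, 200 subjects for the recovery study, 20-subject
cohorts for the grid-cardinality smoke check (with k = 4 selected features
so QDA remains full-rank), original-only battery unless filters are
requested. NIfTI I/O uses a diagonal affine built from the voxel spacing;
round-trips are voxel-exact. All randomness flows from explicit integer
seeds; reruns of any deterministic stage are bit-identical, and the run
manifest records config, per-stage wall-clock and table hashes.

## Known limitations

* Feature values follow this package's definitions; exact numeric parity
  with any specific third-party extractor release is a non-goal.
* The LSTM is a minimal reference implementation, not a tuned model.
* The phantom realism limits above; in particular, external validation
  between two synthetic cohorts shares the generator, so it exercises the
  isolation of the fitting chain, not true domain shift.
* 2D (slice-wise) feature variants, DICOM handling and deep-learning
  image-to-grade models are out of scope.
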