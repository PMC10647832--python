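# Methods

`radiorisk` implements a pre-biopsy risk-classification pipeline for
prostate multiparametric MRI (mpMRI): phantom cohort simulation,
reference-tissue intensity normalization, a 487-quantity radiomic
signature, clinical-genomic (NCCN + Decipher → Spratt) risk labeling,
five adaptive-LASSO logistic models, and ROC-based evaluation with
internal validation.  This note records the model assumptions, the
parameter choices that matter, and the places where the design was
genuinely open.

## The classification problem

Each record is one biopsy-confirmed lesion on one mpMRI exam (a patient
can contribute several lesions).  The outcome is binary: *low risk*
under the combined clinical-genomic (Spratt) criteria, i.e. a candidate
for active surveillance.  The pipeline asks whether that label — which
normally requires a biopsy (grade group) and a genomic assay (Decipher)
— can be predicted from information available *before* biopsy: imaging
and basic clinical variables.

## Risk labels

* **Decipher category**: score < 0.45 low, [0.45, 0.60) intermediate,
  ≥ 0.60 high.  The published cutoffs state no inclusivity; we use
  half-open intervals (documented in `radiorisk.risk`).
* **NCCN group** (0–3): from T stage, grade group and PSA.  Low = ≤ T2a,
  GG1, PSA < 10; high/very-high = any of ≥ T3a, GG ≥ 4, PSA > 20;
  intermediate otherwise, split favorable/unfavorable by the
  single-risk-factor / GG ≤ 2 / < 50 % positive cores rule.  The full
  guideline table has more special cases; the rule table here is
  configurable and covers the variables the cohort carries.
* **Spratt score**: numeric sum (0–5) of the NCCN value (0–3) and
  Decipher value (0–2).  Three-tier collapse: *low* exactly when
  (NCCN low ∧ Decipher ≤ intermediate) ∨ (NCCN ≤ intermediate ∧
  Decipher low); *high* when the sum ≥ 4; *intermediate* otherwise.
  Whether "NCCN low-or-intermediate" includes the unfavorable subgroup
  is not fully pinned down by the published wording; the default
  includes it, `RiskRules(low_includes_unfavorable=False)` gives the
  strict variant.
* **Patient label** = worst lesion (max three-tier); a patient is low
  risk iff every lesion is.

## Intensity normalization

T2-weighted and high b-value intensities are scanner-arbitrary.  T2W is
mapped through a monotone interpolant anchored at (0, 0) and at the
three (measured mean, target) knots of gluteus maximus, femoral head
and bladder — dark, intermediate and bright reference tissues.  The
interpolant is a monotone piecewise cubic (PCHIP), with a
piecewise-linear mode for hand-checkable arithmetic; beyond the
brightest knot the map continues linearly with the end slope, and
negative inputs are clamped to zero.  Because a nonlinear map does not
commute with averaging, one pass fixes the knots but not the noisy
tissue *means*; a short correction loop (re-measure means, compose
another monotone map) drives every reference mean onto its target to
1e-12 relative, which also makes the operation idempotent.  BVAL is
rescaled so the gluteus-maximus mean equals its target (exactly, in one
step).  ADC is a physical quantity and passes through unchanged.

Default targets (GM 100, femoral head 300, bladder 1000 for T2W; GM 100
for BVAL) are conventional anchors; nothing downstream depends on their
absolute values, only on the fixed-point property.

## Radiomic signature

Per ROI (lesion L, normally-appearing peripheral zone NAPZ, transition
zone NATZ) and per sequence (t2, adc, b):

* **Intensity** (`int`): the nine histogram descriptors of the in-ROI
  voxel values — 10/25/50/75/90th percentiles (linear interpolation
  between order statistics), mean, sample SD (n−1), excess kurtosis and
  skewness (biased standardized moments).  A degenerate sample (SD = 0)
  reports skewness/kurtosis 0.
* **Texture** (`con`, `cor`, `ene`, `ent`, `hom`): voxel-wise 3D
  Haralick features.  For every ROI voxel, the 5×5×5 window centred on
  it (full image context, not masked to the ROI) is rescaled to integer
  levels 0–255 (min→0, max→255, rounding half-away-from-zero; constant
  windows map to 0), binned into 128 grey levels (`level // 2`), and a
  grey-level co-occurrence matrix is accumulated over the 13 unique
  unit directions in 3D, symmetrized, and normalized.  Energy Σp²,
  entropy −Σp ln p (natural log), contrast Σ(i−j)²p, homogeneity
  Σp/(1+(i−j)²) and correlation (0 when a marginal variance vanishes)
  are evaluated per voxel; the in-ROI map is then summarized by the
  same nine descriptors.

  At image boundaries windows are clipped: out-of-image voxels are
  excluded from both the rescale and the pair counts (minimum 27
  in-image voxels, guaranteed for volumes ≥ 5 voxels per axis).  The
  *local* per-window rescale — rather than a global volume
  normalization — keeps texture values comparable between tumor and
  normal-tissue windows with very different absolute levels.

This yields 3 × 6 × 9 = 162 features per ROI, 486 total, named
`{ROI}_{seq}_{family}_{descriptor}`, plus the tumor volume `HRS6`
(lesion-mask voxel count × voxel volume, cc), for 487 quantities.  The
engine never materializes the per-voxel 128×128 matrix: moment features
accumulate directly over bin pairs and count features come from a
sort/run-length pass, ~10⁴ windows/s on one core; a brute-force
pair-enumeration oracle in the test suite pins the engine to 1e-10.

Conventions the source material leaves open, fixed here and recorded in
`TextureParams`: 13-direction accumulation into a single symmetrized
matrix (vs per-direction averaging), natural-log entropy,
half-away-from-zero rounding, zero-variance correlation = 0, minimum
ROI size 10 voxels.

## Models

Five logistic models predict the low-risk label:

1. clinical: age, PSA density, DRE (0 vs 1–2), PI-RADS (1–2 vs 3–5);
2. lesion radiomics; 3. lesion + NAPZ/NATZ radiomics;
4. clinical + lesion radiomics; 5. clinical + all radiomics.

Radiomic pools are selected by the **adaptive LASSO**: a ridge logistic
fit (C = 1) gives weights w_j = 1/|β̂_j| (γ = 1; variables with zero
ridge coefficient are excluded outright), then a weighted-L1 logistic
path (20 penalties, log-spaced C ∈ [1e-3, 10]) is scored by stratified
10-fold cross-validated deviance and the penalty is chosen by the
one-standard-error rule (the strongest penalty within one SE of the
deviance minimum; `one_se=False` reverts to the CV minimum).  The
one-SE rule is what keeps the selection near-empty on pure noise — the
property the null-cohort tests verify.  Tumor volume `HRS6` is forced
into every radiomics model without selection; clinical variables in
models 4–5 enter unpenalized at the refit stage.  The final model is an
unpenalized logistic refit on selected + forced variables, with a
mild-ridge fallback (C = 100, logged) under separation.  All inputs are
standardized on training data; the parameters are stored and reapplied
verbatim at prediction.  `intensity_only=True` restricts pools to the
27/81 first-order features per the name grammar.

Patient-level prediction offers two policies: `worst_lesion_truth`
evaluates on the lesion with the highest true three-tier score (the
evaluation design when labels exist; patient-level models are refit on
those rows by default) and `min_prob` (minimum predicted low-risk
probability across lesions — the deployable pre-biopsy rule).

## Evaluation

* **AUC**: Mann–Whitney with ties ½ (equals the trapezoidal ROC area).
* **Venkatraman–Begg**: paired-sample permutation test for equality of
  two ROC curves.  Scores become within-sample ranks (mid-ranks on
  ties); the statistic sums |error-count difference| over all integer
  rank cut-points; the null exchanges the two ranks per record with
  probability ½ and re-ranks; p = (1 + #{perm ≥ obs})/(n_perm + 1).
  Measured type-I error at n = 40, n_perm = 200: 0.048 over 500
  replicates.
* **Optimism-corrected AUC** (Harrell): corrected = apparent −
  mean_b[AUC(fit_b, resample_b) − AUC(fit_b, original)]; single-class
  resamples are redrawn and counted.  By default the bootstrap refits
  only the logistic coefficients on the variables selected once on the
  full data (matching a single reported variable list); full
  re-selection per resample is available via a custom `model_builder`.
  Known limitation: under extreme overfitting (p approaching n/2, near
  separation) the estimator undercorrects, because the bootstrap model
  has seen ~63 % of the "test" sample; our own simulations show
  corrected AUC ≈ 0.7 where truth is 0.5 in that regime.  The
  correction is accurate in the mild-overfit regimes the pipeline
  actually produces (selection keeps models small).
* **Experiment grid**: models × {lesion, patient} × {all, DRE = 0} ×
  {full, intensity-only}, with Venkatraman–Begg p-values against the
  clinical model; single-class cells are reported as undefined.

## Synthetic cohorts

The generator emulates the statistical structure of a mixed
surveillance/treatment biopsy cohort; it is a *statistical phantom*,
not an anatomical simulation.  Defaults (all in `CohortConfig`):

* 78 patients, 1–5 lesions each (probabilities .32/.13/.26/.11/.18),
  57.6 % of lesions low risk — the cohort profile the analysis design
  assumes; one exam per patient (a `duplicate_exam_frac` flag exercises
  repeat exams).
* Grid 48×48×32 voxels at 1×1×3 mm.  Schematic anatomy: a prostate box
  split into PZ/TZ, plus GM / femoral-head / bladder blocks with
  distinct means per sequence; Gaussian background noise (5 % of the
  local mean); a random global scale U(0.7, 1.4) on T2W and BVAL so
  normalization is exercised.
* Lesions are ellipsoids (semi-axes in mm, jittered), placed in PZ with
  probability 0.75, contained in the prostate, pairwise disjoint.
  Class contrasts in normalized units — effect sizes the published
  analysis reports only qualitatively (lower T2/ADC, higher BVAL,
  larger volume in intermediate/high lesions), so the defaults are the
  package's own choice of a clearly detectable but noisy signal:
  extra shift (non-low vs low) t2 −40, adc −250, b +30; radii 3.5–6.5 mm
  (low) vs 4.5–8 mm (non-low); in-lesion smoothed-noise texture with
  correlation length 0.5 voxels (low) vs +0.8 (non-low); a modest
  normal-tissue "field effect" (t2 −12, adc −70, b +8) in non-low
  patients so the NAPZ/NATZ models have something to find.
* Clinical/genomic structure: Decipher ~ Beta(2, 6) (low) vs Beta(6, 3)
  (non-low); DRE positive with probability 0.02 vs 0.60 by patient
  class; PI-RADS ordinal, class-shifted; PSA/T-stage drawn from
  class-compatible pools; age class-independent.  Records are sampled
  so the risk labels recomputed from them *equal the intended class by
  construction* (asserted during generation).  `CohortConfig.null()`
  zeroes every imaging effect while keeping the label structure — the
  chance-level baseline.  `dre_only_clinical=True` makes DRE the only
  class-informative clinical variable (class-independent PI-RADS,
  low-compatible PSA/stage pools for everyone), the condition under
  which the clinical model should collapse on the DRE-negative subset
  while radiomics models hold — the pattern the acceptance tests check.

What the phantom does **not** model: real prostate anatomy and lesion
morphology, scanner/vendor/field-strength heterogeneity, registration
error between sequences, DCE imaging, spatial correlation between a
lesion and its surrounding tissue beyond the planted mean shifts.
Passing tests therefore demonstrate that the pipeline recovers the
structure it targets when that structure is present, and finds nothing
when it is absent — not that the published effect sizes are correct.

## Problem sizes used in tests and the acceptance script

Statistical checks run at deliberately scaled sizes chosen for stable
Monte-Carlo behaviour: null cohorts of ~200 lesions × 5 seeds
(two-fold cross-evaluation over patients, so chance level is assessed
out-of-sample), planted-signal cohorts of 120 patients × 3 seeds,
noise-selection runs at n = 200, p = 50 × 20 seeds, Venkatraman–Begg
calibration at 500 replicates × 200 permutations, optimism runs at 200
bootstrap replicates.  `scripts/acceptance.py` recomputes the same
quantities at slightly smaller sizes (3 null and 2 signal cohorts, 300
VB replicates), all seeded from its `--seed` argument.

## Numerical choices and degenerate inputs

Floating tolerances: GLCM normalization 1e-12; oracle agreement 1e-10;
normalization fixed point 1e-9 relative (iteration stops at 1e-12).
Empty masks, single-class labels, non-monotone reference means,
out-of-range clinical codes and missing sequences all raise typed
errors naming the offending object.  Ties: mid-ranks throughout;
`rescale_window` rounds half-away-from-zero so results do not depend on
banker's rounding.  All stochastic components take explicit seeds;
identical (config, seed) reproduce outputs bit-for-bit, including the
liblinear stages (seeded) and the disk pipeline (verified by checksum
in the test suite).
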