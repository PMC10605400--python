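# Methods

`csprad` implements a radiomics analysis pipeline for one clinical question:
among prostate mpMRI lesions already scored PI-RADS 4 or 5, which harbour
clinically significant cancer (csPC, ISUP grade group ≥ 2 / Gleason ≥ 7)?
PI-RADS 4/5 lesions are routinely biopsied, yet a substantial fraction are
benign or indolent; a model built on T2-weighted and ADC texture plus routine
clinical indices (age, PSA, PSA density, prostate volume, mean lesion ADC)
can in principle raise the positive predictive value of the imaging call and
spare unnecessary biopsies.

The pipeline has five stages: synthetic cohort generation (or ingestion of
real co-registered NIfTI volumes), image conditioning, feature extraction,
stability feature selection, and cross-validated diagnostic model
evaluation.

## Synthetic phantom cohort

No public dataset accompanies this problem setting, so the `phantom` module
generates cohorts with known ground truth; every downstream stage is
testable against the generative parameters.

**Cohort structure.** Default: 99 patients with a fixed lesion-multiplicity
pattern (89 patients with one lesion, 8 with two, 2 with three → 111
lesions, 1.12 lesions/patient), csPC prevalence 0.712, PI-RADS 4 probability
0.667, and zone assignment P(PZ | PI-RADS 4) = 0.919, P(PZ | PI-RADS 5) =
0.487. Lesion labels are drawn i.i.d. at the configured prevalence,
independent of zone (the mild zone-conditional prevalence difference seen in
real cohorts is not modelled).

**Image model.** Each lesion sample is a pair of volumes on native grids
(T2: 0.5 × 0.5 × 3 mm, 40 × 40 × 8 voxels; ADC: 1 × 1 × 3 mm over the same
physical extent). Tissue texture is a stationary Gaussian random field —
white noise smoothed with a Gaussian kernel of configurable correlation
length (T2: 0.9 mm; ADC: 1.8 mm) and rescaled to zero mean / unit SD. The
lesion is an ellipsoid (radii 3.5–7 mm in-plane, 3.2–6 mm axially) with a
smooth boundary perturbation, guaranteed ≥ 30 voxels on both grids; a
homogeneous reference region emulating healthy peripheral zone sits in a
corner slab, disjoint from the lesion. Volumes are multiplied by a bias
field exp(P(x)) with P a random order-2 polynomial over physical
coordinates, demeaned and scaled to max|P| = 0.3 by default.

**Class structure.** Class separations are parameterised in SD units and
split around the configured marginal with prevalence weighting, so cohort
marginals match the population values regardless of effect size:

- mean lesion ADC: marginal 653 × 10⁻⁶ mm²/s, between-lesion SD 180,
  effect −1 SD (csPC ≈ 601, non-csPC ≈ 781);
- T2 within-lesion texture SD: marginal 60 (arbitrary units), fractional
  split 0.6 (csPC lesions more heterogeneous);
- per-lesion mean levels additionally jitter with the between-lesion SD.

The within-lesion texture SD itself varies between lesions of the same
class (lognormal, CV 0.4, mean 1). This matters: texture-SD-sensitive
features are estimated over ~10³ voxels and would otherwise recover the
class SD almost exactly, making classification trivially perfect — a
property no real cohort has. With the jitter, the end-to-end demo lands in
a plausible diagnostic range (best univariate accuracy ≈ 0.79, best
multivariate ≈ 0.85 on the default cohort).

**Clinical covariates.** Per patient, conditioned on whether any of the
patient's lesions is csPC: age normal (70 ± 6.5 y csPC, 67.2 ± 7 y
non-csPC); PSA lognormal (8.8 ± 5.0 vs 5.9 ± 3.2 ng/mL); prostate volume
lognormal (47 ± 24 vs 63 ± 31 mL). Prevalence-weighted marginals ≈ 7.9
ng/mL PSA, 51.6 mL volume, PSA density ≈ 0.17. PSA density is always
computed as PSA / volume, never drawn. These per-class splits are modelling
assumptions (population data report only marginals); they give PSA density
the high-specificity / low-sensitivity univariate profile expected of it.

**Determinism.** One seed drives a single `numpy` Generator consumed
sequentially through the cohort; identical config + seed gives bit-identical
cohorts.

**What the phantom does not emulate.** Anatomy (no gland, no zonal
structure beyond a label), rician noise, partial-volume effects at lesion
boundaries, inter-sequence misregistration, DCE/T1 channels, biopsy
undersampling error in the reference standard. Passing tests on the
phantom therefore demonstrate correctness of the pipeline's computations
and recoverability of planted effects — not clinical performance on real
mpMRI.

## Preprocessing

Order: bias-field correction → reference normalization (T2 only) →
resampling.

- **Bias correction** fits an order-2 polynomial to log-intensities by
  least squares over the body mask, divides by its exponential, and
  rescales to preserve the mask mean. It is deliberately matched to the
  phantom's generative bias family so ground-truth recovery is testable
  (log-bias correlation ≥ 0.95 at amplitude 0.3); a `passthrough` mode
  accepts volumes corrected externally (e.g. by N4). It is a self-contained
  estimator, not a reimplementation of N4.
- **T2 normalization** divides by the mean intensity in the healthy-PZ
  reference VOI ("ranging at the reference mean" is read as division; the
  operation is idempotent). ADC is a quantitative map and is not
  normalized.
- **Resampling** maps images onto fixed grids — 0.4 × 0.4 × 3.0 mm (T2) and
  0.8 × 0.8 × 3.0 mm (ADC) — with order-3 b-spline interpolation
  (SimpleITK), preserving the physical extent within one voxel per face.
  Masks are resampled by linear interpolation of the indicator thresholded
  at 0.5 (volume-preserving up to one boundary-voxel layer); a mask that
  empties raises a warning and the sample is excluded downstream.

Coordinates are voxel-centre: physical = origin + index × spacing, axes
ordered x, y, z. NIfTI affines must be axis-aligned scaling + translation;
shears/rotations are rejected.

## Feature extraction

293 features per modality, 586 per lesion, named
`modality-filter_class_FeatureName` (e.g. `ADC-original_glcm_ClusterShade`).

- **Filters**: original image, plus the LLL and HHH subbands of a
  single-level stationary (undecimated) 3D coif1 wavelet decomposition —
  separable convolution with the coif1 decomposition filters, symmetric
  boundary extension, no subband renormalization.
- **Quantization**: fixed bin count over the masked intensity range —
  32 bins on original images; 8 (T2) / 16 (ADC) bins on wavelet subbands.
- **Classes**: shape (14, original only), first-order (18), GLCM (24),
  GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5); 107 on the original image
  and 93 per subband.

Texture conventions (IBSI definitions throughout): distance-1, 13 unique
3D directions for GLCM/GLRLM with per-direction features averaged;
26-connectivity for GLSZM zones and GLDM/NGTDM neighbourhoods; GLDM
gray-level tolerance α = 0, with the dependence index stored as
1 + (dependent-neighbour count) so small-dependence formulas stay defined.
First-order Entropy/Uniformity reuse the image's fixed-bin quantization.
Shape features are computed once from the ADC-grid lesion mask (shape is a
mask property; one grid is fixed as reference) and emitted under both
modality prefixes. Every texture matrix is verified against brute-force
enumeration oracles (pair, run, flood-fill, neighbour-count) in the test
suite.

Lesions with any undefined feature (e.g. single-voxel masks after
resampling) are dropped before selection with a logged count.

## Stability feature selection

Candidates are the five clinical covariates plus the 586 radiomic features.
For each of 100 × 5 = 500 trials (stratified 5-fold splits, class balance
per fold within ±1 of proportional), using the 4 training folds only:

1. per-feature two-sided Wilcoxon rank-sum test against the outcome
   (vectorized normal approximation with tie and continuity corrections;
   the scalar API uses exact enumeration for tie-free samples of n ≤ 10);
2. Benjamini–Hochberg step-up at FDR 0.05 (all-lesion and PZ analyses) or
   0.1 (TZ);
3. greedy redundancy pruning among survivors, ranked by ascending p:
   discard any feature with |Spearman ρ| > 0.5 to an already-kept one
   (constant columns have undefined ρ and are treated as uncorrelated).

A feature's selection frequency is the fraction of trials it survives;
features above 20% (10% for TZ) form the chosen pool. Running BH before the
correlation pruning keeps the FDR step interpretable (pruning only removes
redundant survivors); the alternative order is a one-line change in the
trial loop. Trials whose training portion lacks a class are skipped, logged
and removed from the denominator. Ties in the greedy order follow column
order (stable sort on p).

## Model evaluation

The same 100 × 5 stratified scheme (same seed ⇒ identical partitions as
selection) evaluates:

- **Univariate models**: threshold maximizing the training Youden index
  J = sens + spec − 1, candidates at midpoints of consecutive sorted unique
  training values plus ±∞ sentinels, both orientations; ties on J break
  toward orientation "high predicts positive", then the smallest threshold.
  A best-J of 0 marks the model uninformative.
- **Multivariate models**: every non-empty subset of the chosen pool
  (capped at 12 for exhaustive search) × six families — linear
  discriminant; linear, quadratic (poly-2) and cubic (poly-3) SVM (C = 1,
  coef0 = 1, scaled gamma); Gini classification tree (min leaf 3); 5-NN on
  standardized features. Per trial: standardize with training-fold
  statistics, fit, Youden-threshold the training scores
  (decision_function, or positive-class probability for tree/KNN), score
  the held-out fold.

Metrics: sensitivity, specificity, PPV, NPV, accuracy summarized as
mean ± SD (ddof = 1) over the validation trials; trials with a zero
denominator are excluded from that metric with contributing-trial counts
reported. Models rank by mean accuracy, ties by higher mean PPV. No
test-fold information enters standardization, fitting or threshold choice
(asserted by poisoned-fold tests).

Feature selection is run once on the full cohort before evaluation (as the
frozen-pool reading of the procedure implies); a fully trial-nested
selection would be the conservative alternative and can be composed from
the same building blocks.

## Numerical and degenerate-input choices

- GLCM Correlation on a single-level region → 1; MCC on fewer than two
  occupied levels → 1; InverseVariance sums off-diagonal terms only;
  0·log 0 = 0 throughout.
- NGTDM features over a single occupied level → 0 (Coarseness → 10⁶ when
  the weighted difference sum is zero).
- Quantization assigns max-valued voxels to the top bin; constant regions
  map to level 1.
- Single-voxel masks: GLCM features are emitted as missing; mesh-based
  shape features are missing when marching cubes has no surface.
- Youden threshold sentinels ±∞ allow the degenerate all-positive /
  all-negative calls.

## Problem sizes of the bundled demo

`scripts/acceptance.py` runs the full default cohort (99 patients, 111
lesions), the full 586-feature catalog, and the full 500-trial all-lesion
selection. The multivariate search uses the top 6 chosen features by
frequency and 20 × 5 CV trials — the package's demo defaults for the
exhaustive subset × family sweep; `CVConfig(n_repeats=100)` reproduces the
full-scale evaluation. The whole script completes in a few minutes on one
CPU.

## Known limitations

- The phantom's simplicity means selection tends to favour first-order and
  variance-type features; the full catalog is exercised but not all
  features receive discriminative signal.
- The built-in bias model is polynomial; strongly non-polynomial coil
  profiles in real data should be corrected externally (passthrough mode).
- Exhaustive multivariate search over large pools is combinatorial; the
  pool cap (12) bounds it at 4095 subsets × 6 families.
- Real-data diagnostic values depend on cohort composition and reference
  standard; nothing here validates clinical performance.
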