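# Methods

## The problem

The glymphatic system clears metabolic waste from the brain: cerebrospinal
fluid (CSF) enters along periarterial spaces (pAs), exchanges with
interstitial fluid in the white-matter (WM) parenchyma, and exits along
perivenous spaces (pVs). `glymphkit` quantifies all three limbs from
multi-shell diffusion MRI: periarterial fluid mobility (free-water axial
diffusivity, FWAD) and local CSF accumulation (free-water volume fraction,
FWVF) inside segmented perivascular spaces; parenchymal free-water burden
(WM-FWVF); and perivenous efflux via the DTI-ALPS index.  A statistical
battery relates these subject-level features to cardiometabolic risk,
diagnosis, amyloid status and cognition.

## Bi-tensor signal model

Each voxel's diffusion-weighted signal is a two-compartment mixture

    S(b, g) = S0 [ f exp(-b gᵀ D_fluid g) + (1 - f) exp(-b gᵀ D_tissue g) ]

with free-water volume fraction `f` (the FWVF), a fluid tensor `D_fluid`
and a tissue tensor `D_tissue`.  Unlike classical free-water-elimination
DTI, which pins the fluid compartment to an isotropic ball at the free-water
diffusivity (3.0 × 10⁻³ mm²/s at body temperature), the fluid tensor here is
fully anisotropic: water inside a perivascular channel diffuses
preferentially along the vessel, and FWAD — the fluid tensor's principal
eigenvalue — is the mobility readout of interest.  FWRD/FWMD/FWFA and the
tissue analogues tAD/tRD/tMD/tFA follow from the two eigensystems.

Separating two exponential decays requires at least two distinct nonzero
shells; single-shell schemes are refused (`InsufficientDataError`).  Both
study protocols qualify: the HCP-Aging-style scheme (6 b0 + 45 @ b=1500 +
45 @ b=3000 s/mm², 96 volumes) and the ADNI-style scheme (14 b0 + 6 @ 500 +
56 @ 1000 + 56 @ 2000, 132 volumes).

### Estimation

Parameters are estimated per voxel by nonlinear least squares on signal
magnitudes (Levenberg–Marquardt), with

* tensors parameterised by their Cholesky factors (positive semi-definite by
  construction) and `f` through a logistic transform, so the optimisation is
  smooth and unconstrained;
* `S0` fixed at the mean of the b0 volumes rather than fitted;
* staged initialisation: a weighted log-linear single-tensor fit, then the
  isotropic free-water-elimination fit (7 parameters) for `f` and the tissue
  tensor, then the full anisotropic model (13 parameters) with the fluid
  tensor started at 3.0 × 10⁻³ · I;
* physical eigenvalue bounds enforced by hinge penalties — tissue
  eigenvalues in [0.05, 2.5] × 10⁻³, fluid in [1.0, 6.0] × 10⁻³ mm²/s — which
  also prevent the two compartments from swapping roles (a final guard swaps
  labels if the fluid tensor ends up slower than the tissue tensor);
* a small set of deterministic alternative starts when the first solve stalls
  at a residual clearly above the noise level estimated from the b0 repeats.

Without a spatial prior the returned fit never has a larger data residual
than its initialisation; non-convergence is flagged in the result, never
raised.

### Noise handling

Two measurement-noise issues dominate at realistic SNR and are handled
explicitly:

1. **Rician floor.** Magnitude images have E[M²] = S² + 2σ², which inflates
   the high-b measurements and biases `f` upward.  σ is estimated from the
   spread of the b0 repeats and the signal is de-biased as
   √max(M² − 2σ², ε) before fitting.  This is a standard first-order
   magnitude correction; the objective remains ordinary least squares, not a
   Rician likelihood.
2. **Noise-flat ridges.** The bi-exponential objective lets `f` trade
   against tissue diffusivity with almost no change in predicted signal.  A
   Fisher-information calculation for the isotropic model on the 96-volume
   two-shell protocol puts the per-voxel Cramér–Rao bound on `f` near 0.05
   at SNR 30 — voxelwise fitting cannot beat this.  Two remedies:
   * **Noise-scaled MAP priors** on the fluid tensor: Gaussian penalties
     pulling the fluid mean diffusivity toward 3.0 × 10⁻³ mm²/s (relative sd
     0.2) and the fluid eigenvalue spread toward isotropy (relative sd 0.4).
     Because the penalty weight is proportional to the estimated σ, the
     priors vanish identically on noiseless data — exact recovery there is
     untouched — and act only where noise would otherwise wander the ridge.
   * **Spatial refinement** in `fit_volume` (default on): after the
     voxelwise pass, each voxel is refit with a noise-scaled prior centred
     on the component-wise median of its 3×3×3 neighbourhood's first-pass
     parameters.  Neighbours whose first-pass `f` differs by more than 0.2
     are treated as another compartment and excluded, so thin tubes and
     small lesions keep their own statistics instead of being dragged toward
     the surrounding tissue.  The prior sd on `f` is 0.03: the gated
     neighbourhood median is accurate to ~0.015 on piecewise-smooth media,
     so the refit mostly selects the neighbourhood-consistent point on the
     data-flat ridge at essentially no cost in data fit.  The second pass
     optimises the penalized objective; the plain RSS-monotonicity guarantee
     applies to the first pass.

   The two regularisation strengths were calibrated once on the SNR-30
   phantom described below and then frozen; both are configuration fields.
   This scheme assumes locally smooth tissue; on real brains with fine
   heterogeneity below the voxel scale, the spatial prior trades a small
   amount of edge bias for a large variance reduction, and can be disabled
   (`spatial_refine=False`).

### What the tests show

On noiseless signals the full anisotropic model is recovered essentially
exactly (f within ±0.02 and FWAD within ±5 % for >95 % of 200 random
physiological voxels).  On a 1000-voxel phantom at Rician SNR 30 the FWVF
map error is ≈0.02 mean absolute.  When data are generated with genuinely
isotropic free water, the anisotropic fit stays at the isotropic solution
(median fluid FA ≈ 0) — the extra freedom does not invent anisotropy.

## DTI-ALPS

At the level of the lateral-ventricle bodies, medullary veins run
left–right (x), perpendicular to projection fibers (z) and association
fibers (y).  With ROI-mean diffusivities from a conventional single-tensor
fit,

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

is 1 when no perivascular channel contributes and rises with fluid movement
along x.  The index is scale-free and, by construction here, the bilateral
value is the mean of the unilateral ones.  ROIs are supplied as voxel sets
or masks; automatic atlas-based placement would require template
registration and is out of scope.  The diffusivities default to the
whole-signal tensor (the convention of the original ALPS method); callers
may substitute the tissue-tensor field.

## Perivascular-space morphometry

Segmentation masks are consumed as binary volumes (the upstream deep-learning
segmenters are not part of this package).  Components are labeled at
26-connectivity (configurable), measured, and filtered:

* **Diameter**: twice the mean distance-transform value along the medial
  axis, plus a half-voxel surface-offset correction.  The medial axis is the
  ridge of the Euclidean distance transform (local maxima in the 3×3×3
  neighbourhood); topological thinning was found to erode thin tubes
  entirely, so the ridge definition is used instead.  Single-voxel
  components degenerate to the smallest voxel dimension and are flagged.
* **Elongation**: PCA extent along the principal axis over the mean
  orthogonal extent, floored at one voxel; a straight tube scores high, a
  ball scores ≈1.
* **False positives**: removed with machine-readable reasons — WMH overlap
  above 50 %, elongation below 1.5 ("round"), volume outside
  [2 voxels, 3000 mm³].  The thresholds are configuration: the exclusion
  categories are principled, the numbers are defaults.  Additional criteria
  (clustering density, anatomical exclusion masks) plug in as predicates.
  WMH voxels can also be subtracted from components before filtering.

### Cortical ROI mapping into superficial WM

ROI labels defined on the cortical boundary are propagated into superficial
WM in two steps.  First, a depth map: Laplace's equation is solved over the
WM interior (6-neighbour finite differences, direct sparse solve) with
potential 0 on the gray-matter boundary and 1 on the deep boundary; the
potential is converted to metric depth by multiplying with the per-voxel
total path length between the boundaries, approximated as the sum of the
Euclidean distances to each boundary.  On slab geometry this equals the
exact streamline length; it avoids explicit streamline integration.
Unreachable WM pockets are flagged missing.  Second, every WM voxel with
depth ≤ 5 mm receives the majority label of its k = 5 nearest labeled
boundary voxels (Euclidean distance in mm); deeper voxels stay unlabeled.
k is configurable.

### Selection of the n largest components

pAs diffusivity is only trustworthy where the space is large relative to
the DWI voxel, so per ROI the analysis keeps the n largest components by
volume (ties broken by component id; shortfalls recorded).  The default
n = 4 is validated by `optimize_n`: for each candidate n it computes the
covariate-adjusted regression t of FWAD and FWVF against each clinical
variable over subjects having at least n components, and reports the n
maximising the summed |t| together with the subject-inclusion fraction
(non-increasing in n); exact ties break toward smaller n, favouring
inclusion.

## Subject-level features

Per-ROI pAs-FWAD/FWVF are unweighted means over the voxels of the selected
components ("across voxels", not across components); whole-brain values pool
the selected components of all ROIs rather than re-selecting globally (a
configuration switch could re-select; pooling is the default because the
per-ROI selection defines the analysis set).  WM-FWVF averages FWVF over
WM with all WMH and pAs voxels excluded; exclusions are exact (no excluded
voxel contributes to any mean).  Missing ROIs stay missing — never silently
zero.  Feature sets for classification: pAs (FWVF + FWAD × precuneus,
AD-signature, whole brain = 6 columns), WM (3), pVs (ALPS, 1), their
unions, and Aβ/tau-PET SUVR benchmarks on the same regions; missing values
are handled by listwise deletion per set.

## Statistical battery

* **Standardized β**: outcome and predictor are z-scored, covariates enter
  raw; β is the predictor's coefficient, p from the two-sided t test.
  Benjamini–Hochberg FDR (statsmodels' step-up) is applied within a family —
  one anatomical compartment per family by convention, at the caller's
  control.
* **ANCOVA**: nested-OLS F test of the group factor after covariates;
  reduces exactly to one-way ANOVA with no covariates.  Adjusted group means
  evaluate at grand covariate means.  Tukey HSD uses the studentized range
  with q = √2·|Δ|/se(Δ) from the model covariance; with two groups it equals
  the pooled t test.  The nonparametric fallback rank-transforms the outcome
  (mid-ranks) before the ANCOVA and runs pairwise Wilcoxon rank-sum tests
  (exact enumeration when small and tie-free).
* **Classification**: stratified 10-fold cross-validation (shuffled,
  random_state = 42 by default), out-of-fold decision scores pooled in
  subject order into a single ROC/AUC.  Pooling (rather than per-fold AUC
  averaging) gives each model one paired score vector per subject, which is
  what the DeLong test needs.  Estimators are standard scikit-learn
  pipelines (logistic regression, linear/RBF SVM, gradient boosting;
  XGBoost accepted when requested).
* **DeLong test**: midrank AUC estimator with variance/covariance from the
  empirical covariance of the structural components; two-sided normal p.
  Degenerate variance (identical scores) is flagged with p = 1.  Validated
  against a 10⁴-draw permutation oracle.
* **Serial mediation** (X → M1 → M2 → Y): three nested OLS fits plus the
  total-effect fit; serial indirect effect a₁·a₂·b.  Inference by
  nonparametric case-resampling bootstrap (default n = 5000) with
  bias-corrected (BC, not BCa) percentile intervals; an effect is significant
  iff the CI excludes zero.  The OLS decomposition
  c = c′ + a₁·d₁ + a₃·b + a₁·a₂·b holds to machine precision and is asserted
  in tests.  Variables can be z-scored first (`standardize=True`); the
  default reports raw-scale coefficients.
* **Phenotype derivations**: mean arterial pressure
  MAP = (2·diastolic + systolic)/3; amyloid-PET positivity by strict
  tracer-specific SUVR thresholds (AV45 > 1.11, FBB > 1.478).

## Synthetic data

The generators produce every input the pipeline needs and are pure
functions of (spec, seed).

* **Schemes**: the two study protocols above, with gradient directions from
  seeded electrostatic repulsion (antipodally symmetric Coulomb relaxation)
  — quasi-uniform, deterministic.
* **Phantoms**: white matter filling a rectangular grid (anisotropic tissue,
  FWVF 0.10), one perivascular tube running the grid (fluid tensor elongated
  along the tube, FWVF 0.90), spherical WMH blobs (FWVF 0.40), ground-truth
  maps and masks, optional Rician noise at a specified SNR.  The grid's x
  faces double as GM/deep boundaries for depth mapping.  Default contrasts
  mirror the expected ordering (pAs ≫ WM free water); geometry is idealized —
  straight tubes, homogeneous classes — so passing phantom tests demonstrates
  estimator correctness, not robustness to anatomical heterogeneity,
  partial-volume mixtures at tissue interfaces, or motion/eddy artifacts.
* **Cohorts**: phenotype tables with plausible aging-cohort marginals (ages
  36–100, realistic blood pressure, lipids, glycemia; CN/MCI/AD proportions
  0.55/0.39/0.06), features generated as linear functions of planted
  standardized effects (age → FWVF +0.30, MAP → FWAD −0.25, age → ALPS
  −0.30, diagnosis-group offsets, amyloid shifts) plus Gaussian noise, and a
  serial mediation chain generated on its own latent columns with
  configurable path coefficients, mirrored into clinical columns (diastolic
  BP, precuneus FWAD, Aβ SUVR, MoCA) by affine maps.  The marginals are
  plausibility, not a claim of distributional fidelity.
* **Component cohorts** for the n-selection procedure: per-subject component
  lists with strictly decreasing volumes where only the largest four carry
  the planted clinical association and smaller ones are high-variance noise,
  plus a varying component count so inclusion genuinely falls with n.

## Numerical choices and edge cases

* Optimizer: LM with gtol 10⁻⁸, ftol/xtol 10⁻⁸, function-evaluation caps
  (400 isotropic / 600 anisotropic per start) — noisy voxels on flat ridges
  otherwise burn thousands of evaluations for no measurable gain.
* Degenerate voxels (non-positive signal or vanishing b0) are excluded from
  volume fits and flagged in the provenance map with a logged count.
* ALPS ROI means use finite voxels only; negative means are clamped to 0
  with a warning; an all-NaN ROI is an error.
* ROI-assignment ties go to the lowest label id, with a warning.
* Exact ties in `optimize_n` break toward smaller n.
* Laplace solver: anchored connected components only; the discrete maximum
  principle (interior potential within [0, 1]) is asserted in tests.
* All tabular CLI output uses fixed float formatting, making repeated runs
  byte-identical.

## Problem sizes used in validation

The shipped validation uses 200 noiseless voxels for recovery, a 10³-voxel
phantom at SNR 30, 100 voxels for the isotropic limit, an 11-layer slab for
depth, 150 subjects for the n-selection cohort, n = 2000 with 1000 bootstrap
draws for mediation recovery, and 100–200 seeded replicates for null
coverage.  These sizes make the checks sharp (binomial/Monte-Carlo error
well below the tolerances asserted) while keeping the whole suite tractable
on a single CPU.

## Known limitations

* Voxelwise `f` at SNR ≤ 30 is variance-limited by information content, not
  by the optimizer; the spatial prior is what makes map-level accuracy
  possible, and it assumes piecewise-smooth media.
* The Rician correction uses a b0-based σ estimate (≥3 b0 volumes needed);
  spatially varying noise (parallel imaging g-factor) is not modelled.
* ALPS ROI placement on real data is the user's responsibility.
* The mediation model is linear with exogenous X; no causal identification
  beyond the standard product-of-coefficients decomposition is claimed.
* Real-data preprocessing (motion/eddy correction, T1↔DWI registration,
  segmentation) is upstream of this package; inputs are assumed
  co-registered.
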