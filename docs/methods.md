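# Methods

This note documents the models, numerical choices and limitations of
`strokeprog` at the level of detail a user needs to interpret its output.

## Problem setting

Input per case: a binary whole-brain vessel mask derived from CTA, a DWI
intensity volume with a binary ischemic-lesion mask, the affected
hemisphere (left/right), and the dichotomized 90-day outcome
(good = mRS < 3, poor = mRS ≥ 3).  The package does not segment vessels or
lesions; it consumes masks (a simple threshold fallback exists for
phantoms).  All volumes are handled in header-native orientation with axes
(x, y, z), z the slice axis, and spacing in mm taken from the NIfTI header.

## Vessel morphometry (40 features)

The vessel mask is thinned to a one-voxel centerline
(`skimage.morphology.skeletonize`); terminal spurs shorter than 2 voxels
are pruned, as thinning creates such twigs at surface irregularities and
they would otherwise inflate branch counts.  Centerline voxels with
exactly two 26-connected neighbors form chains; all others are node
voxels, and adjacent node voxels are merged into one junction node.
Isolated cycles become a single self-loop edge on a synthetic node.  In
2D (the axial maximum-intensity projection) the same machinery runs with
8-connectivity and pixel units.

Per-segment geometry is measured on a lightly smoothed polyline (moving
average, window 5, endpoints fixed): the raw voxel chain is a staircase
whose arc length overestimates oblique and curved segments by 4–8%, and
whose step-to-step direction jitter would dominate any turning-angle sum.
With smoothing, phantom experiments show total-length and DF errors below
2% at 0.5 mm grids.  Metrics:

* **DF** (distance factor): smoothed arc length / endpoint chord; ≥ 1,
  exactly 1 for straight segments.  Loops (coincident endpoints) are
  excluded from the DF average but counted in branch and length totals.
* **SOAM**: sum of angles between successive direction vectors divided by
  arc length (rad/mm); 0 for straight segments, → curvature 1/R on
  sampled arcs.  Two-point segments have no interior vertex and are
  excluded from the average.
* **Topology**: edge nodes = degree-1 vertices, network nodes =
  degree ≥ 3; degrees count incident edge ends so Σdeg = 2·E holds with
  self-loops.  The clustering coefficient is the mean local clustering
  over vertices of degree ≥ 2 (near-tree vasculature gives values near 0 —
  it is computed regardless).  Structure entropy is the Shannon entropy
  (bits) of the node-degree distribution; this is our concrete reading of
  an otherwise underdetermined name, and it is exported under that name so
  any alternative convention is visible.

The 2D feature set mirrors the 3D set with volume → projected area and
px units.  A grayscale projection is first enhanced with a Hessian-based
tubularity (Sato) filter and re-thresholded at a fixed quantile (0.90);
binary projections pass through unchanged.  Asymmetry features are
value(affected) − value(healthy) for each of the 20 descriptors, with
hemispheres split at the midpoint of the x extent (no registration — the
package assumes roughly centered heads; a mirror-symmetric mask yields
exactly zero asymmetry).  An empty hemisphere contributes zeros with a
warning.  Total: 10 (3D) + 10 (2D) + 20 asymmetry = 40, in a fixed
exported order.

## Lesion and ring radiomics (1,026 features)

The penumbra surrogate is the lesion mask dilated slice-wise with a
Euclidean disk of 10 pixels, minus the lesion.  Dilation is 2D in-plane
because DWI slices are ~6 mm thick against ~0.94 mm in-plane: a 10-voxel
3D ball would span 60 mm through-plane.  The ring is clipped at the
volume border and must be non-empty.

Per ROI, 513 features:

* 18 first-order statistics (energy, entropy, min, P10, P90, max, mean,
  median, IQR, range, MAD, robust MAD over [P10, P90], RMS, SD, variance,
  skewness, excess kurtosis, uniformity).  Variance/SD are population
  statistics; entropy and uniformity use the discretized histogram;
  constant ROIs have skewness = kurtosis = 0, entropy 0, uniformity 1.
* 39 texture features over four matrix families, computed on intensities
  re-binned to 32 equal-width levels inside the ROI (constant ROI → one
  level).  GLCM (8: contrast, dissimilarity, homogeneity, energy,
  correlation, entropy, cluster shade, cluster prominence) and GLRLM (13)
  are computed per direction over the 13 unique 3D displacement vectors at
  distance 1 and averaged; the GLCM is symmetric.  GLSZM (13) uses
  26-connected zones, NGTDM (5: coarseness, contrast, busyness,
  complexity, strength) 26-connected neighborhood means.  Degenerate
  single-level matrices fall back to the conventions above (correlation 0).
  The exact membership of the 18/8/13/13/5 sets follows the common
  radiomics catalogue; all names are exported so substitutions are visible.
* The same 57 features on each of 8 sub-bands of a single-level separable
  3D Haar wavelet transform (456).  Haar is orthogonal and has the
  shortest support, which matters for 16-slice DWI volumes.  Band
  coefficients are nearest-neighbor upsampled (×2 per axis) and cropped to
  the input shape so the original masks index them directly; bands are
  numbered wavelet1..wavelet8 in the fixed order LLL, LLH, LHL, LHH, HLL,
  HLH, HHL, HHH (letter order = axis order x, y, z).

GLRLM matrices are built with an iterative-shift dynamic program (runs of
length ≥ r via r−1 shifted conjunctions), validated against an explicit
line-walking enumeration in the tests.  Bin count, wavelet family and ring
radius are configurable (`RunConfig`).

Lesion + ring gives 1,026 features; with the 40 vascular features the
fused table has 1,066 columns in a stable, documented order.

## Selection and classification

Features are standardized (mean 0, SD 1) with parameters estimated on
training rows only.  Selection solves the label-regression lasso
min (1/2n)‖y − Xw‖² + λ‖w‖₁ (y = ±1) by cyclic coordinate descent on the
Gram matrix to a 1e−6 coefficient tolerance; the nonzero-coefficient set
(|w| > 1e−8) is the selection.  λ is chosen from a geometric grid by
stratified k-fold cross-validated accuracy of the downstream classifier,
with pooled out-of-fold predictions; ties break toward sparser models.  An
`n_features_override` picks the grid point closest to a requested support
size instead.  Note that, as specified, selection for tuning runs on the
full training table before fold evaluation, so tuned CV accuracy is
optimistic under the null; the held-out third is never touched until the
final evaluation and is unbiased.

The classifier stores the training cases (restricted to selected features,
standardized, columns ℓ2-normalized) as a dictionary with class labels.
A test vector x is coded by min ½‖x − Aα‖² + λ_code‖α‖₁ subject to α ≥ 0,
with λ_code = 0.01 (configurable).  The nonnegativity constraint is a
deliberate departure from unconstrained sparse coding: with standardized
features the two classes lie in approximately antipodal directions, so a
negative coefficient on a wrong-class column reconstructs a sample as well
as the right class and residuals lose class specificity — empirically,
unconstrained coding cost ~30 accuracy points on separable synthetic
tables while nonnegative coding recovers the Bayes solution.  Class
residuals r_c = ‖x − A δ_c(α)‖ use only class-c coefficients; the label is
argmin_c r_c and the ROC score (r_good − r_poor)/(r_good + r_poor + ε) is
oriented so larger = more poor-like.  An all-zero code falls back to the
majority training class with score 0 and a warning.

## Evaluation

* Welch two-sided t-tests per feature screen for univariate group
  differences (Student variant by flag); no multiplicity correction, as
  the screening count is descriptive.  Features constant in both groups
  get p = 1.
* ACC/SEN/SPE/PPV/NPV from the 2×2 table; the positive class is a
  parameter (default poor).  Empty predicted classes give NaN PPV/NPV
  with a warning.
* AUC by the Mann–Whitney statistic with half credit for ties; ROC by a
  sweep over unique thresholds.
* DeLong's test for paired AUCs via structural components (midranks);
  two-sided normal p-value; degenerate variance gives p = 1.
* Decision curves: NB(pt) = TP/n − (FP/n)·pt/(1−pt) on a 0.01–0.99 grid
  (step 0.01), with treat-all/treat-none references; SRC scores are mapped
  to (0, 1) by (score + 1)/2.
* Protocol: stratified 2:1 train/test split from the run seed; 10-fold
  stratified CV on the training portion (folds are clamped to the
  minority-class size with a warning on small cohorts); models refit on
  the full training portion before the single test-set pass; DeLong and
  decision curves on the test set.

## Synthetic data

Phantom generators close the loop without patient data.  Tube trees are
unions of capsules around polyline centerlines; per-segment length, DF and
SOAM and the endpoint/junction counts follow from the constructed geometry
in closed form.  Centerline coordinates are snapped to voxel centers:
a tube whose axis runs midway between voxel centers has even width and no
central voxel plane, and thinning then erodes whole branches.  Lesion
phantoms are Gaussian background (mean 100, SD 10, arbitrary DWI-like
units) plus an in-plane disk lesion of elevated mean; the cohort generator
gives poor-prognosis cases a rarefied tree on the affected side (1–2 side
branches versus 3) and a larger (7–8 px vs 4–5 px), brighter
(175 ± 25 vs 150 ± 8) lesion.  These contrasts are caricatures chosen to
make the downstream model learnable at n = 30; passing tests demonstrate
the pipeline's correctness and internal calibration, not clinical
performance — real cohorts have far lower effect sizes, scanner
heterogeneity, registration error and annotation noise, none of which the
phantoms emulate.  Default problem sizes (30-case cohorts on 64×64×24
vessel grids at 0.5×0.5×1 mm and 48×48×12 DWI grids at 0.94×0.94×6 mm;
n = 120 feature tables) keep a full run in tens of seconds while leaving
voxelization error well inside the stated tolerances.

## Known limitations

* Hemisphere splitting assumes a centered head; no mid-sagittal plane fit.
* No per-artery analysis (MCA/ICA): the morphometry is whole-brain.
* The 18/39-feature memberships and the structure-entropy definition are
  conventions; alternative catalogues would change individual values but
  not counts or pipeline behavior.
* SOAM on voxelized centerlines remains upward-biased for strongly curved
  segments even after smoothing; comparisons should stay within one
  resolution.
* The tuned CV accuracy is optimistic (selection precedes fold
  evaluation, by design of the protocol); use the held-out metrics for an
  unbiased estimate.
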