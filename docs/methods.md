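# Methods

`perifw` implements a pipeline for discriminating glioblastoma from brain
metastasis using only the microstructure of the peritumoral region, as seen
by single-shell diffusion MRI. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic benchmark does and
does not demonstrate.

## Signal models

**Single tensor.** The diffusion-weighted signal in a voxel is modelled as
`S_j = S0 exp(-b_j g_j^T D g_j)` for b-value `b_j` (s/mm^2) and unit gradient
direction `g_j`. Fitting is linear in the log domain with design
`(-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1)`. An
ordinary least-squares pass supplies per-measurement weights (the squared
predicted signal), followed by one weighted solve — the standard correction
for the heteroscedasticity introduced by the log transform. Non-positive
signals are floored at 1e-6 of the voxel's maximum before the log.
Eigenvalues are clipped to [0, 5e-3] mm^2/s before any scalar map (FA, MD,
AX = lambda1, RAD = (lambda2+lambda3)/2) is derived; FA of an all-zero
tensor is defined as 0.

**Bi-tensor free-water model.** Each voxel mixes a tissue tensor `D_t` with
an isotropic free-water compartment of fixed diffusivity
`d_water = 3.0e-3 mm^2/s` (body-temperature water):

    S_j = S0 [ (1 - f) exp(-b_j g_j^T D_t g_j) + f exp(-b_j d_water) ]

`f` is the free-water volume fraction (FW-VF). At a single b-value this
decomposition is only weakly identified: a tissue tensor with inflated
eigenvalues can absorb most of an isotropic water compartment, leaving the
data residual nearly flat along a valley in `f`. Two choices restore useful
behaviour:

1. *Interpolated initialization.* The voxel's mean diffusion-weighted
   attenuation is interpolated **linearly** between a configured pure-tissue
   attenuation `exp(-b * MD_tissue)` (default `MD_tissue = 0.7e-3 mm^2/s`,
   a typical parenchymal mean diffusivity) and the pure-water attenuation
   `exp(-b * d_water)`. Linear interpolation is used because the bi-tensor
   signal is exactly linear in `f`; interpolating log-attenuations instead
   would systematically underestimate `f` (convexity of log-sum-exp). The
   init is 0 at the tissue bound, 1 at pure water, 0.5 at the attenuation
   midpoint, and monotone in the voxel's signal loss.
2. *Anchored refinement.* `f` is then refined by a grid search (coarse step
   0.02 within ±0.2 of the init, fine step 0.005) minimizing the mean
   squared signal residual plus a quadratic anchor `0.01 (f - f0)^2`. At
   each candidate `f` the tissue tensor is re-fitted by WLS on the
   water-corrected attenuation `(A - f A_w) / (1 - f)`, with tissue
   eigenvalues clipped to [1e-4, 2.5e-3] mm^2/s — deliberately below
   `d_water`, so the tissue compartment cannot impersonate free water. On
   noiseless data the residual term dominates and the refinement lands on
   the exact `f`; under noise the anchor keeps the estimate from sliding
   along the degenerate valley. Voxels whose estimate pins to the edge of
   the search window are flagged unconverged.

Measured on the canonical test tensor `diag(1.5, 0.4, 0.4)e-3` over
`f ∈ {0, 0.25, 0.5, 0.75, 1}` with 500 voxels per cell, the fit achieves
MAE(f) ≤ 0.02 noiseless and ≤ 0.03 at SNR 40 (Rician). The free-water
corrected maps (FW-FA, FW-AX, FW-RAD) apply the standard scalar formulas to
the fitted tissue tensor.

Everything is vectorized across voxels (batched normal equations and
eigendecompositions), so fitting a whole dilated-edema mask costs seconds.

## Synthetic phantoms

Real cohorts of this kind are IRB-restricted, so the package generates the
study inputs. Each phantom has an ellipsoidal brain, one or (with
probability 0.1) two spherical tumors with a surrounding edema shell, a
ground-truth FW-VF field, and ground-truth tissue tensors; DWI is simulated
with the same bi-tensor forward model (3 b=0 volumes + 30 directions at
b = 1000 s/mm^2, grid 64x64x32 at 1.72x1.72x3 mm) and Rician noise
(default b0 SNR 30, a typical clinical value; Gaussian noise available for
debugging).

The class contrast emulates the biology the classifier exploits:

| parameter                  | glioblastoma | metastasis |
|----------------------------|:---:|:---:|
| edema mean FW-VF           | 0.55 | 0.80 |
| texture correlation length | 4 mm | 15 mm |
| heterogeneity amplitude    | 0.12 | 0.03 |
| radial gradient amplitude  | 0.10 | 0.00 |

Metastatic (vasogenic) edema is fluid-dominated: high, smooth FW-VF.
Glioblastoma (infiltrative) edema carries tumor cells: lower mean FW-VF with
short-range mottling and a radial trend (least free water next to the tumor
boundary, where infiltration is densest). Texture is a Gaussian random field
(white noise smoothed at the correlation length), de-meaned and
unit-normalized over the edema before scaling, so the realized edema mean
tracks the configured target. The class means and texture statistics are
free parameters of the generator, not calibrated to any patient cohort —
no quantitative per-class FW-VF statistics were available to calibrate to.

What the phantoms do **not** model: anatomically realistic geometry or fiber
architecture (tissue tensor orientations are random), structural contrast
(T1/T2/FLAIR), scanner artifacts, partial volume at tissue interfaces, or
imperfect segmentation masks. Passing the benchmark therefore shows that the
pipeline recovers and exploits class-distinct free-water texture when it
exists at the configured effect size; it does not certify clinical accuracy.

## Patch sampling

Per subject, the patch budget is `floor(edema voxels / 256)` (minimum one
when edema is non-empty). Patches are 16x16 axial windows — the in-plane
choice matches the anisotropic voxel and the 2D classifier. A candidate
window is admissible when its center voxel lies in edema, its footprint
contains zero tumor voxels and stays inside the brain, and at most 20%
(51/256) of the footprint falls on healthy (non-edema, non-tumor) brain.
Candidates are drawn by jittering a window around a uniformly chosen edema
voxel, with rejection capped at 1000 attempts per patch; if the budget
cannot be placed the feasible subset is returned and a warning logged,
never a fabricated patch. With multiple lesions the edema union is sampled,
so every peritumoral area contributes. All of a subject's patches inherit
its class label.

Augmentation shifts each source patch in-plane (up to ±8 voxels), under the
same zero-tumor and ≤20%-healthy-brain constraints; one augmentation per
source is the default. Test subjects are never augmented.

Intensities are normalized deterministically per map kind: FA, FW-FA and
FW-VF are used raw (already in [0, 1]); diffusivity maps are scaled by the
fixed physical range [0, 3e-3] mm^2/s. Map combinations (e.g. FW-VF +
FW-FA) are two-channel patches sampled at identical coordinates.

## Patch classifier and majority voting

The CNN is implemented directly on NumPy (im2col convolutions, explicit
backpropagation), which keeps the whole pipeline dependency-light and makes
training bit-reproducible on one CPU from a single seed. Default
architecture: six 3x3 convolutions with ReLU and filter counts
(16, 16, 32, 32, 64, 64); 2x2 average pooling after conv 2 and conv 4; 2x2
max pooling after conv 6; global average pooling of each feature map; a
dense softmax head over the two classes. Training uses RMSprop (learning
rate 1e-3, rho 0.9) on categorical cross-entropy, batch size 64, 100 epochs
by default. No early stopping, dropout or weight decay — shift augmentation
is the anti-overfitting device. Class balance is enforced by randomly
capping the majority class's patch count before training.

A subject's label is the majority vote over its patch argmax labels; ties
are broken toward the class with the higher mean patch probability and
flagged. The fraction of patches voting glioblastoma doubles as the
subject-level ROC score.

## Texture baselines

*Gabor + random forest*: 4 wavelengths {2, 4, 8, 16} voxels x 4 orientations
{0°, 45°, 90°, 135°}, sigma = 0.56 wavelength, unit aspect ratio; mean and
standard deviation of each filter's response magnitude on the
mean-subtracted patch (32 features). Wrap-around filtering keeps the bank
exactly equivariant under 90° patch rotation.

*Radiomics + random forest*: first-order statistics (mean, variance,
skewness, kurtosis, 16-bin entropy, energy, percentiles, range), GLCM
contrast/correlation/energy/homogeneity at distance 1 averaged over 4
directions, and GLRLM run statistics (SRE, LRE, GLN, RLN, RP) averaged over
4 directions, on a 16-level discretization of the map's fixed physical
range — 19 features. Shape/size descriptors are excluded: they are constant
across fixed 16x16 patches. Degenerate constant patches get
skewness/kurtosis/correlation defined as 0 and are flagged.

Both baselines are reduced by PCA to the smallest component count covering
98% of the training variance (fitted strictly on training folds) and
classified by a 500-tree random forest with sqrt-features splits.

## Evaluation

Glioblastoma is the positive class: sensitivity is glioblastoma recall,
specificity metastasis recall; percentages are rounded to integer percent in
tabular output, and a metric with a zero denominator is reported as
not-available, never 0. Cross-validation is patch-level 5-fold by default
(shuffled, near-equal folds), mirroring the protocol of interest; a grouped
subject-level mode is provided because patch-level folds allow one
subject's patches to span train and validation — the package measures
(rather than silently fixes) that leakage direction. ROC curves enumerate
all score thresholds; AUC is the Mann-Whitney statistic with ties counted
half. Correlated AUCs are compared with the DeLong structural-components
(placement-value) estimator and a two-sided normal test; comparing a
classifier with itself yields p = 1. Pooled validation scores (not
fold-averaged curves) are the default for CV ROC.

## Problem sizes

The benchmark experiment uses 20+20 training and 5+5 held-out subjects at
the default grid, with CNN trainings in experiments run for 25-30 epochs
(the toy cohorts converge long before the 100-epoch library default). The
free-water recovery grid uses 500 voxels per (f, SNR) cell. The null-cohort
(gap removed) cross-validation uses 10+10 subjects sampled from ground-truth
maps. These sizes are the package's benchmark conditions; all are
configurable.

## Known limitations

- Single-shell free-water estimation remains intrinsically
  init-anchored; with strongly atypical tissue (mean diffusivity far from
  the configured tissue bound) the init bias propagates into `f`.
- Patch admissibility needs edema regions that can host a mostly-edema
  16x16 in-plane window; very thin shells yield fewer patches than the
  budget (logged, and those subjects carry less evidence into the vote).
- The NumPy CNN is single-threaded by design; it is sized for 16x16 inputs
  and would not scale to large images.
- No preprocessing (denoising, eddy/motion correction, skull stripping) or
  mask registration is included; masks and DWI are assumed co-registered.
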