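# Methods

`pvskit` implements a two-part analysis: automated segmentation of
perivascular spaces (PVS) from T1-weighted-like 3D volumes, and
Gamma/log-link generalized linear modelling of PVS volume fractions
against stress (cortisol), hypertension (ACE) and inflammatory plasma
biomarkers, including physiological x inflammatory interactions.
Because the clinical data this kind of analysis targets are access
restricted, a synthetic-data module generates tube phantoms and
simulated cohorts with known ground truth; every claim the test suite
makes is a claim about those synthetic conditions.

## Imaging chain

### Noise model and noise-scale estimation

Magnitude MR images carry Rician noise: `M = sqrt((A + g1 s)^2 + (g2
s)^2)` with independent standard-normal `g1, g2` and noise scale `s`
(intensity units).  The scale is estimated from local pseudo-residuals
— each voxel minus the median of its 6-neighborhood, scaled by
`sqrt(6/7)` — summarized by `1.4826 * MAD`, a robust scale that ignores
edges.  That statistic estimates the *Gaussian-equivalent* noise scale,
which understates `s` at low SNR (for a pure-noise Rayleigh field it
converges to `0.655 s`).  The estimator therefore inverts the Rician
variance-correction function `xi(theta)` (`Var(M) = xi * s^2`, `theta =
A/s`) by a fixed-point iteration on the volume's mean/scale ratio and
divides the raw estimate by `sqrt(xi)`.  In simulation the estimate is
within ~8% on pure-noise volumes of 64^3 and within ~2% at SNR 20.

### Non-local-means denoising

The filter replaces each voxel by a patch-similarity-weighted average
over a search window: `w(v, u) = exp(-d^2 / h^2)` where `d^2` is the
mean squared intensity difference between the 3x3x3 patches at `v` and
`u` (patch radius 1 voxel, chosen to preserve single-voxel-scale
structures such as PVS).  Defaults: search radius 3 voxels, bandwidth
`h^2 = 2 s^2 P` with `P = 27` patch voxels, both configurable
(`h_factor` rescales the bandwidth).  Patches are clipped at volume
edges and the patch mean renormalized over the voxels actually present.

Rician bias correction (default on) averages squared intensities with
the same weights and removes the noise floor, `sqrt(max(E[M^2] - 2 s^2,
0))`, the appropriate debiasing because `E[M^2] = A^2 + 2 s^2`.  Two
degenerate-input conventions are worth noting.  With `s = 0` the
bandwidth collapses and the input is returned unchanged.  A constant
volume passes through exactly when `s` is estimated (the estimate is 0)
or when bias correction is off; supplying a large `s` for a noise-free
constant volume deliberately lands below the noise floor and clamps at
0 — the correction formula is kept faithful rather than special-cased.

### Frangi vesselness

The Hessian is computed per scale by separable correlation with 1D
Gaussian-derivative kernels in voxel units.  Kernels are sampled
Gaussians (radius `int(4 sigma + 0.5)`, at least 1) with
moment-corrected weights so the discrete operators are exact on
low-order polynomials: constants map to exactly zero, `d/dx x = 1`,
`d2/dx2 x^2 = 2`.  At the sub-voxel end of the published scale range
(0.1 voxel) the kernels reduce to central finite differences, i.e.
near-raw-Hessian behaviour; the scale is honored literally.  Responses
are multiplied by `scale^2` (gamma = 1 normalization) so the
across-scale maximum is meaningful.

Eigenvalues are sorted by magnitude, `|l1| <= |l2| <= |l3|`, and the
vesselness is

    V = (1 - exp(-Ra^2 / 2 a^2)) * exp(-Rb^2 / 2 b^2) * (1 - exp(-S^2 / 2 c^2))

with `Ra = |l2|/|l3|`, `Rb = |l1|/sqrt(|l2 l3|)`, `S` the Hessian
Frobenius norm, evaluated only where the dark-tube sign condition
`l2 > 0, l3 > 0` holds (PVS are hypointense on T1w; polarity is
configurable).  Sensitivities default to `a = b = 0.5`; `c` defaults to
half the maximum Frobenius norm per scale ("auto").  The multiscale map
is the per-voxel maximum over scales, with the argmax scale kept as a
secondary map.  The default scale list is five logarithmically spaced
values spanning 0.1-5 voxels; the binary PVS mask is `V >= 1e-5`
(inclusive), both configurable.

The production path (scipy separable correlation + batched symmetric
eigendecomposition) is checked in the test suite against a brute-force
path: explicit nested-loop convolution with independently derived
kernels and a closed-form trigonometric 3x3 eigen-solve, agreeing to
1e-8 on small volumes.

### Quantification and outlier handling

ROI masks are unions of parcellation labels grouped as CSO (centrum
semiovale, a union of atlas white-matter regions) or BG (basal
ganglia).  The PVS volume fraction of an ROI is the PVS voxel count
*inside* the ROI divided by the ROI voxel count (PVS voxels outside
never count); volumes in mm^3 use the voxel dimensions.  Per-subject
fractions outside `[Q1 - 1.5 IQR, Q3 + 1.5 IQR]` are flagged as
outliers, with quartiles fixed to linear-interpolation (type 7)
quantiles because the quartile convention changes flags on small
samples.  A subject flagged in either region is excluded from every
model, giving one analysis sample.  The filter is deliberately
single-pass; re-applying it to its own kept set could flag more values.

## Statistical chain

PVS volume fractions are positive and right-skewed, so the conditional
mean is modelled as `E[y] = exp(X b)` with a Gamma response.  Model
forms: a main effect of one biomarker; cortisol x inflammatory marker;
ACE x inflammatory marker — each with sex (reference female), age,
z-scaled BMI and hippocampal volume as covariates, optionally an APOE4
positivity indicator, diagnosis (reference CN) and medication factor
covariates (reference code 0), and optionally restricted to a diagnosis
subgroup.  Continuous predictors are median-centered on the analysis
sample; BMI is z-transformed (its skewness motivates the different
treatment); the interaction column is the product of the two centered
terms, so it vanishes for a subject at both medians.  A `standardize`
switch additionally divides centered predictors by their sample SD,
giving per-SD coefficients; centering and scaling are linear
reparameterizations, so fitted means and p-values are unaffected by the
switch.  Missing data are handled by listwise deletion per model with
logged counts.

Fitting is iteratively reweighted least squares; for the Gamma/log-link
pair the working weights are identically 1, so each step is an OLS
solve (via one QR factorization) of the working response `z = eta + (y
- mu)/mu`.  Convergence: `max|db| < 1e-8` within 100 iterations, with
the outcome recorded in a flag.  Dispersion is the Pearson chi-square
estimate over `n - p`; standard errors come from the scaled inverse
Fisher information; inference is two-sided Wald at 0.05 with no
multiple-testing correction.  Coefficients are reported on the log
scale (`b`), exponentiated (`std_beta`, a multiplicative effect on the
mean fraction), and with standard errors on both scales (`se` log
scale, `se_exp` by the delta method) — the exponentiated column is what
association tables of this kind usually print, with values clustering
around 1 and an intercept near the mean fraction.

Fitted interaction curves evaluate `mu = exp(x'b)` over a grid of the
centered exposure at fixed moderator levels (typically its observed
minimum and maximum), all other covariates at reference, with pointwise
95% bands `exp(x'b +/- 1.96 sqrt(x' Cov x))`.  Residual diagnostics
report Gamma deviance residuals, their skewness/kurtosis, and a
normal-quantile table for QQ plotting.

## Synthetic data

### Tube phantoms

Tubes are capsules (cylinder plus hemispherical caps) around gently
curved three-point polylines, rendered dark (default 30) on a brighter
tissue background (default 100, arbitrary units) inside two disjoint
ROI blocks labelled 1 ("CSO-like") and 2 ("BG-like").  A voxel belongs
to a tube iff its center lies within the radius of the centerline —
deliberately crisp so a brute-force distance count reproduces the truth
mask exactly; an optional partial-volume flag (default off) ramps
intensity linearly within 0.5 voxel of the surface.  Defaults: 64^3
voxels, radius 1-2 voxels, length 10-22 voxels, isotropic 1 mm.  When a
target volume fraction is requested (scalar or per-ROI), tubes are
added until the rasterized in-ROI count reaches the target, so the
achieved fraction overshoots by at most one tube (within +-20% relative
for fractions around 1%).  Rician noise is added with the exact
magnitude formula; phantom SNR is defined as tissue intensity over the
noise scale, with SNR 10 as the standard stress condition.

### Simulated cohorts

Each subject draws biomarkers from log-normal marginals in ng/mL (the
skew expected of plasma markers; the locations are plausible values,
not calibrated to any cohort), demographics from the study-like
distributions (age N(74.85, 7.09) clipped to 55-90, 61.7% male, BMI
N(26.4, 3.9) kg/m^2, hippocampal volume N(6500, 900) mm^3), and
categorical covariates (diagnosis CN/MCI/AD, APOE4 copies, medication
history codes 0-3, current-use codes 0-2) from fixed probabilities.
Outcomes follow the same model the fitter assumes: the linear predictor
is built through the *same* design-preparation code (standardized
convention), and `y ~ Gamma(k, mean mu)`.  Default coefficients mirror
the magnitudes of the published association tables — CSO intercept
`exp(b0) = 0.02`, a negative cortisol x TNF-a interaction `exp(b) =
0.93`, strong positive age (1.24/SD) and BMI (1.07/SD) effects; BG
intercept 0.04 with a TRAIL main effect 1.02 and a cortisol x CRP
interaction 0.98.  The default shape `k = 2.5` is chosen so per-SD
coefficient standard errors come out near 0.03 at n around 460, the
precision the printed tables imply (`phi ~= n * SE^2 ~= 0.4`).

What the generators do **not** emulate: whole-brain anatomy, bias
fields, scanner-specific artifacts, partial-volume texture of real
white matter, and any real dependence structure among biomarkers
(markers are drawn independently).  Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not clinical
performance on real scans.

## Validation harness and problem sizes

The phantom experiment draws each phantom's per-ROI target fraction
from the cohort model's Gamma marginal (clipped to [0.001, 0.08]), so
severity varies across phantoms the way it does across subjects; rank
correlation between estimated and true fractions is meaningful only
under such variation.  It reports Dice against truth at the operating
threshold and across a threshold sweep (always including 1e-5) with the
argmax, per-ROI fraction errors, and the Spearman correlation.  The
published threshold 1e-5 was tuned by expert reading of clinical 1.5T
data; on noisy synthetic phantoms it over-segments (noise passes the
structureness term), so validation emphasises the sweep optimum, and
the phantom harness defaults to Frangi scales {0.5, 1, 1.5, 2} voxels
spanning the phantom tube radii rather than the full 0.1-5 clinical
default.  Representative desk-scale results (20 phantoms, 64^3, SNR
10): sweep-best mean Dice ~0.68, volume-fraction Spearman ~0.97,
denoising RMSE reduction ~63% at 5% noise.

Statistical calibration runs at the study's analysis scale (n = 456):
across 200 simulated cohorts the mean interaction estimate is within
0.02 of the generating value on the log scale, and under a null
interaction the Wald test rejects at a rate within [0.03, 0.07] over
2000 replicates.  These sizes keep the full suite within a few minutes
on one CPU.

## Known limitations

* The sigma estimator assumes a spatially uniform noise level; parallel
  imaging with spatially varying noise maps is out of scope.
* The IQR outlier fence on a Gamma(2.5) population flags more subjects
  (~7%) than a near-lognormal clinical distribution would; exclusion
  truncates the outcome tail and slightly attenuates the fitted
  intercept in the phantom-to-model chain.
* Vesselness at anisotropic voxels is computed in voxel units (scales
  are voxels, matching the published processing); strongly anisotropic
  grids would need resampling first.
* No FLAIR-based white-matter-hyperintensity exclusion is modelled; on
  real T1w data, WMH could masquerade as PVS.
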