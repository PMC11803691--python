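# Methods

This note documents the models, parameter choices, numerical decisions and
limitations of the package. It states no empirical result that the
test-suite or `scripts/acceptance.py` does not itself compute.

## Signal model and T2* fitting

The decay of the gradient-echo magnitude signal is modelled as
mono-exponential,

    S(TE) = S0 · exp(−TE / T2*),

with S0 the amplitude at TE = 0 ("proton density map") and T2* the
effective transverse relaxation time in milliseconds. The fit minimises the
sum of squared residuals over all acquired echoes. Two-stage scheme:

* **Initialisation** — ordinary least squares of ln S on TE using only the
  strictly positive samples (slope = −1/T2*, intercept = ln S0). On
  noiseless exponential data this is already exact to machine precision.
  Fewer than two positive samples, or a slope that is not meaningfully
  negative (< −1e−12, guarding against float noise on constant signals),
  marks the voxel unfittable.
* **Refinement** — damped Gauss–Newton (Levenberg–Marquardt) steps on
  (S0, R2* = 1/T2*). The model has two parameters, so the normal equations
  are solved in closed form and the whole volume is refined as one batched
  numpy problem; a 64³ grid fits in a few seconds on one CPU. Only
  SSE-improving steps are accepted, so the refined SSE never exceeds the
  SSE at the (box-projected) starting point. Non-positive samples are kept
  in the nonlinear SSE (they are real measurements) but excluded from the
  log-domain initialiser.

**Constraints.** T2* is confined to (0, 1000] msec during fitting. The cap
is deliberately twice the 500 msec *reporting* threshold: near-fluid voxels
(amniotic fluid, CSF) then fit stably instead of diverging, and are
excluded later at reporting time — mirroring an analysis that thresholds
ROI means rather than the fit itself. Voxels that cannot be fitted carry
NaN plus a zero validity flag and are excluded from every downstream mean,
texture or map statistic; they are never silently zero-filled.

**ROI means.** The organ mean T2* averages in-mask, valid voxels with
T2* < 500 msec (threshold configurable). The threshold excludes
fluid partial-volume voxels, whose T2* is several-fold longer than tissue.

**Precision at the emulated protocol.** For the five echo times
(11.2–194.7 msec) and additive noise with SD = (mean first-echo
signal)/SNR, the Cramér–Rao bound at T2* ≈ 95 msec and first-echo SNR 20
gives sd(T2*) ≈ 1.97 σ ≈ 9 % relative per voxel, i.e. a median absolute
relative error of ≈ 6 % for any unbiased voxelwise estimator. Per-voxel
precision at this SNR is therefore intrinsically limited; organ means,
averaging 10³–10⁴ voxels of largely independent noise, recover the true
tissue mean to well under 1 % (both quantities are measured by the
acceptance script).

## Placental morphometrics

All three measures derive from the binary mask alone:

* **Volume** = foreground voxel count × voxel volume (mm³). Reported in
  mm³; any rescaling to mL is left to presentation layers.
* **Distance map** — anisotropy-aware Euclidean distance transform
  (scipy.ndimage, `sampling=spacing`): each foreground voxel receives the
  distance in mm to the nearest *background voxel centre*. The grid is
  padded by one background layer first, so masks touching the grid edge
  are treated as bounded there. Under this convention an isolated voxel
  scores one voxel spacing (interior values are strictly positive), which
  matches the intended reading of the morphological map.
* **Morphology score** = mean + SD of the distance map over foreground
  voxels. The SD uses the population (N) denominator — the voxels are the
  entire population of the mask, not a sample; the choice is pinned and
  tested. Though computed on mm-valued distances, the score is reported as
  a dimensionless shape index: it is not a direct physical measurement of
  any single anatomical length. Thin, uniform discs score low; bulkier or
  unevenly thick shapes score high.
* **Maximum thickness** = 2 × the distance-map maximum — the diameter of
  the largest inscribed sphere, in mm.

Masks are used exactly as given; no hole-filling or component selection is
applied by default (a `select_largest_component` flag exists for cohorts
with fragmented segmentations).

## Placental texture (GLCM correlation)

The texture input is the fitted T2* map inside the placental mask (a flag
allows the first-echo magnitude instead). Voxels at or above the 500 msec
threshold are excluded first, for consistency with the ROI mean. Pipeline:

1. **Quantisation** — linear binning into L = 32 grey levels between the
   1st and 99th percentile of the in-mask values (robust to outliers, and
   invariant to affine rescaling of the map). A constant field is
   degenerate: the texture is NaN, not 0.
2. **Accumulation** — co-occurring level pairs at the three axis-aligned
   unit offsets and their negations, both voxels in-mask, each pair counted
   in both orders (symmetric matrix), normalised to sum 1. Accumulation is
   fully 3D because the acquisition is near-isotropic (2.5 mm). The
   established GLCM implementations are 2D and unmasked, so the masked 3D
   accumulation is implemented directly and verified against
   pair-enumeration oracles (and against scikit-image on 2D slices).
3. **Correlation** — Σᵢⱼ p(i,j)(i−μ)(j−μ)/σ², with μ, σ the marginal
   moments of the symmetric matrix. Range [−1, 1]; +1 for perfectly smooth
   ramps, ≈ 0 for spatially white fields, lower values for more
   heterogeneous tissue.

All parameters are pinned in `TextureParams` and echoed into output
metadata. Absolute texture values depend on these choices (levels, offsets,
quantisation); only *relative* comparisons under a fixed parameter set are
meaningful, and the tests accordingly verify direction (smoother fields →
higher correlation), not absolute levels.

## Cohort statistics

Two-sided tests at α = 0.05 throughout; complete-case handling per test
(rows missing a variable are dropped for that test only, with n reported).

* **Spearman** correlation on midranks, two-sided p from the t
  approximation with n−2 df.
* **Partial Spearman** — rank-transform x, y, z; residualise rank-x and
  rank-y on rank-z by OLS; Pearson correlation of the residuals; p from a
  t distribution with n−3 df. Equivalent to the closed-form rank partial
  correlation (tested to 1e−10, and against pingouin). A constant
  covariate degenerates to the plain Spearman correlation with a warning.
* **ANCOVA** — OLS of metric on group + covariate (statsmodels); the group
  p is the coefficient t-test. Estimated marginal means are model
  predictions for each group at the pooled covariate mean, with SEs from
  the coefficient covariance; the EMM difference is invariant to covariate
  recentering.
* **Interaction tests** — OLS y ~ x × group. For the GA-adjusted
  association panels, y and x are first rank-transformed, residualised on
  ranked GA and standardised, so the interaction coefficient is on the
  same adjusted-rank scale as the partial correlations (the scale is
  explicitly this; raw-scale interaction is available by omitting the
  covariate).
* **Mann–Whitney U** — exact enumeration when the combined sample is ≤ 12
  without ties, tie-corrected normal approximation otherwise.
* **Shapiro–Wilk gate** — decides mean ± SD vs median (IQR) reporting;
  n < 3 or constant samples default to nonparametric.
* **BH-FDR** — step-up adjusted p-values implemented from the definition
  (q(i) = min over j ≥ i of p(j)·m/j, clipped at 1), applied within each
  configured family: the between-group comparison table, the pooled GA
  correlations, and each association panel separately. Family membership
  is recorded in the report, since reasonable analyses could group tests
  differently.

The default analysis plan assigns ANCOVA (GA-adjusted) to the metrics that
trend with GA in the emulated study — brain T2*, placental T2*, placental
volume — and plain ANOVA to texture, thickness and morphology; GA and
maternal age are compared by Mann–Whitney. The plan is configuration, not
hard-coded behaviour.

## Synthetic data generator

The generator emulates the target acquisition and cohort so that every
pipeline stage can be validated against known truth.

**Phantom (image level).** A disc-like placenta (default radius 45 mm,
thickness 24 mm) whose rim carries outward-only sinusoidal lobes and whose
local thickness is modulated by a smooth in-plane bump pattern; one
perturbation amplitude drives both, so amplitude 0 is a rotationally
symmetric uniform disc and larger amplitudes give strictly bulkier shapes
(outward-only lobes make the mask a superset of every smaller-amplitude
mask — inward clefts would otherwise reduce the mean boundary distance and
break monotonicity of the morphology score). An ellipsoidal fetal brain
(default semi-axes 32/28/26 mm) sits elsewhere in the grid; everything else
is amniotic-fluid-like background with T2* = 600 msec (> the 500 msec
threshold) so that fluid exclusion is exercised. Organ T2* fields are
Gaussian random fields: smoothed white noise re-standardised over the mask
(placenta: mean 95, SD 15 msec, correlation length 12 mm emulating
lobulation; brain: mean 210, SD 8 msec), clipped to (5, 450) msec. The
forward model is the mono-exponential decay at the five protocol echo
times; noise is additive Gaussian with SD = (mean in-mask first-echo
signal)/SNR, truncated at zero — a documented simplification of Rician
magnitude noise, adequate at the simulated SNR ≥ 10 regime. Default
first-echo SNR: 20.

**Cohort (table and image mode).** Per fetus, GA is uniform within group
ranges reproducing the emulated demographics — control GA ~ U(30, 39) wk
(median 34.5), CHD ~ U(30, 34) wk (median 32.0), both bounded below by the
30-week inclusion cutoff — so GA confounds every contrast by design. Organ
T2* means follow

    T2*_organ = intercept + slope·GA + offset·1[CHD] + loading·u + ε,

with u a shared standard-normal latent factor whose loadings are chosen so
the GA-adjusted brain–placenta correlation equals `latent_corr` (default
0.46), and ε independent residual noise. Default calibration (placental
slope −6.8 msec/wk, brain slope −3.6 msec/wk, CHD offsets −14 and −16 msec,
residual SDs 18 and 24.6 msec, intercepts set so the control EMMs at the
pooled mean GA are ≈ 97 and 218 msec) reproduces the qualitative structure
the statistics stage must handle: steep placental and shallower brain GA
decline, group deficits masked by the GA gap in raw means, and a positive
adjusted brain–placenta association. Texture couples to the placental T2*
residual (partial correlation 0.46 by construction); volume has a positive
GA slope; morphology and thickness are GA-independent group-shifted
Gaussians. In image mode each fetus is rendered as a phantom whose field
means equal its true organ means, with CHD placentas given a larger
perturbation amplitude (2 → 6 mm) and a shorter T2* correlation length
(12 → 6 mm); both group levels sit on the verified-monotone branch of the
respective metric. A `CohortSpec.null()` constructor zeroes every slope,
offset and correlation (and removes the GA gap) for type-I-error
calibration. A (spec, seed) pair fully determines all outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: fetal and maternal motion, coil/bias fields,
Rician noise at low SNR, susceptibility and B0 effects, anatomically
realistic organ shapes, segmentation error (masks are exact), and any
regional structure beyond a single correlation length. Recovery results on
phantoms bound the method's numerical behaviour, not its clinical accuracy.

## Problem sizes and runtime

Tests and the acceptance script size their simulations for a single CPU:
the noiseless and noisy recovery checks use the full 64³ grid; oracle
comparisons run on ≤ 20³ masks (the O(n²) EDT oracle) and ≤ 16³ images
(pair enumeration); null calibration uses 400 table-mode cohorts and the
confounded-recovery protocol 200; the end-to-end image-mode check renders
12 phantoms. The full suite runs in well under a minute of compute-heavy
work; the acceptance script in ≈ 20 s.

## Known limitations

* Mono-exponential decay only; multi-compartment or stretched-exponential
  models are out of scope, as are motion and susceptibility correction
  (the emulated single-shot acquisition freezes motion per slice; echoes
  are assumed aligned).
* Per-voxel T2* precision at first-echo SNR 20 is bounded at ≈ 6 % median
  relative error by the Cramér–Rao bound of the 5-echo protocol (see
  above); studies needing tighter voxelwise maps require more echoes,
  higher SNR, or spatial regularisation, which this package deliberately
  does not apply.
* Absolute texture and morphology values are parameter-convention-bound;
  only within-convention comparisons are meaningful.
* The statistics stage covers the fixed two-group, single-covariate design;
  mixed-effects models, Bayesian alternatives and subtype stratification
  are out of scope.
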