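# fetalt2star

Quantitative T2* relaxometry of the placenta and fetal brain from multi-echo
gradient-echo MRI, for researchers studying in-utero oxygenation — in
particular the relationship between placental function and fetal brain
development in pregnancies affected by congenital heart disease (CHD).

T2* (the effective transverse relaxation time) shortens with increasing
deoxyhemoglobin concentration (the BOLD effect), so organ-mean T2* serves as
a noninvasive proxy for tissue oxygenation. The package implements the full
quantitative chain from raw multi-echo magnitude images to cohort-level
statistics:

1. **Relaxometry** — voxelwise mono-exponential fitting of
   S(TE) = S₀·e^(−TE/T2\*) by nonlinear least squares over all echoes
   (log-linear initialisation, batched Levenberg–Marquardt refinement),
   and ROI means restricted to T2\* < 500 msec to exclude amniotic-fluid /
   CSF partial-volume voxels.
2. **Placental morphometrics** — volume (foreground count × voxel volume),
   a morphology score (mean + SD of the Euclidean distance-to-boundary map;
   higher = bulkier, less uniformly shaped placentas) and a
   maximum-thickness estimate (2 × the largest distance value).
3. **Placental texture** — grey-level co-occurrence matrix (GLCM)
   correlation of the masked 3D T2* map; lower values = more heterogeneous
   tissue.
4. **Cohort statistics** — Spearman correlations with gestational age (GA),
   GA-adjusted partial Spearman correlations (rank residualisation),
   ANCOVA with estimated marginal means at the pooled mean GA, one-way
   ANOVA, Mann–Whitney U, Shapiro–Wilk reporting gates, interaction tests,
   and Benjamini–Hochberg FDR within configurable families.
5. **Synthetic data** — phantom fetuses (perturbed-disc placenta,
   ellipsoidal brain, spatially correlated T2* fields, mono-exponential
   forward model with Gaussian noise) and two-group cohorts with
   GA-dependent decline, group offsets, and a latent factor coupling brain
   and placental oxygenation — every dataset carries complete ground truth.

Because no clinical data ship with the package, all worked examples and
tests run on the synthetic generators, which emulate the target acquisition:
five echoes at TE = (11.2, 57.1, 102.9, 148.8, 194.7) msec, 2.5 mm isotropic
voxels, 30 control vs 51 CHD fetuses with the control group scanned ~2.5
weeks later in gestation (so GA confounds every group contrast, and the
ANCOVA adjustment is exercised exactly as a real analysis needs it).

## Worked example

`examples/04_cohort_statistics.py` generates the default synthetic cohort
and runs the statistical stage:

```text
placental T2* (msec):
  raw means        control   83.3   CHD   86.8
  EMM @ GA 32.8 wk  control   94.8   CHD   80.1
  ANCOVA group coefficient -14.7 msec, p = 0.0011, p_FDR = 0.0023

GA correlations (pooled Spearman):
  placenta_t2star_msec     rho =  -0.61  p = 0.0000
  brain_t2star_msec        rho =  -0.26  p = 0.0194
  placenta_volume_mm3      rho =   0.41  p = 0.0002

brain vs placenta T2*, GA-adjusted partial Spearman:
  all      rho =  0.43 (p = 0.0001)
  control  rho =  0.16 (p = 0.4020)
  CHD      rho =  0.49 (p = 0.0003)
  interaction coefficient = 0.143 (p = 0.57)
```

The raw placental means are *reversed* relative to the generative truth
(the CHD deficit is −14 msec): CHD fetuses are scanned earlier, and
placental T2* falls steeply with GA, so the unadjusted contrast is
confounded. The estimated marginal means — both groups evaluated at the
pooled mean GA — recover the deficit. The other examples cover map fitting
(`01`), shape metrics (`02`), texture (`03`) and the full image-to-report
pipeline (`05`); each prints a short interpretation of its numbers.

A thin CLI wraps the same library calls:

```bash
fetalt2star simulate phantom --seed 3 --out ph/
fetalt2star fit --image ph/echo.nii.gz --sidecar ph/echo.json --out ph/maps/
fetalt2star metrics --image ph/echo.nii.gz --sidecar ph/echo.json \
    --placenta-mask ph/placenta.nii.gz --brain-mask ph/brain.nii.gz \
    --out-json ph/metrics.json
fetalt2star simulate cohort --seed 3 --out co/
fetalt2star stats --table co/cohort_table.csv --out-json co/report.json
```

## Data formats

- 4D multi-echo magnitude volumes: NIfTI, echo as the 4th dimension, with a
  JSON sidecar carrying `"EchoTimes"` in msec.
- Organ masks: 3D uint8 NIfTI on the same grid (values > 0.5 foreground).
- Cohort tables / manifests: CSV with documented fixed columns.
- Maps (T2*, S0, distance): float32 NIfTI, units in the header description;
  invalid voxels are NaN, never silent zeros.

See `docs/methods.md` for the models, parameter choices, numerical details
and limitations.
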