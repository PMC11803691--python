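"""Synthetic phantoms and cohorts with full ground truth.

Two generators provide every input the pipeline consumes, at the acquisition
conditions of the emulated study (5 echoes at TE = 11.2, 57.1, 102.9, 148.8,
194.7 msec; 2.5 mm isotropic voxels) together with the ground truth needed
for recovery testing:

* :func:`make_phantom` renders one fetus: a disc-like placenta whose
  thickness and rim are modulated by a smooth sinusoidal perturbation, an
  ellipsoidal fetal-brain compartment, amniotic-fluid background with long
  T2*, a spatially correlated ("lobulated") placental T2* field, and the
  mono-exponential forward signal with additive Gaussian noise (a documented
  simplification of Rician noise, adequate at first-echo SNR ≳ 10).

* :func:`generate_cohort` draws a two-group cohort (control vs CHD) with
  GA-dependent T2* decline, group offsets, a shared latent factor producing
  the brain-placenta correlation, and texture/morphology group shifts —
  either directly at the metric level (table mode) or by rendering a phantom
  per fetus (image mode).

Default cohort parameters emulate the study conditions: 30 controls vs 51
CHD fetuses, control GA centred higher than CHD GA (so GA confounds every
group contrast and the ANCOVA adjustment is exercised), placental T2* around
97 msec declining ~6.8 msec/week, brain T2* around 218 msec declining ~3.6
msec/week, CHD deficits of 14 / 16 msec, and a GA-adjusted brain-placenta
correlation of 0.46.

A ``(spec, seed)`` pair fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FormatError
from .io import (
    BinaryMask,
    CohortTable,
    EchoTimes,
    MultiEchoVolume,
    RoiMetrics,
    ScalarMap,
    SubjectRecord,
    VoxelGeometry,
    write_cohort_table,
    write_mask,
    write_multiecho,
    write_scalar_map,
)

__all__ = [
    "STUDY_ECHO_TIMES",
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "PhantomBundle",
    "make_placenta_mask",
    "make_brain_mask",
    "make_t2star_field",
    "simulate_multiecho",
    "make_phantom",
    "generate_cohort",
    "render_image_cohort",
]

#: Echo times (msec) of the emulated multi-echo gradient-echo acquisition.
STUDY_ECHO_TIMES = EchoTimes(values=(11.2, 57.1, 102.9, 148.8, 194.7))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and noise parameters of one rendered fetus."""

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.5
    # placenta: disc radius, base thickness, smooth boundary perturbation
    placenta_radius_mm: float = 45.0
    placenta_thickness_mm: float = 24.0
    perturb_amplitude_mm: float = 6.0
    perturb_wavelength_mm: float = 40.0
    # fetal brain: ellipsoid semi-axes
    brain_radii_mm: tuple[float, float, float] = (32.0, 28.0, 26.0)
    # tissue T2* (msec)
    placenta_t2star_mean: float = 95.0
    placenta_t2star_sd: float = 15.0
    placenta_corr_length_mm: float = 12.0
    brain_t2star_mean: float = 210.0
    brain_t2star_sd: float = 8.0
    brain_corr_length_mm: float = 6.0
    fluid_t2star: float = 600.0  # > 500 msec reporting threshold
    # signal amplitudes (arbitrary units)
    s0_placenta: float = 100.0
    s0_brain: float = 80.0
    s0_fluid: float = 120.0
    snr_echo1: float | None = 20.0  # None => noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dims) < 8 or self.spacing_mm <= 0:
            raise FormatError("phantom grid must be at least 8 voxels per axis")
        if self.fluid_t2star <= 500.0:
            raise FormatError("fluid T2* must exceed the 500 msec reporting threshold")
        if self.snr_echo1 is not None and self.snr_echo1 <= 0:
            raise FormatError("snr_echo1 must be positive or None")

    @property
    def geometry(self) -> VoxelGeometry:
        s = float(self.spacing_mm)
        return VoxelGeometry(dims=self.dims, spacing=(s, s, s))


@dataclass(frozen=True)
class PhantomBundle:
    """One rendered fetus plus its complete ground truth."""

    volume: MultiEchoVolume
    placenta_mask: BinaryMask
    brain_mask: BinaryMask
    t2star_truth: ScalarMap
    s0_truth: ScalarMap
    spec: PhantomSpec


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a two-group cohort.

    T2* means follow ``intercept + slope·GA + offset·1[CHD] + loading·u``
    with ``u`` a shared standard-normal latent factor producing the
    GA-adjusted brain-placenta correlation (``latent_corr``), plus
    independent residual noise.  Texture is additionally coupled to the
    placental T2* residual (``texture_t2star_corr``).
    """

    n_control: int = 30
    n_chd: int = 51
    # uniform GA draws reproducing the emulated demographics: controls
    # median 34.5 (IQR ≈ 32.25-36.75) vs CHD median 32.0 (IQR ≈ 31-33),
    # both bounded below by the 30-week inclusion cutoff
    ga_range_control: tuple[float, float] = (30.0, 39.0)
    ga_range_chd: tuple[float, float] = (30.0, 34.0)
    maternal_age_range: tuple[float, float] = (27.0, 40.0)
    # placental T2* model (msec, msec/week)
    placenta_intercept: float = 321.3
    placenta_ga_slope: float = -6.8
    placenta_chd_offset: float = -14.0
    placenta_resid_sd: float = 18.0
    # fetal brain T2* model
    brain_intercept: float = 336.8
    brain_ga_slope: float = -3.6
    brain_chd_offset: float = -16.0
    brain_resid_sd: float = 24.6
    #: GA-adjusted brain-placenta correlation induced by the latent factor
    latent_corr: float = 0.46
    # placental volume model (mm**3 at the organ scale used by the phantoms)
    volume_intercept: float = -196.8
    volume_ga_slope: float = 23.0
    volume_chd_offset: float = 60.0
    volume_resid_sd: float = 195.0
    # GA-independent shape/texture metrics
    texture_mean: float = 0.845
    texture_chd_offset: float = -0.04
    texture_sd: float = 0.03
    texture_t2star_corr: float = 0.46
    morphology_mean: float = 9.9
    morphology_chd_offset: float = 0.9
    morphology_sd: float = 2.1
    thickness_mean: float = 38.7
    thickness_chd_offset: float = 1.8
    thickness_sd: float = 8.1
    # image-mode shape parameters (CHD placentas bumpier / more heterogeneous);
    # both group levels sit on the rising branch of the morphology-vs-amplitude
    # curve (deep rim clefts beyond ~8 mm start lowering the mean distance)
    image_amplitude_base_mm: float = 2.0
    image_amplitude_shift_mm: float = 4.0
    image_corr_length_shift_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_chd < 2:
            raise FormatError("need at least 2 subjects per group")
        if not -1.0 <= self.latent_corr <= 1.0:
            raise FormatError("latent_corr must lie in [-1, 1]")
        if not -1.0 <= self.texture_t2star_corr <= 1.0:
            raise FormatError("texture_t2star_corr must lie in [-1, 1]")

    @classmethod
    def null(cls, **overrides) -> "CohortSpec":
        """A no-effect cohort: zero slopes, offsets and correlations.

        Used for type-I-error calibration of the statistical stage.
        """
        base = dict(
            placenta_intercept=95.0,
            placenta_ga_slope=0.0,
            placenta_chd_offset=0.0,
            brain_intercept=210.0,
            brain_ga_slope=0.0,
            brain_chd_offset=0.0,
            latent_corr=0.0,
            volume_intercept=580.0,
            volume_ga_slope=0.0,
            volume_chd_offset=0.0,
            texture_chd_offset=0.0,
            texture_t2star_corr=0.0,
            morphology_chd_offset=0.0,
            thickness_chd_offset=0.0,
            ga_range_chd=(30.0, 39.0),  # no GA confounding under the null
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class GroundTruth:
    """Everything a recovery test needs: the spec plus per-subject truths."""

    spec: CohortSpec
    per_subject: pd.DataFrame  # id, group, ga, latent u, true organ means


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------


def _grids_mm(geom: VoxelGeometry):
    axes = [np.arange(n) * s for n, s in zip(geom.dims, geom.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def make_placenta_mask(spec: PhantomSpec) -> BinaryMask:
    """Voxelise a disc-like placenta with smooth sinusoidal boundary modulation.

    The disc rim radius is modulated around the circumference and the local
    thickness is modulated by a smooth in-plane bump pattern; both share the
    perturbation amplitude, so amplitude 0 yields a rotationally symmetric
    uniform disc and larger amplitudes yield bumpier, locally thicker
    ("bulkier, less uniform") placentas.  Deterministic given ``spec.seed``.
    """
    geom = spec.geometry
    extent = [n * s for n, s in zip(geom.dims, geom.spacing)]
    max_r = spec.placenta_radius_mm + spec.perturb_amplitude_mm
    if 2 * max_r >= min(extent[0], extent[1]) - 2 * spec.spacing_mm:
        raise FormatError("placenta radius + perturbation does not fit the grid")
    zc = 0.25 * extent[2]
    half_t_max = 0.5 * spec.placenta_thickness_mm + spec.perturb_amplitude_mm
    if zc - half_t_max <= spec.spacing_mm or zc + half_t_max >= extent[2] - spec.spacing_mm:
        raise FormatError("placenta thickness + perturbation does not fit the grid")

    rng = np.random.default_rng(spec.seed)
    phase_rim, phase_x, phase_y = rng.uniform(0, 2 * np.pi, size=3)
    xg, yg, zg = _grids_mm(geom)
    # centre on the symmetric middle of the voxel lattice, not the field of view
    cx = 0.5 * (geom.dims[0] - 1) * geom.spacing[0]
    cy = 0.5 * (geom.dims[1] - 1) * geom.spacing[1]
    r = np.hypot(xg - cx, yg - cy)
    theta = np.arctan2(yg - cy, xg - cx)
    n_lobes = max(2, int(round(2 * np.pi * spec.placenta_radius_mm / spec.perturb_wavelength_mm)))
    # outward-only rim lobes: a larger amplitude always yields a superset
    # mask, so the perturbation bulks the shape rather than carving clefts
    rim = spec.placenta_radius_mm + spec.perturb_amplitude_mm * 0.5 * (
        1.0 + np.sin(n_lobes * theta + phase_rim)
    )
    bump = 0.5 * (
        1.0
        + np.sin(2 * np.pi * xg / spec.perturb_wavelength_mm + phase_x)
        * np.sin(2 * np.pi * yg / spec.perturb_wavelength_mm + phase_y)
    )
    thickness = spec.placenta_thickness_mm + 2.0 * spec.perturb_amplitude_mm * bump
    inside = (r <= rim) & (np.abs(zg - zc) <= 0.5 * thickness)
    mask = BinaryMask(data=inside.astype(np.uint8), geometry=geom, label="placenta")
    if mask.is_empty:
        raise FormatError("placenta spec produced an empty mask")
    return mask


def make_brain_mask(spec: PhantomSpec) -> BinaryMask:
    """Voxelise the ellipsoidal fetal intracranial compartment."""
    geom = spec.geometry
    extent = [n * s for n, s in zip(geom.dims, geom.spacing)]
    center = (
        0.5 * (geom.dims[0] - 1) * geom.spacing[0],
        0.5 * (geom.dims[1] - 1) * geom.spacing[1],
        0.7 * extent[2],
    )
    for c, rad, e in zip(center, spec.brain_radii_mm, extent):
        if c - rad <= spec.spacing_mm or c + rad >= e - spec.spacing_mm:
            raise FormatError("brain ellipsoid does not fit the grid")
    xg, yg, zg = _grids_mm(geom)
    rx, ry, rz = spec.brain_radii_mm
    inside = (
        ((xg - center[0]) / rx) ** 2 + ((yg - center[1]) / ry) ** 2 + ((zg - center[2]) / rz) ** 2
    ) <= 1.0
    return BinaryMask(data=inside.astype(np.uint8), geometry=geom, label="brain")


def make_t2star_field(
    spec: PhantomSpec,
    mask: BinaryMask,
    mean: float | None = None,
    sd: float | None = None,
    corr_length_mm: float | None = None,
    rng: np.random.Generator | None = None,
) -> ScalarMap:
    """Spatially correlated Gaussian T2* field inside a mask.

    White noise is smoothed with a Gaussian kernel of the requested
    correlation length, re-standardised over the mask, scaled to the target
    mean/SD and clipped to (5, 450) msec.  ``sd = 0`` yields a constant
    field at the mean.
    """
    mean = spec.placenta_t2star_mean if mean is None else mean
    sd = spec.placenta_t2star_sd if sd is None else sd
    corr = spec.placenta_corr_length_mm if corr_length_mm is None else corr_length_mm
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    geom = mask.geometry
    field = np.full(geom.dims, np.nan)
    sel = mask.as_bool()
    if sd > 0:
        white = rng.standard_normal(geom.dims)
        sigma_vox = [max(corr / s, 1e-6) for s in geom.spacing]
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        vals = smooth[sel]
        vals = (vals - vals.mean()) / max(vals.std(ddof=0), 1e-12)
        field[sel] = np.clip(mean + sd * vals, 5.0, 450.0)
    else:
        field[sel] = np.clip(mean, 5.0, 450.0)
    return ScalarMap(data=field, geometry=geom, units="msec", validity=mask.data)


def simulate_multiecho(
    t2star_truth: ScalarMap,
    s0_truth: ScalarMap,
    echoes: EchoTimes = STUDY_ECHO_TIMES,
    snr: float | None = 20.0,
    seed: int = 0,
    noise_ref_mask: BinaryMask | None = None,
) -> MultiEchoVolume:
    """Forward-model the multi-echo signal and add magnitude-domain noise.

    Noise is Gaussian with SD = (mean first-echo signal over the reference
    mask) / snr, truncated at zero; ``snr=None`` disables it.  The reference
    mask defaults to all voxels with S0 > 0.
    """
    if t2star_truth.geometry != s0_truth.geometry:
        raise FormatError("T2* and S0 truth maps are on different grids")
    geom = t2star_truth.geometry
    te = echoes.as_array()
    t2 = np.nan_to_num(t2star_truth.data, nan=1.0)
    s0 = np.nan_to_num(s0_truth.data, nan=0.0)
    with np.errstate(over="ignore", divide="ignore"):
        signal = s0[..., None] * np.exp(-te[None, None, None, :] / np.maximum(t2, 1e-6)[..., None])
    signal[s0 == 0] = 0.0
    if snr is not None and np.isfinite(snr):
        if noise_ref_mask is not None:
            ref = noise_ref_mask.as_bool()
        else:
            ref = s0 > 0
        mean_e1 = float(signal[..., 0][ref].mean())
        sigma = mean_e1 / snr
        rng = np.random.default_rng(seed)
        signal = np.clip(signal + rng.normal(0.0, sigma, size=signal.shape), 0.0, None)
    return MultiEchoVolume(data=signal, echoes=echoes, geometry=geom)


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render one fetus: masks, ground-truth maps, and the noisy acquisition.

    The background (everything outside placenta and brain) is amniotic-fluid-
    like: long T2* above the 500 msec reporting threshold.
    """
    geom = spec.geometry
    placenta = make_placenta_mask(spec)
    brain = make_brain_mask(spec)
    if (placenta.as_bool() & brain.as_bool()).any():
        raise FormatError("placenta and brain masks overlap; adjust the spec")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    t2 = np.full(geom.dims, float(spec.fluid_t2star))
    s0 = np.full(geom.dims, float(spec.s0_fluid))
    pl_field = make_t2star_field(
        spec, placenta, spec.placenta_t2star_mean, spec.placenta_t2star_sd,
        spec.placenta_corr_length_mm, rng,
    )
    br_field = make_t2star_field(
        spec, brain, spec.brain_t2star_mean, spec.brain_t2star_sd,
        spec.brain_corr_length_mm, rng,
    )
    psel, bsel = placenta.as_bool(), brain.as_bool()
    t2[psel] = pl_field.data[psel]
    t2[bsel] = br_field.data[bsel]
    s0[psel] = spec.s0_placenta
    s0[bsel] = spec.s0_brain

    t2_map = ScalarMap(data=t2, geometry=geom, units="msec")
    s0_map = ScalarMap(data=s0, geometry=geom, units="a.u.")
    organs = BinaryMask(data=(psel | bsel).astype(np.uint8), geometry=geom, label="placenta")
    volume = simulate_multiecho(
        t2_map, s0_map, STUDY_ECHO_TIMES, spec.snr_echo1,
        seed=int(np.random.SeedSequence([spec.seed, 2]).generate_state(1)[0] % (2**31)),
        noise_ref_mask=organs,
    )
    return PhantomBundle(
        volume=volume, placenta_mask=placenta, brain_mask=brain,
        t2star_truth=t2_map, s0_truth=s0_map, spec=spec,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _draw_subjects(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lat = np.sqrt(max(spec.latent_corr, 0.0))
    sign = 1.0 if spec.latent_corr >= 0 else -1.0
    for i in range(spec.n_control + spec.n_chd):
        group = "control" if i < spec.n_control else "CHD"
        lo, hi = spec.ga_range_control if group == "control" else spec.ga_range_chd
        ga = rng.uniform(lo, hi)
        mat = rng.uniform(*spec.maternal_age_range)
        u = rng.standard_normal()
        chd = 1.0 if group == "CHD" else 0.0
        pl_true = (
            spec.placenta_intercept + spec.placenta_ga_slope * ga
            + spec.placenta_chd_offset * chd + lat * spec.placenta_resid_sd * u
        )
        br_true = (
            spec.brain_intercept + spec.brain_ga_slope * ga
            + spec.brain_chd_offset * chd + sign * lat * spec.brain_resid_sd * u
        )
        rows.append(
            dict(id="sub-%03d" % (i + 1), group=group, ga_weeks=ga,
                 maternal_age_years=mat, latent_u=u,
                 placenta_t2star_true=pl_true, brain_t2star_true=br_true)
        )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec = CohortSpec()) -> tuple[CohortTable, GroundTruth]:
    """Draw a metric-level (table mode) cohort with its ground truth.

    Per subject, organ T2* means are the latent-factor linear model plus
    independent residual noise; texture is coupled to the placental T2*
    residual; volume follows its own GA trend; morphology and thickness are
    GA-independent group-shifted Gaussians.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _draw_subjects(spec, rng)
    n = len(truth)
    resid_scale = np.sqrt(1.0 - abs(spec.latent_corr))
    eps_p = rng.standard_normal(n) * spec.placenta_resid_sd * resid_scale
    eps_b = rng.standard_normal(n) * spec.brain_resid_sd * resid_scale
    pl = truth["placenta_t2star_true"].to_numpy() + eps_p
    br = truth["brain_t2star_true"].to_numpy() + eps_b
    chd = (truth["group"] == "CHD").to_numpy(dtype=float)
    ga = truth["ga_weeks"].to_numpy()

    vol = (
        spec.volume_intercept + spec.volume_ga_slope * ga + spec.volume_chd_offset * chd
        + rng.standard_normal(n) * spec.volume_resid_sd
    )
    # texture couples to the placental residual (latent + noise), standardised
    pl_resid = pl - (spec.placenta_intercept + spec.placenta_ga_slope * ga
                     + spec.placenta_chd_offset * chd)
    pl_resid_std = pl_resid / max(spec.placenta_resid_sd, 1e-12)
    k = spec.texture_t2star_corr * spec.texture_sd
    eps_t_sd = spec.texture_sd * np.sqrt(max(1.0 - spec.texture_t2star_corr**2, 0.0))
    tex = np.clip(
        spec.texture_mean + spec.texture_chd_offset * chd + k * pl_resid_std
        + rng.standard_normal(n) * eps_t_sd,
        -1.0, 1.0,
    )
    morph = (
        spec.morphology_mean + spec.morphology_chd_offset * chd
        + rng.standard_normal(n) * spec.morphology_sd
    )
    thick = np.clip(
        spec.thickness_mean + spec.thickness_chd_offset * chd
        + rng.standard_normal(n) * spec.thickness_sd,
        5.0, None,
    )

    records = []
    for i, row in truth.iterrows():
        metrics = RoiMetrics(
            mean_t2star_msec=float(pl[i]),
            volume_mm3=float(max(vol[i], 1.0)),
            texture=float(tex[i]),
            morphology=float(morph[i]),
            max_thickness_mm=float(thick[i]),
        )
        records.append(
            SubjectRecord(
                id=row["id"], group=row["group"], ga_weeks=float(row["ga_weeks"]),
                maternal_age_years=float(row["maternal_age_years"]),
                placenta_metrics=metrics, brain_mean_t2star=float(br[i]),
            )
        )
    return CohortTable(records=tuple(records)), GroundTruth(spec=spec, per_subject=truth)


def render_image_cohort(
    spec: CohortSpec,
    phantom_base: PhantomSpec | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomBundle], GroundTruth, pd.DataFrame]:
    """Image mode: render one phantom per fetus of the cohort.

    Each subject's phantom inherits the cohort's generative structure: its
    placental and brain T2* field means are the subject's true organ means,
    CHD placentas get a larger boundary-perturbation amplitude (bulkier
    shape) and a shorter T2* correlation length (more heterogeneous
    texture).  Returns the bundles, the ground truth, and a manifest frame;
    when ``out_dir`` is given, NIfTI volumes, masks, sidecars and the
    manifest CSV are written there.
    """
    base = phantom_base if phantom_base is not None else PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    truth = _draw_subjects(spec, rng)
    bundles: list[PhantomBundle] = []
    manifest_rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, row in truth.iterrows():
        chd = row["group"] == "CHD"
        sub_seed = int(np.random.SeedSequence([spec.seed, 100 + i]).generate_state(1)[0] % (2**31))
        sub_spec = replace(
            base,
            placenta_t2star_mean=float(np.clip(row["placenta_t2star_true"], 40.0, 250.0)),
            brain_t2star_mean=float(np.clip(row["brain_t2star_true"], 120.0, 320.0)),
            perturb_amplitude_mm=spec.image_amplitude_base_mm
            + (spec.image_amplitude_shift_mm if chd else 0.0),
            placenta_corr_length_mm=max(
                base.placenta_corr_length_mm - (spec.image_corr_length_shift_mm if chd else 0.0),
                2.0,
            ),
            seed=sub_seed,
        )
        bundle = make_phantom(sub_spec)
        bundles.append(bundle)
        entry = dict(
            id=row["id"], group=row["group"], ga_weeks=float(row["ga_weeks"]),
            maternal_age_years=float(row["maternal_age_years"]),
        )
        if out is not None:
            paths = {
                "image": out / ("%s_echo.nii.gz" % row["id"]),
                "sidecar": out / ("%s_echo.json" % row["id"]),
                "placenta_mask": out / ("%s_placenta.nii.gz" % row["id"]),
                "brain_mask": out / ("%s_brain.nii.gz" % row["id"]),
                "t2star_truth": out / ("%s_t2star_truth.nii.gz" % row["id"]),
            }
            write_multiecho(bundle.volume, paths["image"], paths["sidecar"])
            write_mask(bundle.placenta_mask, paths["placenta_mask"])
            write_mask(bundle.brain_mask, paths["brain_mask"])
            write_scalar_map(bundle.t2star_truth, paths["t2star_truth"])
            entry.update({k: str(v) for k, v in paths.items() if k != "t2star_truth"})
        manifest_rows.append(entry)
    manifest = pd.DataFrame(manifest_rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
        truth.to_csv(out / "ground_truth.csv", index=False)
    return bundles, GroundTruth(spec=spec, per_subject=truth), manifest
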