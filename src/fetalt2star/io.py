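"""Core data types and NIfTI / sidecar / cohort-table I/O.

Volumes, masks and derived maps are stored as NIfTI (.nii/.nii.gz) with a
BIDS-flavored JSON sidecar carrying the echo times in milliseconds under the
key ``"EchoTimes"``.  Cohort manifests and metric tables are plain CSV.

All geometry (voxel counts and spacing in mm) is read once at ingestion and
propagated through the pipeline; it is never re-derived from data arrays.
Voxel indices are 0-based; world coordinates are not used because every
metric in the pipeline is mask-relative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

__all__ = [
    "EchoTimes",
    "VoxelGeometry",
    "MultiEchoVolume",
    "BinaryMask",
    "ScalarMap",
    "RoiMetrics",
    "SubjectRecord",
    "CohortTable",
    "read_multiecho",
    "read_mask",
    "read_scalar_map",
    "write_multiecho",
    "write_mask",
    "write_scalar_map",
    "read_cohort_table",
    "write_cohort_table",
]

GROUP_LABELS = ("control", "CHD")

#: Fixed column order of the cohort CSV (documented contract).
COHORT_COLUMNS = [
    "id",
    "group",
    "ga_weeks",
    "maternal_age_years",
    "placenta_t2star_msec",
    "placenta_volume_mm3",
    "placenta_texture",
    "placenta_morphology",
    "placenta_max_thickness_mm",
    "brain_t2star_msec",
]


@dataclass(frozen=True)
class EchoTimes:
    """Ordered acquisition echo times in milliseconds (strictly increasing)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise FormatError("need at least 2 echo times, got %d" % len(vals))
        if any(v <= 0 for v in vals):
            raise FormatError("echo times must be positive: %r" % (vals,))
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise FormatError("echo times must be strictly increasing: %r" % (vals,))

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class VoxelGeometry:
    """Grid shape (voxels) and voxel spacing (mm) of a 3D acquisition."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise FormatError("dims must be three integers >= 1, got %r" % (dims,))
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError("spacing must be three positives, got %r" % (spacing,))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        return aff


@dataclass(frozen=True)
class MultiEchoVolume:
    """4D magnitude image indexed (x, y, z, echo) with its echo times."""

    data: np.ndarray
    echoes: EchoTimes
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise FormatError("multi-echo volume must be 4D, got %dD" % data.ndim)
        if data.shape[:3] != self.geometry.dims:
            raise FormatError(
                "volume grid %r does not match geometry %r"
                % (data.shape[:3], self.geometry.dims)
            )
        if data.shape[3] != len(self.echoes):
            raise FormatError(
                "4th dimension (%d) does not match number of echo times (%d)"
                % (data.shape[3], len(self.echoes))
            )
        if not np.all(np.isfinite(data)):
            raise FormatError("signal contains non-finite values")
        if np.any(data < 0):
            raise FormatError("magnitude signal must be non-negative")


@dataclass(frozen=True)
class BinaryMask:
    """Binary organ mask on the acquisition grid.

    ``label`` names the ROI ("placenta" or "brain"); an all-zero mask is
    permitted but flagged via :attr:`is_empty` so downstream metrics can
    mark the ROI invalid instead of silently producing zeros.
    """

    data: np.ndarray
    geometry: VoxelGeometry
    label: str = "placenta"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise FormatError("mask must be 3D, got %dD" % data.ndim)
        if data.shape != self.geometry.dims:
            raise FormatError(
                "mask grid %r does not match geometry %r"
                % (data.shape, self.geometry.dims)
            )
        data = (np.asarray(data, dtype=float) > 0.5).astype(np.uint8)
        object.__setattr__(self, "data", data)

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass(frozen=True)
class ScalarMap:
    """3D scalar map with explicit per-voxel validity.

    Invalid voxels carry NaN in ``data`` and 0 in ``validity`` — never a
    silent zero.  ``units`` declares the physical unit ("msec" for T2*,
    "a.u." for S0, "mm" for distance maps).
    """

    data: np.ndarray
    geometry: VoxelGeometry
    units: str
    validity: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape != self.geometry.dims:
            raise FormatError(
                "map grid %r does not match geometry %r"
                % (data.shape, self.geometry.dims)
            )
        if self.validity is None:
            validity = np.isfinite(data).astype(np.uint8)
        else:
            validity = (np.asarray(self.validity) > 0).astype(np.uint8)
            if validity.shape != data.shape:
                raise FormatError("validity grid does not match data grid")
        data = data.copy()
        data[validity == 0] = np.nan
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "validity", validity)

    def valid_values(self, mask: "BinaryMask | None" = None) -> np.ndarray:
        sel = self.validity.astype(bool)
        if mask is not None:
            if mask.geometry != self.geometry:
                raise FormatError("mask and map are on different grids")
            sel = sel & mask.as_bool()
        return self.data[sel]


@dataclass(frozen=True)
class RoiMetrics:
    """Per-subject placental metrics (NaN marks a failed/unavailable metric)."""

    mean_t2star_msec: float = np.nan
    volume_mm3: float = np.nan
    texture: float = np.nan
    morphology: float = np.nan
    max_thickness_mm: float = np.nan


@dataclass(frozen=True)
class SubjectRecord:
    """One fetus: covariates plus placental and brain measures."""

    id: str
    group: str
    ga_weeks: float
    maternal_age_years: float
    placenta_metrics: RoiMetrics = field(default_factory=RoiMetrics)
    brain_mean_t2star: float = np.nan
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise FormatError(
                "group must be one of %r, got %r" % (GROUP_LABELS, self.group)
            )
        if not (20.0 < float(self.ga_weeks) < 45.0):
            raise FormatError("ga_weeks must lie in (20, 45), got %r" % self.ga_weeks)


@dataclass(frozen=True)
class CohortTable:
    """Cohort of subject records with unique ids."""

    records: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate subject ids in cohort table")

    def __len__(self) -> int:
        return len(self.records)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUP_LABELS}
        for r in self.records:
            sizes[r.group] += 1
        return sizes

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            m = r.placenta_metrics
            rows.append(
                {
                    "id": r.id,
                    "group": r.group,
                    "ga_weeks": r.ga_weeks,
                    "maternal_age_years": r.maternal_age_years,
                    "placenta_t2star_msec": m.mean_t2star_msec,
                    "placenta_volume_mm3": m.volume_mm3,
                    "placenta_texture": m.texture,
                    "placenta_morphology": m.morphology,
                    "placenta_max_thickness_mm": m.max_thickness_mm,
                    "brain_t2star_msec": r.brain_mean_t2star,
                }
            )
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError("cohort table is missing columns: %r" % missing)
        records = []
        for _, row in df.iterrows():
            metrics = RoiMetrics(
                mean_t2star_msec=float(row["placenta_t2star_msec"]),
                volume_mm3=float(row["placenta_volume_mm3"]),
                texture=float(row["placenta_texture"]),
                morphology=float(row["placenta_morphology"]),
                max_thickness_mm=float(row["placenta_max_thickness_mm"]),
            )
            records.append(
                SubjectRecord(
                    id=str(row["id"]),
                    group=str(row["group"]),
                    ga_weeks=float(row["ga_weeks"]),
                    maternal_age_years=float(row["maternal_age_years"]),
                    placenta_metrics=metrics,
                    brain_mean_t2star=float(row["brain_t2star_msec"]),
                )
            )
        return cls(records=tuple(records))


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------


def _geometry_from_image(img: nib.Nifti1Image) -> VoxelGeometry:
    zooms = img.header.get_zooms()[:3]
    return VoxelGeometry(dims=tuple(img.shape[:3]), spacing=tuple(float(z) for z in zooms))


def read_multiecho(image_path: str | Path, sidecar_path: str | Path) -> MultiEchoVolume:
    """Load a 4D multi-echo magnitude NIfTI plus its echo-time sidecar.

    The sidecar is JSON with ``"EchoTimes"`` in milliseconds; its length is
    cross-checked against the image's 4th dimension.
    """
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise ConfigurationError("missing echo-time sidecar: %s" % sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if "EchoTimes" not in meta:
        raise ConfigurationError("sidecar %s lacks an 'EchoTimes' entry" % sidecar_path)
    echoes = EchoTimes(values=tuple(meta["EchoTimes"]))

    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(
            "%s: expected a 4D multi-echo image, got %dD" % (image_path, data.ndim)
        )
    if data.shape[3] != len(echoes):
        raise FormatError(
            "%s: image has %d echoes but sidecar lists %d echo times"
            % (image_path, data.shape[3], len(echoes))
        )
    return MultiEchoVolume(data=data, echoes=echoes, geometry=_geometry_from_image(img))


def read_mask(path: str | Path, reference: VoxelGeometry, label: str = "placenta") -> BinaryMask:
    """Load a 3D binary mask, verifying it sits on the reference grid.

    Values are thresholded at 0.5.  An empty mask is legal but triggers a
    warning so the caller can flag the ROI invalid.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError("%s: mask must be 3D, got %dD" % (path, data.ndim))
    geom = _geometry_from_image(img)
    if geom.dims != reference.dims:
        raise FormatError(
            "%s: mask grid %r does not match reference %r" % (path, geom.dims, reference.dims)
        )
    mask = BinaryMask(data=data, geometry=reference, label=label)
    if mask.is_empty:
        warnings.warn("mask %s is empty; ROI will be flagged invalid" % path, stacklevel=2)
    return mask


def write_multiecho(volume: MultiEchoVolume, image_path: str | Path, sidecar_path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.geometry.affine())
    img.header.set_zooms(volume.geometry.spacing + (1.0,))
    nib.save(img, str(image_path))
    with open(sidecar_path, "w") as fh:
        json.dump({"EchoTimes": list(volume.echoes.values), "EchoTimeUnits": "msec"}, fh, indent=1)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.geometry.affine())
    img.header.set_zooms(mask.geometry.spacing)
    nib.save(img, str(path))


def write_scalar_map(smap: ScalarMap, path: str | Path) -> None:
    """Write a scalar map as float32 NIfTI; units go in the header description."""
    img = nib.Nifti1Image(smap.data.astype(np.float32), smap.geometry.affine())
    img.header.set_zooms(smap.geometry.spacing)
    img.header["descrip"] = ("units=%s" % smap.units).encode()[:79]
    nib.save(img, str(path))


def read_scalar_map(path: str | Path, units: str | None = None) -> ScalarMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError("%s: scalar map must be 3D" % path)
    if units is None:
        descrip = img.header["descrip"].tobytes().decode(errors="ignore").rstrip("\x00")
        units = descrip.split("units=")[-1] if "units=" in descrip else "unknown"
    return ScalarMap(data=data, geometry=_geometry_from_image(img), units=units)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    """Write the cohort as CSV with the fixed documented column order."""
    table.to_dataframe().to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"id": str})
    return CohortTable.from_dataframe(df)
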