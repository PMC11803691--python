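"""Placental shape metrics from the binary mask.

Three measures are derived from the mask alone:

* **volume** — foreground voxel count times the voxel volume (mm³);
* **morphology score** — mean + population SD of the Euclidean
  distance-to-boundary map over foreground voxels.  Thin, uniformly shaped
  placentas give low scores; bulky or unevenly thick ones give high scores;
* **maximum thickness** — twice the largest distance-map value (mm), i.e. the
  diameter of the largest inscribed sphere.

Distances are computed in millimetres with an anisotropy-aware Euclidean
distance transform: each foreground voxel receives the distance to the
nearest *background voxel centre*, so an isolated voxel scores one voxel
spacing rather than zero.  The morphology score is consequently mm-valued;
it is reported as a dimensionless shape index because it is not a direct
physical measurement of any single anatomical length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, FormatError
from .io import BinaryMask, ScalarMap, VoxelGeometry

__all__ = [
    "MorphologyResult",
    "mask_volume",
    "distance_map",
    "morphology_score",
    "max_thickness",
    "largest_component",
    "morphology_metrics",
]


@dataclass(frozen=True)
class MorphologyResult:
    volume_mm3: float
    morphology_score: float
    max_thickness_mm: float
    distance_map: ScalarMap


def mask_volume(mask: BinaryMask, geometry: VoxelGeometry | None = None) -> float:
    """ROI volume in mm³: foreground count × voxel volume."""
    geom = geometry if geometry is not None else mask.geometry
    if geom != mask.geometry:
        raise FormatError("mask and geometry disagree")
    return float(mask.n_voxels) * geom.voxel_volume_mm3


def distance_map(mask: BinaryMask, geometry: VoxelGeometry | None = None) -> ScalarMap:
    """Euclidean distance (mm) from each foreground voxel to the nearest
    background voxel centre; background voxels are invalid (NaN).

    The mask is padded with one layer of background before the transform so
    that voxels touching the grid edge are treated as boundary voxels rather
    than interior ones.
    """
    geom = geometry if geometry is not None else mask.geometry
    if geom != mask.geometry:
        raise FormatError("mask and geometry disagree")
    if mask.is_empty:
        raise DegenerateInputError("cannot compute a distance map of an empty mask")
    padded = np.pad(mask.as_bool(), 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=geom.spacing)
    dist = dist[1:-1, 1:-1, 1:-1]
    data = np.where(mask.as_bool(), dist, np.nan)
    return ScalarMap(data=data, geometry=geom, units="mm", validity=mask.data)


def morphology_score(dmap: ScalarMap, mask: BinaryMask) -> float:
    """Mean + population SD (denominator N) of the in-mask distance map.

    A single-voxel mask scores mean + 0.  Higher values correspond to
    bulkier, less uniformly shaped masks.
    """
    if dmap.geometry != mask.geometry:
        raise FormatError("distance map and mask are on different grids")
    vals = dmap.valid_values(mask)
    if vals.size == 0:
        raise DegenerateInputError("morphology score of an empty mask is undefined")
    return float(vals.mean() + vals.std(ddof=0))


def max_thickness(dmap: ScalarMap) -> float:
    """2 × maximum distance-map value: the largest inscribed-sphere diameter (mm)."""
    vals = dmap.valid_values()
    if vals.size == 0:
        raise DegenerateInputError("max thickness of an empty distance map is undefined")
    return float(2.0 * vals.max())


def largest_component(mask: BinaryMask) -> BinaryMask:
    """Optionally restrict a mask to its largest 26-connected component.

    Off by default throughout the pipeline: masks are used as given.
    """
    if mask.is_empty:
        return mask
    labels, n = ndimage.label(mask.as_bool(), structure=np.ones((3, 3, 3), dtype=int))
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = labels == counts.argmax()
    return BinaryMask(data=keep.astype(np.uint8), geometry=mask.geometry, label=mask.label)


def morphology_metrics(mask: BinaryMask, select_largest: bool = False) -> MorphologyResult:
    """Volume, morphology score, and maximum thickness of one mask."""
    if select_largest:
        mask = largest_component(mask)
    dmap = distance_map(mask)
    return MorphologyResult(
        volume_mm3=mask_volume(mask),
        morphology_score=morphology_score(dmap, mask),
        max_thickness_mm=max_thickness(dmap),
        distance_map=dmap,
    )
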