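"""Placental texture via grey-level co-occurrence matrix (GLCM) correlation.

The T2* map inside the placental mask is quantised to a small number of grey
levels between robust percentiles, voxel pairs at a set of 3D displacement
offsets (both voxels in-mask) are accumulated into a symmetric normalised
co-occurrence matrix, and the GLCM *correlation* statistic

    corr = Σ_ij p(i,j) (i - μ_i)(j - μ_j) / (σ_i σ_j)

is returned.  Values near +1 indicate spatially smooth (homogeneous) tissue;
lower values indicate more heterogeneous tissue on the millimetre scale of
the offsets.  Accumulation is fully 3D (axis-aligned unit offsets and their
negations by default) because the acquisition is near-isotropic.

The established 2D GLCM implementations operate on rectangular unmasked
images; the masked 3D accumulation needed here is implemented directly and
checked against pair-enumeration oracles in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, FormatError
from .io import BinaryMask, ScalarMap

__all__ = [
    "TextureParams",
    "GLCMatrix",
    "quantize",
    "glcm_accumulate",
    "glcm_correlation",
    "placental_texture",
    "DEFAULT_OFFSETS",
]

#: Axis-aligned unit displacements; negations are added during accumulation.
DEFAULT_OFFSETS = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

#: Sentinel grey level marking voxels excluded from accumulation.
IGNORE = -1


@dataclass(frozen=True)
class TextureParams:
    """Pinned GLCM parameters, echoed into output metadata for provenance."""

    n_levels: int = 32
    lo_pct: float = 1.0
    hi_pct: float = 99.0
    offsets: tuple[tuple[int, int, int], ...] = DEFAULT_OFFSETS
    #: values at/above this (msec) are excluded before quantisation,
    #: mirroring the fluid-exclusion threshold of the ROI mean.
    exclude_above: float = 500.0


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, normalised grey-level co-occurrence matrix."""

    p: np.ndarray
    offsets: tuple[tuple[int, int, int], ...]
    n_levels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.n_levels, self.n_levels):
            raise FormatError("GLCM must be %d×%d" % (self.n_levels, self.n_levels))
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise FormatError("GLCM entries must be non-negative and sum to 1")
        object.__setattr__(self, "p", p)


def quantize(
    smap: ScalarMap,
    mask: BinaryMask,
    n_levels: int = 32,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
) -> np.ndarray:
    """Linear binning of in-mask values into [0, n_levels-1].

    Bin edges span the (lo_pct, hi_pct) percentiles of the in-mask valid
    values; values outside are clipped into the extreme bins.  Out-of-mask
    and invalid voxels are tagged with the ``IGNORE`` sentinel.  Being
    percentile-based, the binning is invariant to affine rescaling of the
    input map.
    """
    if smap.geometry != mask.geometry:
        raise FormatError("map and mask are on different grids")
    if n_levels < 2:
        raise FormatError("need at least 2 grey levels")
    sel = mask.as_bool() & smap.validity.astype(bool)
    vals = smap.data[sel]
    if vals.size == 0:
        raise DegenerateInputError("no valid in-mask voxels to quantise")
    lo, hi = np.percentile(vals, [lo_pct, hi_pct])
    if not hi > lo:
        raise DegenerateInputError("constant in-mask image: quantisation is degenerate")
    q = np.full(smap.geometry.dims, IGNORE, dtype=np.int32)
    scaled = (smap.data[sel] - lo) / (hi - lo) * n_levels
    q[sel] = np.clip(np.floor(scaled), 0, n_levels - 1).astype(np.int32)
    return q


def glcm_accumulate(
    q: np.ndarray,
    mask: BinaryMask,
    offsets: tuple[tuple[int, int, int], ...] = DEFAULT_OFFSETS,
) -> GLCMatrix:
    """Count co-occurring grey-level pairs over the offsets and their negations.

    A pair contributes only when both voxels are in-mask (grey level !=
    IGNORE).  Each ordered pair is counted in both orders, making the matrix
    symmetric; counts are normalised to sum to one.
    """
    q = np.asarray(q)
    if q.shape != mask.geometry.dims:
        raise FormatError("quantised image and mask are on different grids")
    if any(all(c == 0 for c in off) for off in offsets):
        raise FormatError("offsets must be nonzero displacements")
    n_levels = int(q.max()) + 1 if q.max() >= 0 else 0
    if n_levels == 0:
        raise DegenerateInputError("no in-mask voxels")
    valid = q != IGNORE
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for off in offsets:
        sl_a, sl_b = [], []
        for d, n in zip(off, q.shape):
            if d >= 0:
                sl_a.append(slice(0, n - d))
                sl_b.append(slice(d, n))
            else:
                sl_a.append(slice(-d, n))
                sl_b.append(slice(0, n + d))
        a, b = q[tuple(sl_a)], q[tuple(sl_b)]
        both = valid[tuple(sl_a)] & valid[tuple(sl_b)]
        av, bv = a[both], b[both]
        np.add.at(counts, (av, bv), 1)
        np.add.at(counts, (bv, av), 1)  # symmetric + negated offset
    total = counts.sum()
    if total == 0:
        raise DegenerateInputError("no co-occurring in-mask voxel pairs")
    return GLCMatrix(p=counts / total, offsets=tuple(offsets), n_levels=n_levels)


def glcm_correlation(g: GLCMatrix) -> float:
    """GLCM correlation in [-1, 1]; NaN when a marginal SD is zero."""
    levels = np.arange(g.n_levels, dtype=float)
    px = g.p.sum(axis=1)  # symmetric, so both marginals coincide
    mu = float(px @ levels)
    var = float(px @ (levels - mu) ** 2)
    if var <= 0:
        return float("nan")
    cov = float(((levels[:, None] - mu) * (levels[None, :] - mu) * g.p).sum())
    return cov / var


def placental_texture(
    t2star: ScalarMap,
    mask: BinaryMask,
    params: TextureParams = TextureParams(),
) -> float:
    """Scalar placental texture: quantise → accumulate → GLCM correlation.

    Voxels at or above ``params.exclude_above`` msec (fluid partial volume)
    are excluded before quantisation, consistent with the thresholded ROI
    mean.  Degenerate inputs (constant field, no pairs) yield NaN.
    """
    if t2star.geometry != mask.geometry:
        raise FormatError("map and mask are on different grids")
    keep = (
        mask.as_bool()
        & t2star.validity.astype(bool)
        & np.nan_to_num(t2star.data, nan=np.inf).__lt__(params.exclude_above)
    )
    sub_mask = BinaryMask(data=keep.astype(np.uint8), geometry=mask.geometry, label=mask.label)
    try:
        q = quantize(t2star, sub_mask, params.n_levels, params.lo_pct, params.hi_pct)
        g = glcm_accumulate(q, sub_mask, params.offsets)
    except DegenerateInputError:
        return float("nan")
    return glcm_correlation(g)
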