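"""GLCM texture: quantisation, accumulation, correlation, and oracles.

Accumulation and the correlation statistic are checked exactly against
direct pair-enumeration / double-sum oracles, and cross-checked against
scikit-image's 2D implementation on single slices.
"""

import numpy as np
import pytest

import fetalt2star as f
from fetalt2star.errors import DegenerateInputError
from fetalt2star.texture import (
    DEFAULT_OFFSETS,
    IGNORE,
    GLCMatrix,
    glcm_accumulate,
    glcm_correlation,
    placental_texture,
    quantize,
)


def make_mask(data, spacing=2.5):
    data = np.asarray(data)
    geom = f.VoxelGeometry(dims=data.shape, spacing=(spacing,) * 3)
    return f.BinaryMask(data=data, geometry=geom)


def make_map(data, spacing=2.5):
    data = np.asarray(data, dtype=float)
    geom = f.VoxelGeometry(dims=data.shape, spacing=(spacing,) * 3)
    return f.ScalarMap(data=data, geometry=geom, units="msec")


def oracle_glcm(q, mask, offsets):
    """Direct pair enumeration: both voxels in-mask, symmetric counting."""
    n_levels = int(q.max()) + 1
    counts = np.zeros((n_levels, n_levels))
    nx, ny, nz = q.shape
    for dx, dy, dz in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    X, Y, Z = x + dx, y + dy, z + dz
                    if not (0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz):
                        continue
                    if q[x, y, z] == IGNORE or q[X, Y, Z] == IGNORE:
                        continue
                    counts[q[x, y, z], q[X, Y, Z]] += 1
                    counts[q[X, Y, Z], q[x, y, z]] += 1
    return counts / counts.sum()


def oracle_correlation(p):
    """Textbook double sum over the symmetric normalised matrix."""
    L = p.shape[0]
    levels = np.arange(L, dtype=float)
    px = p.sum(axis=1)
    mu = (px * levels).sum()
    sigma = np.sqrt((px * (levels - mu) ** 2).sum())
    if sigma == 0:
        return float("nan")
    acc = 0.0
    for i in range(L):
        for j in range(L):
            acc += p[i, j] * (i - mu) * (j - mu)
    return acc / sigma**2


def test_quantize_uniform_span_gives_equal_occupancy():
    vals = np.linspace(0.0, 1.0, 64).reshape(4, 4, 4)
    smap = make_map(vals)
    mask = make_mask(np.ones((4, 4, 4)))
    q = quantize(smap, mask, n_levels=4, lo_pct=0, hi_pct=100)
    occupancy = np.bincount(q[q != IGNORE], minlength=4)
    assert occupancy.max() - occupancy.min() <= 1


def test_quantize_scale_invariance():
    rng = np.random.default_rng(2)
    vals = rng.uniform(50, 150, (6, 6, 6))
    mask = make_mask(np.ones((6, 6, 6)))
    q1 = quantize(make_map(vals), mask, 8)
    q2 = quantize(make_map(3.7 * vals + 12.0), mask, 8)  # affine rescale
    np.testing.assert_array_equal(q1, q2)


def test_quantize_constant_image_is_degenerate():
    mask = make_mask(np.ones((4, 4, 4)))
    with pytest.raises(DegenerateInputError):
        quantize(make_map(np.full((4, 4, 4), 7.0)), mask, 8)


def test_checkerboard_glcm_mass_and_correlation(echoes):
    """4×4×1 two-level checkerboard at offset (1,0,0): all co-occurrence mass
    on (0,1)/(1,0), hence correlation exactly −1."""
    board = np.indices((4, 4, 1)).sum(axis=0) % 2
    mask = make_mask(np.ones((4, 4, 1)))
    g = glcm_accumulate(board.astype(np.int32), mask, offsets=((1, 0, 0),))
    assert g.p[0, 1] == pytest.approx(0.5)
    assert g.p[1, 0] == pytest.approx(0.5)
    assert g.p[0, 0] == 0 and g.p[1, 1] == 0
    assert glcm_correlation(g) == pytest.approx(-1.0)
    np.testing.assert_allclose(g.p, oracle_glcm(board, mask, ((1, 0, 0),)), atol=1e-15)


def test_ramp_is_perfectly_correlated_along_other_axis():
    """q(x,y,z) = x with offsets along y: paired levels always equal -> +1."""
    q = np.indices((5, 5, 3))[0].astype(np.int32)
    mask = make_mask(np.ones((5, 5, 3)))
    g = glcm_accumulate(q, mask, offsets=((0, 1, 0),))
    assert glcm_correlation(g) == pytest.approx(1.0)


def test_single_voxel_has_no_pairs():
    data = np.zeros((3, 3, 3))
    data[1, 1, 1] = 1
    mask = make_mask(data)
    q = np.where(data > 0, 0, IGNORE).astype(np.int32)
    with pytest.raises(DegenerateInputError):
        glcm_accumulate(q, mask)


def test_accumulation_and_correlation_match_oracles_on_random_images():
    rng = np.random.default_rng(4)
    for shape in [(6, 5, 4), (8, 8, 8)]:
        q = rng.integers(0, 5, shape).astype(np.int32)
        mdata = (rng.random(shape) < 0.7).astype(np.uint8)
        mdata[0, 0, 0] = 1
        q[mdata == 0] = IGNORE
        mask = make_mask(mdata)
        g = glcm_accumulate(q, mask, DEFAULT_OFFSETS)
        ref = oracle_glcm(q, mask, DEFAULT_OFFSETS)
        np.testing.assert_allclose(g.p, ref, atol=1e-15)
        assert glcm_correlation(g) == pytest.approx(oracle_correlation(ref), abs=1e-12)


def test_correlation_matches_skimage_on_2d_slice():
    """Cross-check against scikit-image's graycoprops on an unmasked slice."""
    skimage = pytest.importorskip("skimage.feature")
    rng = np.random.default_rng(6)
    img2d = rng.integers(0, 8, (16, 16)).astype(np.uint8)
    q = img2d[:, :, None].astype(np.int32)
    mask = make_mask(np.ones((16, 16, 1)))
    g = glcm_accumulate(q, mask, offsets=((0, 1, 0),))  # skimage angle 0: along columns
    ref = skimage.graycomatrix(img2d, [1], [0], levels=8, symmetric=True, normed=True)
    corr_ref = skimage.graycoprops(ref, "correlation")[0, 0]
    assert glcm_correlation(g) == pytest.approx(corr_ref, abs=1e-12)


def test_texture_invariant_under_axis_flips():
    rng = np.random.default_rng(5)
    vals = rng.uniform(60, 140, (10, 10, 6))
    mdata = (rng.random((10, 10, 6)) < 0.8).astype(np.uint8)
    mdata[5, 5, 3] = 1
    t0 = placental_texture(make_map(vals), make_mask(mdata))
    for axis in range(3):
        t1 = placental_texture(
            make_map(np.flip(vals, axis).copy()), make_mask(np.flip(mdata, axis).copy())
        )
        assert t1 == pytest.approx(t0, abs=1e-12)


def test_white_noise_texture_near_zero():
    """Spatially independent voxel values: expected GLCM correlation 0."""
    rng = np.random.default_rng(10)
    vals = rng.normal(100, 15, (24, 24, 24))  # ~4e4 pairs per offset
    mask = make_mask(np.ones((24, 24, 24)))
    t = placental_texture(make_map(vals), mask)
    assert abs(t) < 0.05


def test_texture_increases_with_field_correlation_length(small_phantom_spec):
    """Smoother (longer-correlation) T2* fields read as more homogeneous."""
    from fetalt2star.synthetic import make_placenta_mask, make_t2star_field

    mask = make_placenta_mask(small_phantom_spec)
    textures = []
    for cl in (2.0, 6.0, 14.0):
        field = make_t2star_field(
            small_phantom_spec, mask, corr_length_mm=cl, rng=np.random.default_rng(20)
        )
        textures.append(placental_texture(field, mask))
    assert all(b > a for a, b in zip(textures, textures[1:]))


def test_constant_field_texture_is_nan(small_geometry):
    mask = f.BinaryMask(data=np.ones(small_geometry.dims), geometry=small_geometry)
    smap = f.ScalarMap(
        data=np.full(small_geometry.dims, 90.0), geometry=small_geometry, units="msec"
    )
    assert np.isnan(placental_texture(smap, mask))


def test_texture_excludes_values_above_threshold(small_geometry):
    """Fluid-like voxels (>= 500 msec) must not contribute pairs."""
    rng = np.random.default_rng(12)
    vals = rng.uniform(60, 140, small_geometry.dims)
    fluid = np.zeros(small_geometry.dims, dtype=bool)
    fluid[::2] = True
    vals_with_fluid = vals.copy()
    vals_with_fluid[fluid] = 600.0
    mask_all = f.BinaryMask(data=np.ones(small_geometry.dims), geometry=small_geometry)
    mask_tissue = f.BinaryMask(data=(~fluid).astype(np.uint8), geometry=small_geometry)
    t_thresholded = placental_texture(
        f.ScalarMap(data=vals_with_fluid, geometry=small_geometry, units="msec"), mask_all
    )
    t_masked = placental_texture(
        f.ScalarMap(data=vals, geometry=small_geometry, units="msec"), mask_tissue
    )
    assert t_thresholded == pytest.approx(t_masked, abs=1e-12)
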