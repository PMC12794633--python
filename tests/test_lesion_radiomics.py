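import numpy as np
import pytest

from strokeprog import (
    BinaryMask,
    VolumeGrid,
    discretize,
    extract_dwi_features,
    generate_lesion_case,
    intensity_features,
    make_ring_roi,
    roi_radiomics,
    texture_features,
    wavelet_bands,
)
from strokeprog.imaging_core import EmptyROIError
from strokeprog.lesion_radiomics import (
    DIRECTIONS_3D,
    DiscretizedROI,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    wavelet_decompose,
)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation path)
# ---------------------------------------------------------------------------

def brute_glcm(levels, direction):
    """Co-occurrence counts by explicit voxel-pair enumeration."""
    ng = int(levels.max())
    mat = np.zeros((ng, ng))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            continue
        nb = tuple(i + o for i, o in zip(idx, direction))
        if all(0 <= n < s for n, s in zip(nb, shape)) and levels[nb] > 0:
            mat[levels[idx] - 1, levels[nb] - 1] += 1
    mat = mat + mat.T
    s = mat.sum()
    return mat / s if s else mat


def brute_glrlm(levels, direction):
    """Run-length counts by walking every line voxel by voxel."""
    shape = levels.shape
    runs = {}
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            continue
        prev = tuple(i - o for i, o in zip(idx, direction))
        inb = all(0 <= p < s for p, s in zip(prev, shape))
        if inb and levels[prev] == levels[idx]:
            continue  # not a run start
        g, length, cur = levels[idx], 1, idx
        while True:
            nxt = tuple(i + o for i, o in zip(cur, direction))
            if not all(0 <= n < s for n, s in zip(nxt, shape)):
                break
            if levels[nxt] != g:
                break
            length += 1
            cur = nxt
        runs[(g, length)] = runs.get((g, length), 0) + 1
    ng = int(levels.max())
    rmax = max((l for (_, l) in runs), default=1)
    M = np.zeros((ng, rmax))
    for (g, l), c in runs.items():
        M[g - 1, l - 1] = c
    return M


def brute_glszm(levels):
    """Zone sizes by breadth-first flood fill over 26-connected neighbors."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    offsets = [o for o in np.ndindex(3, 3, 3)]
    offsets = [tuple(x - 1 for x in o) for o in offsets if o != (1, 1, 1)]
    zones = {}
    for idx in np.ndindex(shape):
        if levels[idx] == 0 or seen[idx]:
            continue
        g = levels[idx]
        stack, size = [idx], 0
        seen[idx] = True
        while stack:
            cur = stack.pop()
            size += 1
            for o in offsets:
                nb = tuple(i + d for i, d in zip(cur, o))
                if (all(0 <= n < s for n, s in zip(nb, shape))
                        and not seen[nb] and levels[nb] == g):
                    seen[nb] = True
                    stack.append(nb)
        zones[(g, size)] = zones.get((g, size), 0) + 1
    ng = int(levels.max())
    smax = max((s for (_, s) in zones), default=1)
    Z = np.zeros((ng, smax))
    for (g, s), c in zones.items():
        Z[g - 1, s - 1] = c
    return Z


def _random_droi(rng, shape=(4, 4, 2), ng=4):
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    return DiscretizedROI(levels=levels, mask=np.ones(shape, bool),
                          n_levels=int(levels.max()),
                          bin_edges=np.arange(ng + 1, dtype=float))


# ---------------------------------------------------------------------------
# Ring ROI
# ---------------------------------------------------------------------------

class TestRingROI:
    def test_single_pixel_radius_one(self):
        les = np.zeros((9, 9, 1))
        les[4, 4, 0] = 1
        ring = make_ring_roi(BinaryMask(les, (1, 1, 1)), 1)
        assert ring.n_foreground == 4
        assert ring.data[4, 4, 0] == 0

    def test_radius_zero_empty_ring(self):
        les = np.zeros((5, 5, 1))
        les[2, 2, 0] = 1
        ring = make_ring_roi(BinaryMask(les, (1, 1, 1)), 0)
        assert ring.n_foreground == 0

    def test_radius_ten_lattice_count(self):
        les = np.zeros((31, 31, 1))
        les[15, 15, 0] = 1
        ring = make_ring_roi(BinaryMask(les, (1, 1, 1)), 10)
        brute = sum(1 for x in range(-15, 16) for y in range(-15, 16)
                    if 0 < x * x + y * y <= 100)
        assert ring.n_foreground == brute

    def test_disjoint_from_lesion(self, lesion_case):
        ring = make_ring_roi(lesion_case.lesion, 10)
        assert not np.any(ring.data & lesion_case.lesion.data)

    def test_empty_lesion_rejected(self):
        with pytest.raises(EmptyROIError):
            make_ring_roi(BinaryMask(np.zeros((4, 4, 2)), (1, 1, 1)), 5)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

class TestDiscretize:
    def test_constant_roi_single_level(self):
        d = discretize(np.full((3, 3, 2), 5.0), np.ones((3, 3, 2), bool))
        assert d.n_levels == 1
        assert np.all(d.levels[d.mask] == 1)

    def test_identity_mapping_32_values(self):
        vals = np.arange(32, dtype=float).reshape(4, 4, 2)
        d = discretize(vals, np.ones((4, 4, 2), bool), n_bins=32)
        np.testing.assert_array_equal(d.levels[d.mask], vals.ravel() + 1)

    def test_monotone_transform_preserves_levels(self, rng):
        vals = rng.random((5, 5, 2))
        mask = np.ones((5, 5, 2), bool)
        d1 = discretize(vals, mask, n_bins=8)
        d2 = discretize(np.exp(vals), mask, n_bins=8)
        # bin labels sorted by original intensity are non-decreasing for any
        # monotone transform of the intensities
        order = np.argsort(vals[mask])
        assert np.all(np.diff(d1.levels[d1.mask][order]) >= 0)
        assert np.all(np.diff(d2.levels[d2.mask][order]) >= 0)


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

class TestIntensity:
    def test_constant_roi_conventions(self):
        img = VolumeGrid(np.full((4, 4, 2), 3.0), (1, 1, 1))
        roi = BinaryMask(np.ones((4, 4, 2)), (1, 1, 1))
        f = intensity_features(img, roi)
        n = 32
        assert f["mean"] == 3.0 and f["variance"] == 0.0
        assert f["energy"] == n * 9.0
        assert f["entropy"] == 0.0 and f["uniformity"] == 1.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0

    def test_four_value_hand_arithmetic(self):
        img = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        roi = np.ones((4, 1, 1), bool)
        f = intensity_features(img, roi)
        assert f["mean"] == 2.5
        assert f["median"] == 2.5
        assert f["range"] == 3.0
        assert f["variance"] == 1.25          # population variance
        assert f["minimum"] == 1.0 and f["maximum"] == 4.0
        assert f["root mean squared"] == pytest.approx(np.sqrt(7.5))
        assert f["mean absolute deviation"] == 1.0

    def test_gaussian_moments_near_zero(self, rng):
        x = rng.standard_normal((25, 25, 16))
        f = intensity_features(x, np.ones(x.shape, bool))
        assert abs(f["skewness"]) < 0.2
        assert abs(f["kurtosis"]) < 0.2

    def test_count_is_18(self, lesion_case):
        f = intensity_features(lesion_case.dwi, lesion_case.lesion)
        assert len(f) == 18

    def test_empty_roi_rejected(self):
        with pytest.raises(EmptyROIError):
            intensity_features(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))


# ---------------------------------------------------------------------------
# Texture matrices vs brute force
# ---------------------------------------------------------------------------

class TestTextureOracles:
    def test_glcm_two_by_two_example(self):
        lv = np.array([[[1], [2]], [[1], [2]]], dtype=np.int32)  # (x, y, z)
        d = DiscretizedROI(levels=lv, mask=lv > 0, n_levels=2,
                           bin_edges=np.arange(3, dtype=float))
        M = glcm_matrix(d, (0, 1, 0))
        np.testing.assert_allclose(M, [[0.0, 0.5], [0.5, 0.0]])
        from strokeprog.lesion_radiomics import _glcm_features

        assert _glcm_features(M)["contrast"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_glcm_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = _random_droi(rng)
        for direction in DIRECTIONS_3D:
            np.testing.assert_allclose(
                glcm_matrix(d, direction), brute_glcm(d.levels, direction),
                atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_glrlm_matches_line_walk(self, seed):
        rng = np.random.default_rng(seed)
        d = _random_droi(rng)
        for direction in DIRECTIONS_3D:
            ours = glrlm_matrix(d, direction)
            brute = brute_glrlm(d.levels, direction)
            r = max(ours.shape[1], brute.shape[1])
            ours = np.pad(ours, ((0, 0), (0, r - ours.shape[1])))
            brute = np.pad(brute, ((0, 0), (0, r - brute.shape[1])))
            np.testing.assert_allclose(ours, brute, atol=1e-12)

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_glszm_matches_flood_fill(self, seed):
        rng = np.random.default_rng(seed)
        d = _random_droi(rng)
        ours = glszm_matrix(d)
        brute = brute_glszm(d.levels)
        s = max(ours.shape[1], brute.shape[1])
        ours = np.pad(ours, ((0, 0), (0, s - ours.shape[1])))
        brute = np.pad(brute, ((0, 0), (0, s - brute.shape[1])))
        np.testing.assert_allclose(ours, brute, atol=1e-12)

    def test_checkerboard_zone_count(self):
        # 2-level 3D checkerboard: with 26-connectivity all same-level voxels
        # connect diagonally, giving exactly one zone per level
        idx = np.indices((4, 4, 2)).sum(axis=0)
        lv = (idx % 2 + 1).astype(np.int32)
        d = DiscretizedROI(levels=lv, mask=np.ones(lv.shape, bool),
                           n_levels=2, bin_edges=np.arange(3, dtype=float))
        Z = glszm_matrix(d)
        brute = brute_glszm(lv)
        assert Z.sum() == brute.sum() == 2

    def test_constant_roi_conventions(self):
        d = discretize(np.full((4, 4, 2), 9.0), np.ones((4, 4, 2), bool))
        f = texture_features(d)
        glcm = "textures.gray-level co-occurrence matrix."
        assert f[glcm + "contrast"] == 0.0
        assert f[glcm + "dissimilarity"] == 0.0
        assert f[glcm + "homogeneity"] == 1.0
        assert f[glcm + "entropy"] == 0.0

    def test_count_is_39(self, rng):
        d = _random_droi(rng, shape=(5, 5, 3))
        assert len(texture_features(d)) == 39


# ---------------------------------------------------------------------------
# Wavelets
# ---------------------------------------------------------------------------

class TestWavelets:
    def test_constant_image_detail_bands_vanish(self):
        bands = wavelet_bands(np.full((8, 8, 8), 5.0))
        for name, arr in bands.items():
            if "H" in name:
                np.testing.assert_allclose(arr, 0.0, atol=1e-10)
        # Haar approximation gains 2^(1/2) per axis
        np.testing.assert_allclose(bands["LLL"], 5.0 * 2 ** 1.5, rtol=1e-9)

    def test_eight_bands_any_shape(self, rng):
        for shape in [(5, 6, 3), (8, 8, 8), (7, 3, 2)]:
            bands = wavelet_bands(rng.random(shape))
            assert len(bands) == 8
            for arr in bands.values():
                assert arr.shape == shape

    def test_parseval_orthogonal_haar(self, rng):
        vol = rng.standard_normal((8, 10, 6))  # even sizes: exact orthogonality
        coeffs = wavelet_decompose(vol)
        total = sum((a ** 2).sum() for a in coeffs.values())
        assert total == pytest.approx((vol ** 2).sum(), rel=1e-9)


# ---------------------------------------------------------------------------
# Assembly counts and invariances
# ---------------------------------------------------------------------------

class TestAssembly:
    def test_roi_radiomics_is_513(self, lesion_case):
        f = roi_radiomics(lesion_case.dwi, lesion_case.lesion)
        assert len(f) == 513
        assert sum(1 for k in f if k.startswith("wavelet")) == 456

    def test_translation_invariance(self):
        base = np.zeros((20, 20, 6))
        rng = np.random.default_rng(0)
        patch = rng.random((4, 4, 2)) + 1.0
        roi = np.zeros((20, 20, 6), bool)
        img_a = base.copy(); img_a[3:7, 3:7, 1:3] = patch
        roi_a = roi.copy(); roi_a[3:7, 3:7, 1:3] = True
        img_b = base.copy(); img_b[9:13, 11:15, 2:4] = patch
        roi_b = roi.copy(); roi_b[9:13, 11:15, 2:4] = True
        fa = intensity_features(img_a, roi_a)
        fb = intensity_features(img_b, roi_b)
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], rel=1e-12), k
        ta = texture_features(discretize(img_a, roi_a))
        tb = texture_features(discretize(img_b, roi_b))
        for k in ta:
            assert ta[k] == pytest.approx(tb[k], rel=1e-12), k

    def test_case_features_are_1026(self, lesion_case):
        f = extract_dwi_features(lesion_case)
        assert len(f) == 1026
        assert sum(1 for k in f if k.startswith("lesion.")) == 513
        assert sum(1 for k in f if k.startswith("ring.")) == 513

    def test_lesion_features_independent_of_ring_radius(self, lesion_case):
        f5 = extract_dwi_features(lesion_case, ring_px=5)
        f10 = extract_dwi_features(lesion_case, ring_px=10)
        for k in f5:
            if k.startswith("lesion."):
                assert f5[k] == f10[k], k
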