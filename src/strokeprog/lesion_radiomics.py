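"""Radiomics of the DWI ischemic lesion and the peri-lesion ring.

Per region of interest we compute 513 features:

* 18 first-order intensity statistics;
* 39 texture features from four matrix families — gray-level co-occurrence
  (GLCM, 8), gray-level run-length (GLRLM, 13), gray-level size zone
  (GLSZM, 13) and neighborhood gray-tone difference (NGTDM, 5);
* the same 57 features on each of the 8 sub-bands of a single-level 3D
  separable wavelet decomposition (456 wavelet features).

Texture matrices follow the standard radiomics definitions: gray levels are
re-binned to ``n_bins`` equal-width levels inside the ROI; GLCM and GLRLM are
aggregated over the 13 unique 3D directions at distance 1 (features averaged
across directions, GLCM symmetric); GLSZM zones and NGTDM neighborhoods use
26-connectivity.

A case contributes two ROIs — the lesion itself and a ring obtained by
expanding the lesion in-plane by ``ring_px`` pixels and subtracting it
(a perfusion-free surrogate for the peri-ischemic penumbra) — for
1,026 features in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pywt
from scipy import ndimage

from .imaging_core import BinaryMask, CaseRecord, EmptyROIError, VolumeGrid, dilate_mask

# 13 unique direction vectors of the 26-neighborhood (one per +/- pair)
DIRECTIONS_3D: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

INTENSITY_FEATURES: Tuple[str, ...] = (
    "energy", "entropy", "minimum", "10th percentile", "90th percentile",
    "maximum", "mean", "median", "interquartile range", "range",
    "mean absolute deviation", "robust mean absolute deviation",
    "root mean squared", "standard deviation", "variance", "skewness",
    "kurtosis", "uniformity",
)

GLCM_FEATURES: Tuple[str, ...] = (
    "contrast", "dissimilarity", "homogeneity", "energy", "correlation",
    "entropy", "cluster shade", "cluster prominence",
)

GLRLM_FEATURES: Tuple[str, ...] = (
    "short run emphasis", "long run emphasis", "gray-level non-uniformity",
    "run-length non-uniformity", "run percentage",
    "low gray-level run emphasis", "high gray-level run emphasis",
    "short run low gray-level emphasis", "short run high gray-level emphasis",
    "long run low gray-level emphasis", "long run high gray-level emphasis",
    "gray-level variance", "run-length variance",
)

GLSZM_FEATURES: Tuple[str, ...] = (
    "small zone emphasis", "large zone emphasis", "gray-level non-uniformity",
    "zone-size non-uniformity", "zone percentage",
    "low gray-level zone emphasis", "high gray-level zone emphasis",
    "small zone low gray-level emphasis", "small zone high gray-level emphasis",
    "large zone low gray-level emphasis", "large zone high gray-level emphasis",
    "gray-level variance", "zone-size variance",
)

NGTDM_FEATURES: Tuple[str, ...] = (
    "coarseness", "contrast", "busyness", "complexity", "strength",
)

WAVELET_BAND_NAMES: Tuple[str, ...] = (
    "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
)


# ---------------------------------------------------------------------------
# ROI construction and discretization
# ---------------------------------------------------------------------------

def make_ring_roi(lesion: BinaryMask, radius_px: int = 10) -> BinaryMask:
    """Peri-lesion ring: in-plane dilation by ``radius_px`` minus the lesion."""
    if lesion.is_empty():
        raise EmptyROIError("lesion mask is empty")
    dilated = dilate_mask(lesion, radius_px, mode="in_plane_2d")
    ring = dilated.data.astype(np.int16) - lesion.data.astype(np.int16)
    return BinaryMask(ring > 0, lesion.spacing)


@dataclass
class DiscretizedROI:
    """ROI gray levels re-binned to ``{1..n_levels}`` with equal-width bins."""

    levels: np.ndarray   # int array, 0 outside ROI, 1..n_levels inside
    mask: np.ndarray     # bool, the ROI
    n_levels: int
    bin_edges: np.ndarray


def discretize(image: VolumeGrid | np.ndarray, roi: BinaryMask | np.ndarray,
               n_bins: int = 32) -> DiscretizedROI:
    """Equal-width re-binning of ROI intensities to ``n_bins`` levels.

    A constant ROI maps to a single level 1.  The result is cropped to the
    ROI bounding box to keep the texture matrices cheap.
    """
    data = image.data if isinstance(image, VolumeGrid) else np.asarray(image)
    mask = (roi.data if isinstance(roi, BinaryMask) else np.asarray(roi)) > 0
    if not mask.any():
        raise EmptyROIError("ROI is empty")
    # crop to bounding box
    sl = ndimage.find_objects(mask.astype(np.uint8))[0]
    data, mask = data[sl], mask[sl]
    vals = data[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(mask.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
        edges = np.array([lo, hi])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        binned = np.digitize(data, edges[1:-1], right=False) + 1
        levels[mask] = binned[mask]
    return DiscretizedROI(levels=levels, mask=mask, n_levels=int(levels.max()),
                          bin_edges=edges)


# ---------------------------------------------------------------------------
# First-order intensity statistics
# ---------------------------------------------------------------------------

def intensity_features(image: VolumeGrid | np.ndarray,
                       roi: BinaryMask | np.ndarray,
                       n_bins: int = 32) -> Dict[str, float]:
    """The 18 first-order statistics of ROI voxel intensities.

    Entropy and uniformity are computed on the equal-width ``n_bins``
    histogram; variance and standard deviation are population statistics;
    kurtosis is the excess kurtosis (0 for a Gaussian).  A constant ROI has
    skewness and kurtosis 0, entropy 0 and uniformity 1 by convention.
    """
    data = image.data if isinstance(image, VolumeGrid) else np.asarray(image)
    mask = (roi.data if isinstance(roi, BinaryMask) else np.asarray(roi)) > 0
    if not mask.any():
        raise EmptyROIError("ROI is empty")
    x = data[mask].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var())
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4) - 3.0)
    else:
        skew = kurt = 0.0
    inner = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0

    d = discretize(data, mask, n_bins=n_bins)
    counts = np.bincount(d.levels[d.mask])[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    return {
        "energy": float((x ** 2).sum()),
        "entropy": entropy,
        "minimum": float(x.min()),
        "10th percentile": float(p10),
        "90th percentile": float(p90),
        "maximum": float(x.max()),
        "mean": mean,
        "median": float(p50),
        "interquartile range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean absolute deviation": float(np.abs(x - mean).mean()),
        "robust mean absolute deviation": rmad,
        "root mean squared": float(np.sqrt((x ** 2).mean())),
        "standard deviation": sd,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "uniformity": uniformity,
    }


# ---------------------------------------------------------------------------
# Texture matrices
# ---------------------------------------------------------------------------

def _shift(arr: np.ndarray, off: Tuple[int, ...], fill=0) -> np.ndarray:
    """out[v] = arr[v + off] with out-of-bounds positions set to ``fill``."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for n, o in zip(arr.shape, off):
        src.append(slice(max(o, 0), n + min(o, 0)))
        dst.append(slice(max(-o, 0), n + min(-o, 0)))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def glcm_matrix(d: DiscretizedROI, direction: Tuple[int, int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one direction."""
    L = d.levels
    Lf = _shift(L, direction)
    valid = (L > 0) & (Lf > 0)
    ng = d.n_levels
    mat = np.zeros((ng, ng), dtype=np.float64)
    if valid.any():
        np.add.at(mat, (L[valid] - 1, Lf[valid] - 1), 1.0)
    mat = mat + mat.T
    s = mat.sum()
    return mat / s if s > 0 else mat


def _glcm_features(p: np.ndarray) -> Dict[str, float]:
    ng = p.shape[0]
    if p.sum() == 0:
        return {k: (1.0 if k == "homogeneity" else 0.0) for k in GLCM_FEATURES}
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())   # symmetric: mu_x == mu_y
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    nz = p[p > 0]
    corr = 0.0
    if sig_x > 0:
        corr = float(((ii - mu_x) * (jj - mu_x) * p).sum() / (sig_x * sig_x))
    return {
        "contrast": float((diff ** 2 * p).sum()),
        "dissimilarity": float((diff * p).sum()),
        "homogeneity": float((p / (1.0 + diff)).sum()),
        "energy": float((p ** 2).sum()),
        "correlation": corr,
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "cluster shade": float(((ii + jj - 2 * mu_x) ** 3 * p).sum()),
        "cluster prominence": float(((ii + jj - 2 * mu_x) ** 4 * p).sum()),
    }


def glcm_features(d: DiscretizedROI,
                  directions=DIRECTIONS_3D) -> Dict[str, float]:
    """GLCM features averaged over the given displacement directions."""
    per_dir = [_glcm_features(glcm_matrix(d, v)) for v in directions]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURES}


def glrlm_matrix(d: DiscretizedROI, direction: Tuple[int, ...]) -> np.ndarray:
    """Run-length matrix (levels x run length) for one direction.

    Computed by an iterative-shift dynamic program: ``A_r`` marks voxels that
    begin a same-level run of length >= r, so the count of runs of length
    exactly r is ``#(starts & A_r) - #(starts & A_{r+1})``.
    """
    L = d.levels
    Lf = _shift(L, direction)
    cont = (L > 0) & (Lf == L)               # v continues into v+d
    cont_prev = _shift(cont.astype(np.int8), tuple(-o for o in direction))
    starts = (L > 0) & (cont_prev == 0)
    ng = d.n_levels
    max_len = int(np.sum(np.abs(np.asarray(direction)) * (np.asarray(L.shape) - 1))) + 1
    ge = []                                   # ge[r-1][g-1] = #runs of level g, length >= r
    A = L > 0
    off = tuple(0 for _ in direction)
    for r in range(1, max_len + 1):
        sel = starts & A
        if not sel.any():
            break
        ge.append(np.bincount(L[sel], minlength=ng + 1)[1:])
        A = A & _shift(cont, off).astype(bool)
        off = tuple(o + v for o, v in zip(off, direction))
    if not ge:
        return np.zeros((ng, 1))
    ge = np.asarray(ge, dtype=np.float64).T   # (ng, rmax)
    exact = ge.copy()
    exact[:, :-1] -= ge[:, 1:]
    return exact


def _length_weighted_features(M: np.ndarray, n_voxels: int,
                              names: Tuple[str, ...]) -> Dict[str, float]:
    """Shared feature set over a (gray level x run-or-zone size) matrix."""
    ns = M.sum()
    if ns == 0:
        return {k: 0.0 for k in names}
    ng, smax = M.shape
    i = np.arange(1, ng + 1)[:, None].astype(np.float64)
    j = np.arange(1, smax + 1)[None, :].astype(np.float64)
    p = M / ns
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    vals = (
        float((M / j ** 2).sum() / ns),
        float((M * j ** 2).sum() / ns),
        float((M.sum(axis=1) ** 2).sum() / ns),
        float((M.sum(axis=0) ** 2).sum() / ns),
        float(ns / n_voxels),
        float((M / i ** 2).sum() / ns),
        float((M * i ** 2).sum() / ns),
        float((M / (i ** 2 * j ** 2)).sum() / ns),
        float((M * i ** 2 / j ** 2).sum() / ns),
        float((M * j ** 2 / i ** 2).sum() / ns),
        float((M * i ** 2 * j ** 2).sum() / ns),
        float((p * (i - mu_i) ** 2).sum()),
        float((p * (j - mu_j) ** 2).sum()),
    )
    return dict(zip(names, vals))


def glrlm_features(d: DiscretizedROI,
                   directions=DIRECTIONS_3D) -> Dict[str, float]:
    """GLRLM features averaged over the given directions."""
    n_vox = int(d.mask.sum())
    per_dir = [
        _length_weighted_features(glrlm_matrix(d, v), n_vox, GLRLM_FEATURES)
        for v in directions
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURES}


def glszm_matrix(d: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix: zones are 26-connected same-level components."""
    ng = d.n_levels
    structure = np.ones((3,) * d.levels.ndim, dtype=bool)
    sizes_per_level: List[np.ndarray] = []
    max_size = 1
    for g in range(1, ng + 1):
        lab, nlab = ndimage.label(d.levels == g, structure=structure)
        if nlab == 0:
            sizes_per_level.append(np.array([], dtype=np.int64))
            continue
        sizes = np.bincount(lab.ravel())[1:]
        sizes_per_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    Z = np.zeros((ng, max_size), dtype=np.float64)
    for g, sizes in enumerate(sizes_per_level):
        for s in sizes:
            Z[g, s - 1] += 1
    return Z


def glszm_features(d: DiscretizedROI) -> Dict[str, float]:
    return _length_weighted_features(glszm_matrix(d), int(d.mask.sum()),
                                     GLSZM_FEATURES)


def ngtdm_features(d: DiscretizedROI) -> Dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength (NGTDM)."""
    L = d.levels.astype(np.float64)
    inroi = d.mask
    kernel = np.ones((3,) * L.ndim)
    kernel[(1,) * L.ndim] = 0
    nbr_sum = ndimage.convolve(L * inroi, kernel, mode="constant")
    nbr_cnt = ndimage.convolve(inroi.astype(np.float64), kernel, mode="constant")
    has_nbr = inroi & (nbr_cnt > 0)
    abar = np.zeros_like(L)
    abar[has_nbr] = nbr_sum[has_nbr] / nbr_cnt[has_nbr]
    dev = np.abs(L - abar) * has_nbr

    ng = d.n_levels
    n_vox = int(inroi.sum())
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for g in range(1, ng + 1):
        lvl = inroi & (d.levels == g)
        n_i[g - 1] = lvl.sum()
        s_i[g - 1] = dev[lvl].sum()
    p_i = n_i / n_vox
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)

    sum_ps = float((p_i * s_i).sum())
    coarseness = float(1.0 / sum_ps) if sum_ps > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = float(
            (pi * pj * (ii - jj) ** 2)[both].sum() / (ngp * (ngp - 1))
            * (s_i.sum() / n_vox)
        )
        denom_b = float(np.abs((i * p_i)[:, None] - (i * p_i)[None, :])[both].sum())
        busyness = float(sum_ps / denom_b) if denom_b > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cmplx = np.abs(ii - jj) * (pi * s_i[:, None] + pj * s_i[None, :]) / (pi + pj)
        complexity = float(np.nansum(np.where(both, cmplx, 0.0)) / n_vox)
        strength_num = float(((pi + pj) * (ii - jj) ** 2)[both].sum())
        strength = float(strength_num / s_i.sum()) if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def texture_features(d: DiscretizedROI) -> Dict[str, float]:
    """All 39 texture features of a discretized ROI, canonically named."""
    if int(d.mask.sum()) < 2:
        warnings.warn("single-voxel ROI: texture matrices degenerate, "
                      "features set to matrix conventions")
    out: Dict[str, float] = {}
    for k, v in glcm_features(d).items():
        out[f"textures.gray-level co-occurrence matrix.{k}"] = v
    for k, v in glrlm_features(d).items():
        out[f"textures.gray-level run-length matrix.{k}"] = v
    for k, v in glszm_features(d).items():
        out[f"textures.gray-level size zone matrix.{k}"] = v
    for k, v in ngtdm_features(d).items():
        out[f"textures.neighborhood gray-tone difference matrix.{k}"] = v
    assert len(out) == 39
    return out


# ---------------------------------------------------------------------------
# Wavelet decomposition
# ---------------------------------------------------------------------------

def wavelet_decompose(image: VolumeGrid | np.ndarray,
                      wavelet: str = "haar") -> Dict[str, np.ndarray]:
    """Single-level 3D separable DWT; returns the 8 raw coefficient arrays
    keyed LLL..HHH (L = approximation, H = detail, axis order x,y,z)."""
    data = image.data if isinstance(image, VolumeGrid) else np.asarray(image)
    data = np.asarray(data, dtype=np.float64)
    coeffs = pywt.dwtn(data, wavelet)
    out = {}
    for key, arr in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr
    return out


def wavelet_bands(image: VolumeGrid | np.ndarray, wavelet: str = "haar"
                  ) -> Dict[str, np.ndarray]:
    """The 8 wavelet sub-band images mapped back to the input shape.

    Coefficients are nearest-neighbor upsampled (x2 per axis) and cropped so
    the original ROI masks index the bands directly.
    """
    data = image.data if isinstance(image, VolumeGrid) else np.asarray(image)
    shape = data.shape
    coeffs = wavelet_decompose(data, wavelet)
    bands = {}
    for name, arr in coeffs.items():
        up = arr
        for ax in range(up.ndim):
            up = np.repeat(up, 2, axis=ax)
        bands[name] = up[tuple(slice(0, s) for s in shape)]
    assert len(bands) == 8
    return bands


# ---------------------------------------------------------------------------
# Per-ROI and per-case assembly
# ---------------------------------------------------------------------------

def _band_features(data: np.ndarray, mask: np.ndarray, prefix: str,
                   n_bins: int) -> Dict[str, float]:
    out = {}
    for k, v in intensity_features(data, mask, n_bins=n_bins).items():
        out[f"{prefix}.intensity.{k}"] = v
    d = discretize(data, mask, n_bins=n_bins)
    for k, v in texture_features(d).items():
        out[f"{prefix}.{k}"] = v
    return out


def roi_radiomics(image: VolumeGrid, roi: BinaryMask, n_bins: int = 32,
                  wavelet: str = "haar") -> Dict[str, float]:
    """All 513 features of one ROI: 57 on the original image ("image." prefix)
    plus 57 on each of the 8 wavelet sub-bands ("wavelet1".."wavelet8")."""
    if roi.is_empty():
        raise EmptyROIError("ROI is empty")
    mask = roi.data > 0
    out = _band_features(image.data, mask, "image", n_bins)
    bands = wavelet_bands(image, wavelet)
    for idx, name in enumerate(WAVELET_BAND_NAMES, start=1):
        out.update(_band_features(bands[name], mask, f"wavelet{idx}", n_bins))
    assert len(out) == 513
    return out


def extract_dwi_features(case: CaseRecord, ring_px: int = 10,
                         n_bins: int = 32, wavelet: str = "haar"
                         ) -> Dict[str, float]:
    """1,026 radiomics features: 513 for the lesion + 513 for the ring ROI."""
    if case.dwi is None or case.lesion is None or case.lesion.is_empty():
        raise EmptyROIError(f"case {case.case_id}: DWI or lesion missing/empty")
    ring = make_ring_roi(case.lesion, ring_px)
    if ring.is_empty():
        raise EmptyROIError(f"case {case.case_id}: ring ROI empty after clipping")
    out: Dict[str, float] = {}
    for k, v in roi_radiomics(case.dwi, case.lesion, n_bins, wavelet).items():
        out[f"lesion.{k}"] = v
    for k, v in roi_radiomics(case.dwi, ring, n_bins, wavelet).items():
        out[f"ring.{k}"] = v
    assert len(out) == 1026
    return out


RADIOMICS_FEATURE_COUNT = 513
DWI_FEATURE_COUNT = 1026
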