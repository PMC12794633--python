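"""Shared image/mask data model, NIfTI I/O, and geometric utilities.

Conventions used throughout the package:

* Arrays are indexed ``(x, y, z)`` with ``z`` the slice axis, matching the
  header-native orientation of the NIfTI files we read.  No reorientation is
  performed.
* ``spacing`` is the physical voxel size in millimetres per axis,
  ``(sx, sy, sz)``.
* Binary masks are stored as ``uint8`` arrays over ``{0, 1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a 3D volume."""


class EmptyROIError(ValueError):
    """Raised when an operation requires a non-empty region of interest."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with anisotropic voxel spacing in mm."""

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """A 3D binary mask sharing the VolumeGrid axis/spacing conventions."""

    data: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) > 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D mask, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return self.n_foreground == 0


@dataclass
class CaseRecord:
    """One study case: DWI volume, lesion mask, vessel mask, side and outcome.

    ``label`` is the dichotomized 90-day mRS: ``"good"`` for mRS < 3 and
    ``"poor"`` for mRS >= 3.  ``affected_side`` names the hemisphere
    containing the occlusion and drives the asymmetry features.
    """

    case_id: str
    dwi: VolumeGrid | None = None
    lesion: BinaryMask | None = None
    vessel: BinaryMask | None = None
    affected_side: Literal["left", "right"] | None = None
    label: Literal["good", "poor"] | None = None
    meta: dict = field(default_factory=dict)


GOOD, POOR = "good", "poor"


def label_from_mrs(mrs: int) -> str:
    """Dichotomize a 90-day mRS score: < 3 is good, >= 3 is poor."""
    return GOOD if int(mrs) < 3 else POOR


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI volume; spacing is taken from the file header."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0, vol.spacing)


def write_volume(vol: VolumeGrid | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI with the spacing in the header."""
    affine = np.diag(list(vol.spacing) + [1.0])
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Mask operations
# ---------------------------------------------------------------------------

def binarize(volume: VolumeGrid, threshold: float) -> BinaryMask:
    """Threshold a volume: foreground where intensity > threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryMask(volume.data > threshold, volume.spacing)


def _disk_structure(radius: int) -> np.ndarray:
    """Euclidean disk of the given pixel radius (2D)."""
    r = int(radius)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def dilate_mask(
    mask: BinaryMask,
    radius_px: int,
    mode: Literal["in_plane_2d", "isotropic_3d"] = "in_plane_2d",
) -> BinaryMask:
    """Dilate a mask by ``radius_px`` pixels.

    ``in_plane_2d`` (default) dilates each axial slice independently with a
    Euclidean disk — the natural reading of a pixel-unit expansion on thick
    axial slices.  ``isotropic_3d`` uses a Euclidean ball in voxel units.
    """
    if radius_px < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_px == 0:
        return BinaryMask(mask.data.copy(), mask.spacing)
    if mode == "in_plane_2d":
        disk = _disk_structure(radius_px)
        out = np.zeros_like(mask.data)
        for z in range(mask.data.shape[2]):
            sl = mask.data[:, :, z]
            if sl.any():
                out[:, :, z] = ndimage.binary_dilation(sl, structure=disk)
            # empty slices stay empty
        return BinaryMask(out, mask.spacing)
    elif mode == "isotropic_3d":
        r = int(radius_px)
        zz, yy, xx = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = (xx * xx + yy * yy + zz * zz) <= r * r
        return BinaryMask(
            ndimage.binary_dilation(mask.data, structure=ball), mask.spacing
        )
    raise ValueError(f"unknown dilation mode: {mode!r}")


def split_hemispheres(mask: BinaryMask) -> Tuple[BinaryMask, BinaryMask]:
    """Partition a mask at the mid-sagittal plane (midpoint of the x extent).

    Returns ``(left, right)`` where *left* holds voxels with x below the
    midline.  The two halves partition the input exactly: no registration or
    symmetry-plane fitting is attempted.
    """
    nx = mask.data.shape[0]
    mid = nx // 2 + (nx % 2)  # left gets the centre column for odd nx
    left = np.zeros_like(mask.data)
    right = np.zeros_like(mask.data)
    left[:mid] = mask.data[:mid]
    right[mid:] = mask.data[mid:]
    return BinaryMask(left, mask.spacing), BinaryMask(right, mask.spacing)
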