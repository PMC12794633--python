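"""Deterministic phantom and cohort generators with known ground truth.

Real CTA/DWI stroke cohorts are not redistributable, so every stage of the
pipeline is exercised against synthetic data whose true geometry and
statistics are known by construction:

* tube-tree vessel phantoms (unions of capsules around polyline centerlines)
  with analytic per-segment length, distance factor and SOAM, and exact
  branch/endpoint/junction counts;
* DWI-like lesion phantoms (Gaussian background plus an elevated-mean
  in-plane disk lesion);
* balanced two-class Gaussian feature tables with a known informative
  column set;
* a full synthetic cohort of :class:`~strokeprog.imaging_core.CaseRecord`
  objects in which poor-prognosis cases have a sparser vascular tree on the
  affected side and a brighter, more heterogeneous lesion.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .imaging_core import GOOD, POOR, BinaryMask, CaseRecord, VolumeGrid


# ---------------------------------------------------------------------------
# Tube-tree phantoms
# ---------------------------------------------------------------------------

@dataclass
class TubeSegment:
    """A tube around a polyline centerline, with analytic tortuosity truth."""

    points_mm: np.ndarray      # (n, 3) polyline in physical mm
    radius_mm: float
    true_df: float = 1.0
    true_soam: float = 0.0     # rad per mm

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=np.float64)
        if self.radius_mm <= 0:
            raise ValueError("tube radius must be > 0")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_mm, axis=0),
                                    axis=1).sum())


def snap_to_grid(point_mm: Sequence[float],
                 spacing: Sequence[float]) -> np.ndarray:
    """Round a physical point to the nearest voxel center.

    Thinning algorithms lose branches of even voxel width (a tube whose
    axis runs between voxel centers has no central voxel to survive), so
    phantom centerlines are anchored on the lattice.
    """
    p = np.asarray(point_mm, dtype=np.float64)
    s = np.asarray(spacing, dtype=np.float64)
    return np.round(p / s) * s


def straight_segment(start_mm: Sequence[float], end_mm: Sequence[float],
                     radius_mm: float) -> TubeSegment:
    """A straight capsule: DF = 1, SOAM = 0."""
    return TubeSegment(np.array([start_mm, end_mm]), radius_mm,
                       true_df=1.0, true_soam=0.0)


def arc_segment(center_mm: Sequence[float], curve_radius_mm: float,
                theta0: float, theta1: float, radius_mm: float,
                u: Sequence[float] = (1, 0, 0), v: Sequence[float] = (0, 1, 0),
                n_points: int = 200) -> TubeSegment:
    """A planar circular arc; DF = R*theta / (2 R sin(theta/2)), SOAM = 1/R."""
    c = np.asarray(center_mm, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    thetas = np.linspace(theta0, theta1, n_points)
    pts = c + curve_radius_mm * (np.outer(np.cos(thetas), u)
                                 + np.outer(np.sin(thetas), v))
    theta = abs(theta1 - theta0)
    df = (curve_radius_mm * theta) / (2 * curve_radius_mm * np.sin(theta / 2))
    return TubeSegment(pts, radius_mm, true_df=float(df),
                       true_soam=1.0 / curve_radius_mm)


@dataclass
class PhantomSpec:
    segments: List[TubeSegment]
    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    seed: int = 0


@dataclass
class PhantomTruth:
    """Closed-form geometry of a tube-tree phantom."""

    segment_lengths_mm: np.ndarray
    segment_df: np.ndarray
    segment_soam: np.ndarray
    n_branches: int
    n_endpoints: int
    n_junctions: int
    total_length_mm: float
    volume_mm3: float          # sum of cylinder volumes; approximate if tubes overlap
    overlap_flagged: bool = False


def _point_segment_distance(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    """Distance from each of ``points`` (n,3) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _rasterize_segment(mask: np.ndarray, seg: TubeSegment,
                       spacing: np.ndarray) -> None:
    pts = seg.points_mm
    r = seg.radius_mm
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.minimum(a, b) - r
        hi = np.maximum(a, b) + r
        i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1,
                        np.asarray(mask.shape))
        if np.any(i0 >= i1):
            continue
        grids = np.meshgrid(*[np.arange(i0[d], i1[d]) for d in range(3)],
                            indexing="ij")
        coords = np.stack([g.ravel() * spacing[d]
                           for d, g in enumerate(grids)], axis=1)
        inside = _point_segment_distance(coords, a, b) <= r
        idx = tuple(g.ravel()[inside] for g in grids)
        mask[idx] = True


def generate_tube_tree(spec: PhantomSpec) -> Tuple[BinaryMask, PhantomTruth]:
    """Rasterize a union of capsules and report its analytic geometry.

    Segments sharing an endpoint define the tree topology; the truth counts
    endpoints (degree-1 contact points) and junctions (degree >= 3).  If two
    segments overlap beyond a shared endpoint the branch count is flagged
    approximate.
    """
    spacing = np.asarray(spec.spacing, dtype=np.float64)
    mask = np.zeros(spec.shape, dtype=bool)
    for seg in spec.segments:
        hi = seg.points_mm.max(axis=0) + seg.radius_mm
        if np.any(hi > spacing * np.asarray(spec.shape)):
            raise ValueError("segment does not fit inside the grid")
        _rasterize_segment(mask, seg, spacing)

    # endpoint topology from coincident segment ends
    tol = 1e-6
    ends: List[np.ndarray] = []
    degree: List[int] = []
    for seg in spec.segments:
        for p in (seg.points_mm[0], seg.points_mm[-1]):
            for k, q in enumerate(ends):
                if np.linalg.norm(p - q) < tol:
                    degree[k] += 1
                    break
            else:
                ends.append(p)
                degree.append(1)
    deg = np.asarray(degree)
    lengths = np.array([s.length_mm for s in spec.segments])
    volume = float(sum(np.pi * s.radius_mm ** 2 * s.length_mm
                       for s in spec.segments))
    truth = PhantomTruth(
        segment_lengths_mm=lengths,
        segment_df=np.array([s.true_df for s in spec.segments]),
        segment_soam=np.array([s.true_soam for s in spec.segments]),
        n_branches=len(spec.segments),
        n_endpoints=int((deg == 1).sum()),
        n_junctions=int((deg >= 3).sum()),
        total_length_mm=float(lengths.sum()),
        volume_mm3=volume,
    )
    return BinaryMask(mask, tuple(spec.spacing)), truth


def symmetric_y_phantom(shape=(60, 60, 40), spacing=(0.5, 0.5, 0.5),
                        radius_mm: float = 1.0) -> PhantomSpec:
    """A Y of three straight tubes meeting at one junction (common oracle)."""
    sx, sy, sz = (np.asarray(shape) - 1) * np.asarray(spacing)
    snap = lambda p: snap_to_grid(p, spacing)
    junction = snap((sx / 2, sy / 2, sz / 2))
    root = snap((sx / 2, sy / 2, 3.0))
    tip_l = snap((sx / 2 - sx / 3, sy / 2, sz - 3.0))
    tip_r = snap((sx / 2 + sx / 3, sy / 2, sz - 3.0))
    return PhantomSpec(
        [straight_segment(root, junction, radius_mm),
         straight_segment(junction, tip_l, radius_mm),
         straight_segment(junction, tip_r, radius_mm)],
        tuple(shape), tuple(spacing))


# ---------------------------------------------------------------------------
# Lesion phantoms
# ---------------------------------------------------------------------------

DEFAULT_INTENSITY_MODEL: Dict[str, float] = {
    # DWI-like arbitrary units: bright lesion on a darker parenchyma
    "background_mean": 100.0, "background_sd": 10.0,
    "lesion_mean": 160.0, "lesion_sd": 12.0,
}


def _disk_mask(shape: Tuple[int, int, int], center: Tuple[int, int, int],
               radius_px: int, n_slices: int) -> np.ndarray:
    cx, cy, cz = center
    xs, ys = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    disk = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_px ** 2
    out = np.zeros(shape, dtype=bool)
    z0 = max(cz - n_slices // 2, 0)
    for z in range(z0, min(z0 + n_slices, shape[2])):
        out[:, :, z] = disk
    return out


def generate_lesion_case(
    shape: Tuple[int, int, int] = (48, 48, 12),
    spacing: Tuple[float, float, float] = (0.9375, 0.9375, 6.0),
    lesion_center: Optional[Tuple[int, int, int]] = None,
    lesion_radius_px: int = 6,
    lesion_slices: int = 3,
    intensity_model: Optional[Dict[str, float]] = None,
    seed: int = 0,
    case_id: str = "synthetic",
) -> CaseRecord:
    """A DWI-like volume with an elevated-mean disk lesion.

    ``intensity_model`` keys: background_mean/sd and lesion_mean/sd; an sd
    of 0 gives a constant region.  Deterministic under ``seed``.
    """
    model = dict(DEFAULT_INTENSITY_MODEL)
    if intensity_model:
        model.update(intensity_model)
    if lesion_center is None:
        lesion_center = (shape[0] // 2, shape[1] // 2, shape[2] // 2)
    rng = np.random.default_rng(seed)
    data = model["background_mean"] + model["background_sd"] * rng.standard_normal(shape)
    lesion = _disk_mask(shape, lesion_center, lesion_radius_px, lesion_slices)
    data[lesion] = (model["lesion_mean"]
                    + model["lesion_sd"] * rng.standard_normal(int(lesion.sum())))
    return CaseRecord(
        case_id=case_id,
        dwi=VolumeGrid(data, spacing),
        lesion=BinaryMask(lesion, spacing),
    )


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def generate_feature_table(
    n_cases: int, n_features: int, informative_idx: Sequence[int],
    effect_size: float, seed: int = 0,
    feature_names: Optional[List[str]] = None,
):
    """Balanced two-class Gaussian feature table with known signal columns.

    Informative columns are shifted by ``effect_size`` between the classes
    (+effect/2 for poor, -effect/2 for good); all columns have unit noise.
    """
    from .sparse_models import FeatureTable

    if n_cases % 2:
        raise ValueError("n_cases must be even for balanced classes")
    informative_idx = np.asarray(informative_idx, dtype=int)
    if informative_idx.size and informative_idx.max() >= n_features:
        raise ValueError("informative index out of range")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_cases, n_features))
    labels = np.array([GOOD, POOR] * (n_cases // 2), dtype=object)
    shift = np.where(labels == POOR, effect_size / 2, -effect_size / 2)
    X[:, informative_idx] += shift[:, None]
    if feature_names is None:
        feature_names = [f"f{j:04d}" for j in range(n_features)]
    ids = [f"case{i:03d}" for i in range(n_cases)]
    return FeatureTable(ids, list(feature_names), X, labels)


# ---------------------------------------------------------------------------
# Full synthetic cohort (vessel mask + DWI lesion per case)
# ---------------------------------------------------------------------------

def _cohort_vessel_spec(shape, spacing, affected: str, poor: bool,
                        rng: np.random.Generator) -> PhantomSpec:
    """Two mirrored hemisphere trees; poor cases lose side branches on the
    affected hemisphere (the stroke-related rarefaction the asymmetry
    features are designed to detect)."""
    ext = (np.asarray(shape) - 1) * np.asarray(spacing)
    snap = lambda p: snap_to_grid(p, spacing)
    segs: List[TubeSegment] = []
    for side in ("left", "right"):
        cx = ext[0] * (0.25 if side == "left" else 0.75)
        jitter = rng.uniform(-1.0, 1.0)
        trunk_top = ext[2] - 3.0
        segs.append(straight_segment(snap((cx, ext[1] / 2, 2.0)),
                                     snap((cx, ext[1] / 2, trunk_top)), 1.0))
        n_branch = 3
        if poor and side == affected:
            n_branch = 1 + int(rng.integers(0, 2))   # 1 or 2 branches
        for k in range(n_branch):
            z = 4.0 + (k + 1) * (trunk_top - 8.0) / 4.0
            dy = (ext[1] / 4 + jitter) * (1 if k % 2 else -1)
            segs.append(straight_segment(
                snap((cx, ext[1] / 2, z)),
                snap((cx + (3.0 if side == "left" else -3.0),
                      ext[1] / 2 + dy, z + 4.0)),
                0.8,
            ))
    return PhantomSpec(segs, tuple(shape), tuple(spacing))


def generate_cohort(
    n_cases: int = 30,
    seed: int = 0,
    vessel_shape: Tuple[int, int, int] = (64, 64, 24),
    vessel_spacing: Tuple[float, float, float] = (0.5, 0.5, 1.0),
    dwi_shape: Tuple[int, int, int] = (48, 48, 12),
    dwi_spacing: Tuple[float, float, float] = (0.9375, 0.9375, 6.0),
) -> List[CaseRecord]:
    """A balanced synthetic stroke cohort.

    Poor-prognosis cases have (i) a rarefied vascular tree on the affected
    side and (ii) a larger, brighter, more heterogeneous DWI lesion —
    caricatures of the real contrasts, strong enough that the downstream
    model is learnable at small n.
    """
    rng = np.random.default_rng(seed)
    cases: List[CaseRecord] = []
    for i in range(n_cases):
        poor = i % 2 == 1
        affected = "left" if rng.random() < 0.5 else "right"
        spec = _cohort_vessel_spec(vessel_shape, vessel_spacing, affected,
                                   poor, rng)
        vessel, _ = generate_tube_tree(spec)

        if poor:
            model = {"background_mean": 100.0, "background_sd": 10.0,
                     "lesion_mean": 175.0, "lesion_sd": 25.0}
            radius = int(rng.integers(7, 9))
        else:
            model = {"background_mean": 100.0, "background_sd": 10.0,
                     "lesion_mean": 150.0, "lesion_sd": 8.0}
            radius = int(rng.integers(4, 6))
        cx = dwi_shape[0] // 4 if affected == "left" else 3 * dwi_shape[0] // 4
        case = generate_lesion_case(
            shape=dwi_shape, spacing=dwi_spacing,
            lesion_center=(cx, dwi_shape[1] // 2, dwi_shape[2] // 2),
            lesion_radius_px=radius, intensity_model=model,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            case_id=f"syn{i:03d}",
        )
        case.vessel = vessel
        case.affected_side = affected
        case.label = POOR if poor else GOOD
        cases.append(case)
    return cases
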