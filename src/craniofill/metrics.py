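"""Reconstruction-quality metrics.

* Sørensen–Dice index (SDI): 2·N_TP / (2·N_TP + N_FP + N_FN) × 100 %,
  computed on bone-voxel sets of a predicted model P and ground truth G.
* Directed Hausdorff distance: max over bone voxels of G of the minimum
  Euclidean distance to a bone voxel of P, between voxel centres. In
  lattice units by default; with ``in_mm=True`` centres are scaled by
  the voxel spacing first. For anisotropic voxels one lattice HD unit
  corresponds to a physical distance between min(spacing) and
  ||spacing||₂ — e.g. (0.45, 0.45, 0.8) mm voxels give 0.45–1.0223 mm.
* Cranial vault asymmetry indices (ACVAI/PCVAI): on the axial plane
  that intersects the implant the most, four rays leave a midline point
  O at ±60° from the anterior Y-axis; the outermost skull-boundary
  crossings are A, B (anterior) and C, D (posterior), and
  ACVAI = (AO − BO)/AO × 100 %, PCVAI = (CO − DO)/DO × 100 %.
  A perfectly symmetric vault scores 0 % on both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .volume import DEFAULT_AXES, AxisConvention, BinaryVolume

__all__ = [
    "OverlapCounts",
    "CvaiMeasurement",
    "MetricsReport",
    "overlap_counts",
    "sdi",
    "directed_hausdorff",
    "symmetric_hausdorff",
    "hd_unit_range",
    "select_measurement_plane",
    "cvai_diagonals",
    "cvai_indices",
    "score_reconstruction",
]


@dataclass(frozen=True)
class OverlapCounts:
    n_tp: int
    n_fp: int
    n_fn: int


@dataclass
class CvaiMeasurement:
    plane_index: int
    O: tuple[float, float]            # (x, y) in mm on the plane
    points: dict                      # A/B/C/D -> (x, y) mm
    AO: float
    BO: float
    CO: float
    DO: float
    acvai: float                      # magnitude, %
    pcvai: float
    acvai_signed: float
    pcvai_signed: float


@dataclass
class MetricsReport:
    sdi_percent: float
    hausdorff: float
    hausdorff_mm: float
    cvai: CvaiMeasurement | None = None

    def as_dict(self) -> dict:
        out = {
            "sdi_percent": self.sdi_percent,
            "hausdorff": self.hausdorff,
            "hausdorff_mm": self.hausdorff_mm,
        }
        if self.cvai is not None:
            out["cvai"] = {
                "plane_index": self.cvai.plane_index,
                "AO": self.cvai.AO,
                "BO": self.cvai.BO,
                "CO": self.cvai.CO,
                "DO": self.cvai.DO,
                "acvai_percent": self.cvai.acvai,
                "pcvai_percent": self.cvai.pcvai,
            }
        return out


def overlap_counts(P: BinaryVolume, G: BinaryVolume) -> OverlapCounts:
    """True/false positive and false negative voxel counts of P vs G."""
    if P.shape != G.shape:
        raise ValueError(f"dim mismatch: {P.shape} vs {G.shape}")
    p, g = P.values.astype(bool), G.values.astype(bool)
    return OverlapCounts(
        n_tp=int(np.count_nonzero(p & g)),
        n_fp=int(np.count_nonzero(p & ~g)),
        n_fn=int(np.count_nonzero(~p & g)),
    )


def sdi(P: BinaryVolume, G: BinaryVolume) -> float:
    """Sørensen–Dice index in percent; undefined when both sets are empty."""
    c = overlap_counts(P, G)
    denom = 2 * c.n_tp + c.n_fp + c.n_fn
    if denom == 0:
        raise ValueError("SDI undefined: both volumes are empty")
    return 2.0 * c.n_tp / denom * 100.0


def _bone_points(volume: BinaryVolume, in_mm: bool) -> np.ndarray:
    pts = np.argwhere(volume.values > 0).astype(np.float64)
    if in_mm:
        pts *= np.asarray(volume.spacing)
    return pts


def directed_hausdorff(G: BinaryVolume, P: BinaryVolume, in_mm: bool = False) -> float:
    """max over bone voxels g of G of min over bone voxels p of P of
    ||g − p||₂, between voxel centres."""
    g = _bone_points(G, in_mm)
    p = _bone_points(P, in_mm)
    if g.size == 0 or p.size == 0:
        raise ValueError("directed Hausdorff needs two non-empty voxel sets")
    dists, _ = cKDTree(p).query(g, k=1)
    return float(dists.max())


def symmetric_hausdorff(A: BinaryVolume, B: BinaryVolume, in_mm: bool = False) -> float:
    """max(directed(A→B), directed(B→A)); the undirected variant."""
    return max(directed_hausdorff(A, B, in_mm), directed_hausdorff(B, A, in_mm))


def hd_unit_range(spacing) -> tuple[float, float]:
    """Physical distance, in mm, that one lattice HD unit can span:
    (smallest spacing component, Euclidean norm of the spacing)."""
    s = np.asarray(spacing, dtype=np.float64)
    if np.any(s <= 0):
        raise ValueError("spacing components must be positive")
    return float(s.min()), float(np.linalg.norm(s))


def select_measurement_plane(
    implant: BinaryVolume,
    frankfort_index: int = 0,
    axes: AxisConvention = DEFAULT_AXES,
) -> int:
    """Craniocaudal slice index where the implant's in-slice voxel count
    is maximal (the plane 'intersecting the implant the most', parallel
    to the Frankfort plane); ties go to the inferior-most slice."""
    v = implant.values
    if not v.any():
        raise ValueError("empty implant: no measurement plane")
    ax = axes.craniocaudal_axis
    counts = np.count_nonzero(v, axis=tuple(a for a in range(3) if a != ax))
    counts = counts[frankfort_index:]
    return frankfort_index + int(np.argmax(counts))  # argmax: first maximiser


def _bilinear(slice2d: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample a 2-D field at fractional grid coordinates (clamped)."""
    nx, ny = slice2d.shape
    x = np.clip(x, 0, nx - 1)
    y = np.clip(y, 0, ny - 1)
    x0 = np.clip(np.floor(x).astype(int), 0, nx - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, ny - 2)
    fx, fy = x - x0, y - y0
    f = slice2d
    return (
        f[x0, y0] * (1 - fx) * (1 - fy)
        + f[x0 + 1, y0] * fx * (1 - fy)
        + f[x0, y0 + 1] * (1 - fx) * fy
        + f[x0 + 1, y0 + 1] * fx * fy
    )


def _outermost_crossing(
    slice2d: np.ndarray,
    origin_mm: np.ndarray,
    direction: np.ndarray,
    spacing2: np.ndarray,
    name: str,
) -> float:
    """Distance (mm) from origin to the outermost boundary crossing of
    the contour along a ray; sub-voxel via bisection on the bilinear
    field at level 0.5."""
    extent = np.asarray(slice2d.shape) * spacing2
    t_max = float(np.linalg.norm(extent))
    step = 0.25 * float(spacing2.min())
    ts = np.arange(0.0, t_max, step)
    pts = origin_mm[None, :] + ts[:, None] * direction[None, :]
    vals = _bilinear(slice2d, pts[:, 0] / spacing2[0], pts[:, 1] / spacing2[1])
    inside = vals >= 0.5
    if not inside.any():
        raise ValueError(f"ray {name} never meets the skull contour")
    i_last = int(np.nonzero(inside)[0][-1])
    lo, hi = ts[i_last], ts[min(i_last + 1, len(ts) - 1)]
    for _ in range(24):  # bisect the exit crossing
        mid = 0.5 * (lo + hi)
        p = origin_mm + mid * direction
        if _bilinear(slice2d, np.array([p[0] / spacing2[0]]), np.array([p[1] / spacing2[1]]))[0] >= 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cvai_diagonals(
    skull: BinaryVolume,
    plane_index: int,
    O: tuple[float, float] | None = None,
    angle_deg: float = 60.0,
    axes: AxisConvention = DEFAULT_AXES,
) -> CvaiMeasurement:
    """Measure the four diagonal radii AO, BO, CO, DO on one axial slice.

    Rays leave O at ±``angle_deg`` from the anterior Y-axis: A and B
    anterior (A on the −X side, B on the +X side), C and D posterior
    with C opposite A (line AC) and D opposite B (line BD). Each point
    is the outermost contour crossing along its ray; lengths are
    Euclidean in mm. When O is None it defaults to the centroid of the
    in-plane cross-section (a midline point for a near-symmetric vault).
    """
    ax = axes.craniocaudal_axis
    sl = [slice(None)] * 3
    sl[ax] = plane_index
    slice2d = np.asarray(skull.values[tuple(sl)], dtype=np.float64)
    planar_axes = [a for a in range(3) if a != ax]
    spacing2 = np.asarray([skull.spacing[a] for a in planar_axes])
    if not slice2d.any():
        raise ValueError(f"slice {plane_index} holds no bone")
    if O is None:
        idx = np.argwhere(slice2d > 0)
        O = tuple(idx.mean(axis=0) * spacing2)
    origin = np.asarray(O, dtype=np.float64)
    th = np.deg2rad(angle_deg)
    # direction components: axis 0 = lateral X, axis 1 = anterior Y
    rays = {
        "A": np.array([-np.sin(th), np.cos(th)]),
        "B": np.array([np.sin(th), np.cos(th)]),
        "C": np.array([np.sin(th), -np.cos(th)]),
        "D": np.array([-np.sin(th), -np.cos(th)]),
    }
    lengths, points = {}, {}
    for name, d in rays.items():
        t = _outermost_crossing(slice2d, origin, d, spacing2, name)
        lengths[name] = t
        points[name] = tuple(origin + t * d)
    acvai_s, pcvai_s, acvai, pcvai = cvai_indices(
        lengths["A"], lengths["B"], lengths["C"], lengths["D"], signed=True
    )
    return CvaiMeasurement(
        plane_index=plane_index,
        O=tuple(origin),
        points=points,
        AO=lengths["A"],
        BO=lengths["B"],
        CO=lengths["C"],
        DO=lengths["D"],
        acvai=acvai,
        pcvai=pcvai,
        acvai_signed=acvai_s,
        pcvai_signed=pcvai_s,
    )


def cvai_indices(AO: float, BO: float, CO: float, DO: float, signed: bool = False):
    """ACVAI = (AO − BO)/AO × 100 %, PCVAI = (CO − DO)/DO × 100 %.

    Magnitudes are returned (the printed indices are positive
    regardless of which diagonal is longer); with ``signed=True`` the
    signed values are returned as well:
    (acvai_signed, pcvai_signed, acvai, pcvai).
    """
    if AO <= 0 or DO <= 0:
        raise ValueError("AO and DO must be positive (they are denominators)")
    a = (AO - BO) / AO * 100.0
    p = (CO - DO) / DO * 100.0
    if signed:
        return a, p, abs(a), abs(p)
    return abs(a), abs(p)


def score_reconstruction(
    pred: BinaryVolume,
    truth: BinaryVolume,
    in_mm_hd: bool = False,
    cvai_plane: int | None = None,
) -> MetricsReport:
    """Bundle SDI + directed HD (lattice and mm) and, optionally, the
    asymmetry indices measured on ``pred`` at ``cvai_plane``."""
    report = MetricsReport(
        sdi_percent=sdi(pred, truth),
        hausdorff=directed_hausdorff(truth, pred, in_mm=False),
        hausdorff_mm=directed_hausdorff(truth, pred, in_mm=True),
    )
    if cvai_plane is not None:
        report.cvai = cvai_diagonals(pred, cvai_plane)
    return report
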