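"""Synthetic skull defects and ground-truth implants.

Defects are carved from intact skulls by Boolean subtraction of
parametric 3-D masks — elliptical cylinders, ellipsoids, and two
compound families (a union of two cylinders with independent axes, and
an ellipsoid-cylinder union sharing a centre). The removed bone is the
ground-truth implant, so every defective model comes paired with an
exact target for supervised training and for overlap metrics.

Mask in-plane diameters are sampled from a configurable range,
60-120 mm by default, and placed at random positions over the upper
skull. Rotation augmentation about the craniocaudal axis (2 degree
steps, three variants per side plus the original = seven) expands the
dataset the same way yaw variation between scans would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume

__all__ = [
    "MASK_FAMILIES",
    "MaskSpec",
    "DefectPair",
    "sample_mask_spec",
    "rasterize_mask",
    "apply_defect",
    "rotate_augment",
    "is_defect_in_range",
    "make_defect_pairs",
]

MASK_FAMILIES = (
    "elliptical_cylinder",
    "mixed_elliptical_cylinder",
    "ellipsoid",
    "hybrid_ellipsoid",
)


@dataclass
class MaskComponent:
    """One primitive solid: ``kind`` is 'cylinder' or 'ellipsoid'.

    ``semi_axes`` for a cylinder is (in-plane a, in-plane b, half-height),
    with the half-height measured along ``axis_direction``; for an
    ellipsoid it is the three semi-axes in the frame whose third basis
    vector is ``axis_direction``. All lengths in mm.
    """

    kind: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "ellipsoid"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        d = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis_direction must be a non-zero vector")
        self.axis_direction = tuple(d / n)


@dataclass
class MaskSpec:
    """Parametric description of one defect mask (union of 1-2 primitives)."""

    family: str
    components: list[MaskComponent]

    def __post_init__(self) -> None:
        if self.family not in MASK_FAMILIES:
            raise ValueError(f"family must be one of {MASK_FAMILIES}")
        if not 1 <= len(self.components) <= 2:
            raise ValueError("a mask has 1 or 2 primitive components")

    @property
    def max_diameter_mm(self) -> float:
        """Largest in-plane diameter over the primitive components."""
        return max(2.0 * max(c.semi_axes[:2]) for c in self.components)


@dataclass
class DefectPair:
    defective: BinaryVolume
    implant_truth: BinaryVolume
    mask: MaskSpec | None = None


def _orthobasis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pair of unit vectors orthogonal to ``axis``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def sample_mask_spec(
    rng: np.random.Generator,
    grid_shape: tuple[int, int, int] = (64, 64, 48),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.2),
    diameter_range_mm: tuple[float, float] = (60.0, 120.0),
    families: tuple[str, ...] = MASK_FAMILIES,
) -> MaskSpec:
    """Draw one random mask spec.

    The family is uniform over ``families``; the leading in-plane
    diameter is uniform over ``diameter_range_mm`` (secondary axes are
    scaled fractions of it, so the spec's max diameter equals the
    draw); the centre is uniform over the upper-skull region (upper 45%
    of the craniocaudal extent, central 80% in plane).
    """
    lo, hi = diameter_range_mm
    if not (0 < lo <= hi):
        raise ValueError(f"invalid diameter range {diameter_range_mm}")
    if not families:
        raise ValueError("families must be non-empty")
    for f in families:
        if f not in MASK_FAMILIES:
            raise ValueError(f"unknown family {f!r}")
    family = families[rng.integers(len(families))]
    extent = np.array(grid_shape) * np.array(spacing)
    centre = np.array(
        [
            rng.uniform(0.1, 0.9) * extent[0],
            rng.uniform(0.1, 0.9) * extent[1],
            rng.uniform(0.55, 0.95) * extent[2],
        ]
    )
    diameter = rng.uniform(lo, hi)
    r = diameter / 2.0

    def unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def cyl(c: np.ndarray, lead: float) -> MaskComponent:
        return MaskComponent(
            "cylinder",
            tuple(c),
            (lead, lead * rng.uniform(0.6, 1.0), lead * rng.uniform(0.6, 1.2)),
            tuple(unit()),
        )

    def ell(c: np.ndarray, lead: float) -> MaskComponent:
        return MaskComponent(
            "ellipsoid",
            tuple(c),
            (lead, lead * rng.uniform(0.6, 1.0), lead * rng.uniform(0.5, 1.0)),
            tuple(unit()),
        )

    if family == "elliptical_cylinder":
        comps = [cyl(centre, r)]
    elif family == "mixed_elliptical_cylinder":
        comps = [cyl(centre, r), cyl(centre, r * rng.uniform(0.5, 0.9))]
    elif family == "ellipsoid":
        comps = [ell(centre, r)]
    else:  # hybrid_ellipsoid: ellipsoid + cylinder sharing a centre
        comps = [ell(centre, r), cyl(centre, r * rng.uniform(0.5, 0.9))]
    return MaskSpec(family, comps)


def rasterize_mask(spec: MaskSpec, grid_template: BinaryVolume) -> BinaryVolume:
    """Voxelize ``spec``: voxel = 1 iff its centre lies in the union of
    the primitive solids. Returns an all-zero volume (with a warning
    flag attribute ``empty_mask``) when the mask misses the grid."""
    dims, spacing = grid_template.shape, grid_template.spacing
    coords = np.meshgrid(
        *[np.arange(d) * s for d, s in zip(dims, spacing)], indexing="ij"
    )
    pts = np.stack(coords, axis=-1)  # (X, Y, Z, 3) voxel centres in mm
    inside = np.zeros(dims, dtype=bool)
    for comp in spec.components:
        d = np.asarray(comp.axis_direction)
        e1, e2 = _orthobasis(d)
        rel = pts - np.asarray(comp.center)
        t = rel @ d
        u = rel @ e1
        v = rel @ e2
        sa, sb, sc = comp.semi_axes
        if comp.kind == "cylinder":
            inside |= ((u / sa) ** 2 + (v / sb) ** 2 <= 1.0) & (np.abs(t) <= sc)
        else:
            inside |= (u / sa) ** 2 + (v / sb) ** 2 + (t / sc) ** 2 <= 1.0
    out = BinaryVolume(inside.astype(np.uint8), spacing, grid_template.origin)
    out.empty_mask = not bool(inside.any())
    return out


def apply_defect(intact: BinaryVolume, mask: BinaryVolume) -> DefectPair:
    """Split an intact skull into (defective, ground-truth implant).

    defective = intact AND NOT mask; implant = intact AND mask. The two
    partition the intact bone exactly.
    """
    if not intact.same_grid(mask):
        raise ValueError(
            f"grid mismatch: intact {intact.shape} vs mask {mask.shape}"
        )
    i, m = intact.values.astype(bool), mask.values.astype(bool)
    defective = BinaryVolume((i & ~m).astype(np.uint8), intact.spacing, intact.origin)
    implant = BinaryVolume((i & m).astype(np.uint8), intact.spacing, intact.origin)
    return DefectPair(defective, implant, None)


def rotate_augment(
    volume: BinaryVolume, interval_deg: float = 2.0, per_side: int = 3
) -> list[BinaryVolume]:
    """Rotations about the craniocaudal axis at k*interval_deg for
    k = -per_side..+per_side (2*per_side + 1 variants; the k = 0 member
    is the input itself). Nearest-neighbour resampling keeps the grid
    binary; rotation centre is the grid centre."""
    if interval_deg <= 0:
        raise ValueError("interval_deg must be positive")
    out = []
    for k in range(-per_side, per_side + 1):
        if k == 0:
            out.append(volume.copy())
            continue
        rot = ndimage.rotate(
            volume.values,
            angle=k * interval_deg,
            axes=(0, 1),
            reshape=False,
            order=0,
            mode="constant",
            cval=0,
        )
        out.append(BinaryVolume(rot.astype(np.uint8), volume.spacing, volume.origin))
    return out


def is_defect_in_range(
    pair: DefectPair,
    plane_index: int,
    max_components: int = 2,
    min_component_voxels: int = 27,
) -> bool:
    """Keep a defect only if it is usable for training: the implant is
    non-empty, lies entirely at or above the base plane, and removing
    it does not shatter the skull — the defective model may not have
    more than ``max_components`` large 6-connected pieces beyond what
    the intact model (defective OR implant) already had."""
    implant = pair.implant_truth.values
    if not implant.any():
        return False
    zs = np.nonzero(implant)[2]
    if zs.min() < plane_index:
        return False
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connected

    def n_large(mask: np.ndarray) -> int:
        labels, n = ndimage.label(mask, structure=structure)
        if not n:
            return 0
        sizes = np.bincount(labels.ravel())[1:]
        return int((sizes >= min_component_voxels).sum())

    intact = pair.defective.values.astype(bool) | implant.astype(bool)
    base = max(n_large(intact), 1)
    return n_large(pair.defective.values) <= base + (max_components - 1)


def make_defect_pairs(
    intact: BinaryVolume,
    n_variants: int = 25,
    rng: np.random.Generator | int = 0,
    diameter_range_mm: tuple[float, float] = (60.0, 120.0),
    families: tuple[str, ...] = MASK_FAMILIES,
    plane_index: int | None = None,
    max_attempts_per_variant: int = 40,
) -> list[DefectPair]:
    """Inject ``n_variants`` (default 25) random defects into one intact
    skull, rejecting out-of-range ones, and return the DefectPairs."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if plane_index is None:
        zs = np.nonzero(intact.values)[2]
        plane_index = int(zs.min()) if zs.size else 0
    pairs: list[DefectPair] = []
    attempts = 0
    budget = n_variants * max_attempts_per_variant
    while len(pairs) < n_variants:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n_variants} in-range defects in {budget} attempts"
            )
        attempts += 1
        spec = sample_mask_spec(
            rng, intact.shape, intact.spacing, diameter_range_mm, families
        )
        mask = rasterize_mask(spec, intact)
        pair = apply_defect(intact, mask)
        pair.mask = spec
        if is_defect_in_range(pair, plane_index):
            pairs.append(pair)
    return pairs
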