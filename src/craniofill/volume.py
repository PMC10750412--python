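"""Voxel-grid containers for skull models.

Two containers cover the whole pipeline: :class:`ScalarVolume` for CT
intensities (Hounsfield units) and network probability maps, and
:class:`BinaryVolume` for occupancy grids in which 1 marks bone tissue.
Both carry physical voxel spacing and a world origin in millimetres so
that distances and mesh exports come out in real units.

Axis convention: grid axes are ordered (X, Y, Z) with Z the craniocaudal
(head-to-foot) axis and Y the anterior-posterior axis. Indexing is
0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Triple = tuple[float, float, float]


@dataclass(frozen=True)
class AxisConvention:
    """Which grid axes carry anatomical meaning.

    ``craniocaudal_axis`` is the head-to-foot axis (slices stack along
    it); ``anterior_axis`` points towards the face and defines the
    Y-axis of the asymmetry-index geometry.
    """

    craniocaudal_axis: int = 2
    anterior_axis: int = 1

    def __post_init__(self) -> None:
        if self.craniocaudal_axis == self.anterior_axis:
            raise ValueError("craniocaudal and anterior axes must be distinct")
        for ax in (self.craniocaudal_axis, self.anterior_axis):
            if ax not in (0, 1, 2):
                raise ValueError(f"axis index {ax} outside 0..2")


DEFAULT_AXES = AxisConvention()


def _check_grid(values: np.ndarray, spacing: Triple) -> None:
    if values.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got ndim={values.ndim}")
    if min(values.shape) < 1:
        raise ValueError(f"every dimension must be >= 1, got {values.shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive, got {spacing}")


@dataclass
class ScalarVolume:
    """Real-valued 3-D grid (HU intensities or predicted probabilities)."""

    values: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.values, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.values.copy(), self.spacing, self.origin)


@dataclass
class BinaryVolume:
    """Occupancy grid over {0, 1}; 1 marks bone tissue."""

    values: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.dtype != np.uint8:
            unique = np.unique(values)
            if not np.all(np.isin(unique, (0, 1))):
                raise ValueError("binary volume may only contain 0 and 1")
            values = values.astype(np.uint8)
        self.values = values
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        _check_grid(self.values, self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def ones_count(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "BinaryVolume":
        return BinaryVolume(self.values.copy(), self.spacing, self.origin)

    def same_grid(self, other: "BinaryVolume | ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)
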