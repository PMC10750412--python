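"""Synthetic cranial-vault phantoms.

A phantom is a closed ellipsoidal shell of finite bone thickness whose
right half is scaled by (1 + asymmetry) — real skulls are asymmetric
about the sagittal plane — cropped below a horizontal base plane that
stands in for the Frankfort plane. Shells are defined by an implicit
double-ellipsoid inequality evaluated at voxel centres, so an analytic
volume oracle (4/3)pi(abc - a'b'c') is available for testing.

These phantoms let every downstream stage (defect synthesis, network
training, implant extraction) be exercised without any patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume
from .voxel_io import crop_below_plane, downsample_binary

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset", "DEFAULT_SPEC_RANGES"]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cranial vault.

    Semi-axes and thickness are in mm; ``asymmetry`` is the fractional
    left-right scale difference; ``base_plane_fraction`` is the fraction
    of the craniocaudal grid extent below which bone is removed.
    """

    outer_semi_axes: tuple[float, float, float] = (70.0, 85.0, 60.0)
    shell_thickness: float = 6.0
    asymmetry: float = 0.04
    base_plane_fraction: float = 0.3
    dims: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.2)
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.outer_semi_axes
        if not 0 < self.shell_thickness < min(a, b, c):
            raise ValueError(
                f"shell_thickness {self.shell_thickness} must lie in (0, {min(a, b, c)})"
            )
        if not 0 <= self.asymmetry < 0.5:
            raise ValueError(f"asymmetry {self.asymmetry} outside [0, 0.5)")
        if not 0 <= self.base_plane_fraction < 1:
            raise ValueError(
                f"base_plane_fraction {self.base_plane_fraction} outside [0, 1)"
            )


def generate_phantom(spec: PhantomSpec) -> BinaryVolume:
    """Rasterize the shell described by ``spec`` onto its grid."""
    dims, spacing = spec.dims, spec.spacing
    a, b, c = spec.outer_semi_axes
    # physical grid must contain the (asymmetry-scaled) outer shell
    half_extent = [d * s / 2.0 for d, s in zip(dims, spacing)]
    needed = (a * (1 + spec.asymmetry), b, c)
    for ax, (need, have) in enumerate(zip(needed, half_extent)):
        if need > have:
            raise ValueError(
                f"shell semi-axis {need:.1f} mm exceeds grid half-extent "
                f"{have:.1f} mm along axis {ax}"
            )
    centre = [(d - 1) / 2.0 * s for d, s in zip(dims, spacing)]
    coords = [
        (np.arange(d) * s - c0).astype(np.float64)
        for d, s, c0 in zip(dims, spacing, centre)
    ]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    # right half (x > 0) scaled by (1 + asymmetry)
    xs = np.where(x > 0, x / (1.0 + spec.asymmetry), x)
    t = spec.shell_thickness
    inner = (a - t, b - t, c - t)

    def q(sa: tuple[float, float, float]) -> np.ndarray:
        return (xs / sa[0]) ** 2 + (y / sa[1]) ** 2 + (z / sa[2]) ** 2

    outer = q((a, b, c)) <= 1.0
    shell = outer & (q(inner) > 1.0)
    # a wall thinner than the voxel pitch would rasterize with tunnels;
    # always keep the outer solid's one-voxel boundary layer so the
    # shell stays a closed (6-connected) surface at any resolution
    eroded = ndimage.binary_erosion(
        outer, structure=ndimage.generate_binary_structure(3, 1)
    )
    shell |= outer & ~eroded
    vol = BinaryVolume(shell.astype(np.uint8), spacing)
    plane = int(round(spec.base_plane_fraction * dims[2]))
    if plane > 0:
        vol = crop_below_plane(vol, plane)
    return vol


DEFAULT_SPEC_RANGES: dict[str, tuple[float, float]] = {
    "a": (60.0, 75.0),
    "b": (72.0, 90.0),
    "c": (52.0, 64.0),
    "thickness": (4.5, 8.0),
    "asymmetry": (0.0, 0.08),
    "base_plane_fraction": (0.25, 0.35),
}


def generate_dataset(
    n: int,
    spec_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    dims: tuple[int, int, int] = (64, 64, 48),
    spacing: tuple[float, float, float] | None = None,
    low_res_factor: int = 4,
) -> list[tuple[BinaryVolume, BinaryVolume]]:
    """Draw ``n`` phantoms and pair each with its downsampled twin.

    Parameters are drawn uniformly from ``spec_ranges`` (defaults mimic
    adult cranial-vault proportions). When ``spacing`` is omitted it is
    chosen so the physical field of view stays 192 x 192 x 153.6 mm —
    head-sized — at any grid resolution. Returns ``[(intact_high,
    intact_low), ...]``; the low member is block-majority downsampled by
    ``low_res_factor``, matching the paired-resolution training layout.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spacing is None:
        spacing = (192.0 / dims[0], 192.0 / dims[1], 153.6 / dims[2])
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        ranges.update(spec_ranges)
    for key, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {key!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        u = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        spec = PhantomSpec(
            outer_semi_axes=(u["a"], u["b"], u["c"]),
            shell_thickness=u["thickness"],
            asymmetry=u["asymmetry"],
            base_plane_fraction=u["base_plane_fraction"],
            dims=dims,
            spacing=spacing,
            seed=seed + i,
        )
        high = generate_phantom(spec)
        low = downsample_binary(high, low_res_factor)
        out.append((high, low))
    return out
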