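"""From completed skull to implant geometry.

The implant is the Boolean difference ``completed AND NOT defective``.
In practice the defective model is first scaled up uniformly (102 % by
default) about its occupancy centroid: the slightly inflated subtrahend
gives the surgeon a more tolerant fit and suppresses sliver noise where
the reconstructed and defective surfaces almost coincide. Remaining
specks are removed by a morphological opening (ball element) followed
by connected-component analysis keeping the largest component(s).
The final geometry exports as a watertight STL surface in mm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volume import BinaryVolume

__all__ = [
    "scale_volume",
    "extract_implant",
    "postprocess_implant",
    "export_mesh",
]


def scale_volume(volume: BinaryVolume, factor: float = 1.02) -> BinaryVolume:
    """Uniformly scale the occupancy by ``factor`` about its centroid
    (nearest-neighbour resampling on the same grid)."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return volume.copy()
    v = volume.values
    if not v.any():
        return volume.copy()
    idx = np.argwhere(v > 0).astype(np.float64)
    centroid = idx.mean(axis=0)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    half = np.maximum(centroid - lo, hi - centroid) * factor
    if np.any(centroid - half < -0.5) or np.any(
        centroid + half > np.asarray(v.shape) - 0.5
    ):
        raise ValueError(
            f"scaling by {factor} pushes the shape outside the grid; pad the volume"
        )
    # output voxel x maps to input voxel centroid + (x - centroid)/factor
    matrix = np.eye(3) / factor
    offset = centroid - matrix @ centroid
    out = ndimage.affine_transform(
        v, matrix, offset=offset, order=0, mode="constant", cval=0, output=np.uint8
    )
    return BinaryVolume(out, volume.spacing, volume.origin)


def extract_implant(
    completed: BinaryVolume,
    defective: BinaryVolume,
    tolerance_scale: float = 1.02,
) -> BinaryVolume:
    """implant = completed AND NOT scale(defective, tolerance_scale)."""
    if not completed.same_grid(defective):
        raise ValueError(
            f"grid mismatch: completed {completed.shape} vs defective {defective.shape}"
        )
    subtrahend = scale_volume(defective, tolerance_scale)
    out = completed.values.astype(bool) & ~subtrahend.values.astype(bool)
    return BinaryVolume(out.astype(np.uint8), completed.spacing, completed.origin)


def postprocess_implant(
    implant: BinaryVolume, opening_radius: int = 1, keep_components: int = 1
) -> BinaryVolume:
    """Morphological opening (ball element of ``opening_radius``
    voxels) then keep the ``keep_components`` largest 6-connected
    components. Empty results are allowed."""
    if opening_radius < 0:
        raise ValueError("opening_radius must be >= 0")
    v = implant.values.astype(bool)
    if opening_radius > 0 and v.any():
        r = opening_radius
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = xx**2 + yy**2 + zz**2 <= r**2
        v = ndimage.binary_opening(v, structure=ball)
    if v.any() and keep_components >= 1:
        structure = ndimage.generate_binary_structure(3, 1)
        labels, n = ndimage.label(v, structure=structure)
        if n > keep_components:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            keep = np.argsort(sizes)[::-1][:keep_components]
            v = np.isin(labels, keep)
    return BinaryVolume(v.astype(np.uint8), implant.spacing, implant.origin)


def export_mesh(volume: BinaryVolume, path: str | Path) -> trimesh.Trimesh:
    """Iso-surface the occupancy at level 0.5 and write a binary STL.

    Vertices are in mm (spacing- and origin-aware). The field is
    refined x2 by voxel replication and zero-padded before marching
    cubes: the padding closes the surface and the refinement removes
    the non-manifold checkerboard configurations thin binary shells
    otherwise produce, so the mesh is watertight. Returns the mesh.
    """
    if not volume.values.any():
        raise ValueError("cannot mesh an empty volume")
    fine = volume.values
    for ax in range(3):
        fine = np.repeat(fine, 2, axis=ax)
    padded = np.pad(fine.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    spacing = np.asarray(volume.spacing)
    # fine voxel i sits at original coordinate (i - 1) * s/2 - s/4
    verts = (verts - 1.0) * spacing / 2.0 - spacing / 4.0 + np.asarray(volume.origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    mesh.export(str(path))
    return mesh
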