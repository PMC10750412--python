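"""Reading, writing and resampling 3-D skull volumes.

Supported on-disk formats:

* NIfTI (``.nii`` / ``.nii.gz``) via nibabel,
* NRRD (``.nrrd``) via SimpleITK,
* a raw-uint8 dialect: one byte per voxel in X-fastest order, with a
  JSON sidecar ``<stem>.json`` holding ``{"dims", "spacing", "origin"}``.

Volumes whose payload is {0,1} come back as :class:`BinaryVolume`;
anything else as :class:`ScalarVolume`. Spacing is (sx, sy, sz) in
mm/voxel along the (X, Y, Z) grid axes.

The craniocaudal resampler implements a windowed-sinc (Lanczos, a = 3)
kernel along the slice axis only, which is how anisotropic CT stacks
(0.3-1.25 mm slice interval) are normalised to a fixed slice count
while planar resolution is left untouched. Bone is then extracted by a
closed Hounsfield window, typically [1200, 1817].
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .volume import BinaryVolume, ScalarVolume

__all__ = [
    "read_volume",
    "write_volume",
    "binarize_hounsfield",
    "resample_craniocaudal",
    "downsample_binary",
    "upsample_binary",
    "crop_below_plane",
]

_FORMATS = ("nifti", "nrrd", "raw")


def _format_from_path(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".nrrd"):
        return "nrrd"
    if name.endswith((".raw", ".u8")):
        return "raw"
    raise ValueError(
        f"cannot infer format from {path!r}; pass format= one of {_FORMATS}"
    )


def _wrap(values: np.ndarray, spacing, origin) -> ScalarVolume | BinaryVolume:
    flat = values.ravel()
    sample = flat if flat.size <= 4_000_000 else flat[:: flat.size // 2_000_000]
    if np.all((sample == 0) | (sample == 1)) and np.all((flat == 0) | (flat == 1)):
        return BinaryVolume(values.astype(np.uint8), spacing, origin)
    return ScalarVolume(values.astype(np.float64), spacing, origin)


def read_volume(path: str | Path, format: str | None = None) -> ScalarVolume | BinaryVolume:
    """Read a volume; binary payloads yield a :class:`BinaryVolume`."""
    path = Path(path)
    fmt = format or _format_from_path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt == "nifti":
        img = nib.load(str(path))
        values = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return _wrap(values, tuple(float(z) for z in zooms), origin)
    if fmt == "nrrd":
        img = sitk.ReadImage(str(path))
        # SimpleITK returns arrays as (z, y, x); transpose to (x, y, z)
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return _wrap(values, img.GetSpacing(), img.GetOrigin())
    # raw uint8 + JSON sidecar
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(
            f"raw format needs a JSON sidecar with dims/spacing: {sidecar} missing"
        )
    meta = json.loads(sidecar.read_text())
    for key in ("dims", "spacing"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing required key {key!r}")
    dims = tuple(int(d) for d in meta["dims"])
    payload = np.fromfile(path, dtype=np.uint8)
    if payload.size != int(np.prod(dims)):
        raise ValueError(
            f"raw payload has {payload.size} bytes but sidecar declares dims {dims}"
        )
    # X-fastest ordering: X varies quickest, then Y, then Z
    values = payload.reshape(dims[::-1]).transpose(2, 1, 0)
    origin = tuple(meta.get("origin", (0.0, 0.0, 0.0)))
    return _wrap(values, tuple(meta["spacing"]), origin)


def write_volume(
    volume: ScalarVolume | BinaryVolume, path: str | Path, format: str | None = None
) -> None:
    """Write a volume so that :func:`read_volume` round-trips it."""
    path = Path(path)
    fmt = format or _format_from_path(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    os.makedirs(path.parent or Path("."), exist_ok=True)
    values = volume.values
    if fmt == "nifti":
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        dtype = np.uint8 if isinstance(volume, BinaryVolume) else np.float64
        img = nib.Nifti1Image(values.astype(dtype), affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
        return
    if fmt == "nrrd":
        arr = values.transpose(2, 1, 0)
        dtype = np.uint8 if isinstance(volume, BinaryVolume) else np.float64
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.astype(dtype)))
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
        return
    # raw uint8: 1 byte per voxel, X-fastest
    if not isinstance(volume, BinaryVolume):
        if not np.all(np.isin(np.unique(values), (0, 1))):
            raise ValueError("raw-uint8 dialect stores binary volumes only")
    payload = values.astype(np.uint8).transpose(2, 1, 0).ravel()
    payload.tofile(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "dims": list(values.shape),
                "spacing": list(volume.spacing),
                "origin": list(volume.origin),
            }
        )
    )


def binarize_hounsfield(volume: ScalarVolume, lo: float = 1200.0, hi: float = 1817.0) -> BinaryVolume:
    """Extract bone by a closed HU window: voxel = 1 iff lo <= I <= hi."""
    if lo > hi:
        raise ValueError(f"window is empty: lo={lo} > hi={hi}")
    bad = np.count_nonzero(~np.isfinite(volume.values))
    if bad:
        raise ValueError(f"{bad} non-finite intensities; clean the volume first")
    mask = (volume.values >= lo) & (volume.values <= hi)
    return BinaryVolume(mask.astype(np.uint8), volume.spacing, volume.origin)


def _lanczos_weights(n_in: int, n_out: int, a: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Per-output-sample source indices (edge-clamped) and normalised weights."""
    scale = n_in / n_out
    # map output slice centres onto the input lattice (extent-preserving)
    x = (np.arange(n_out) + 0.5) * scale - 0.5
    left = np.floor(x).astype(int) - a + 1
    offsets = np.arange(2 * a)  # taps per output sample
    idx = left[:, None] + offsets[None, :]
    t = x[:, None] - idx
    w = np.sinc(t) * np.sinc(t / a)
    w[np.abs(t) >= a] = 0.0
    w /= w.sum(axis=1, keepdims=True)  # constants are fixed points
    idx = np.clip(idx, 0, n_in - 1)  # clamp out-of-range taps to edges
    return idx, w


def resample_craniocaudal(
    volume: ScalarVolume | BinaryVolume,
    target_slices: int,
    method: str = "lanczos",
    axis: int = 2,
):
    """Resample only the craniocaudal axis to ``target_slices`` slices.

    Planar dims are untouched; spacing along the axis is rescaled so the
    physical extent is preserved. Binary inputs are interpolated as
    reals and re-thresholded at 0.5.
    """
    if target_slices < 1:
        raise ValueError(f"target_slices must be >= 1, got {target_slices}")
    if method not in ("lanczos", "nearest", "linear"):
        raise ValueError(f"unknown method {method!r}")
    values = np.moveaxis(np.asarray(volume.values, dtype=np.float64), axis, -1)
    n_in = values.shape[-1]
    if method == "nearest":
        src = np.minimum(
            ((np.arange(target_slices) + 0.5) * n_in / target_slices).astype(int),
            n_in - 1,
        )
        out = values[..., src]
    else:
        a = 1 if method == "linear" else 3
        idx, w = _lanczos_weights(n_in, target_slices, a=a)
        out = np.einsum("...ot,ot->...o", values[..., idx], w, optimize=True)
        # fancy indexing placed the output axis before taps; fix shape
    out = np.moveaxis(out, -1, axis)
    spacing = list(volume.spacing)
    spacing[axis] = spacing[axis] * n_in / target_slices
    if isinstance(volume, BinaryVolume):
        return BinaryVolume((out >= 0.5).astype(np.uint8), tuple(spacing), volume.origin)
    return ScalarVolume(out, tuple(spacing), volume.origin)


def downsample_binary(volume: BinaryVolume, factor: int = 4) -> BinaryVolume:
    """Block-majority downsampling; ties (exactly half) count as bone."""
    shape = volume.shape
    if any(d % factor for d in shape):
        raise ValueError(
            f"dims {shape} not divisible by factor {factor}; pad or crop first"
        )
    v = volume.values
    nx, ny, nz = (d // factor for d in shape)
    blocks = v.reshape(nx, factor, ny, factor, nz, factor)
    occupancy = blocks.sum(axis=(1, 3, 5), dtype=np.int64)
    out = (2 * occupancy >= factor**3).astype(np.uint8)
    spacing = tuple(s * factor for s in volume.spacing)
    return BinaryVolume(out, spacing, volume.origin)


def upsample_binary(volume: BinaryVolume, factor: int = 4) -> BinaryVolume:
    """Replicate each voxel into a factor-cubed block (inverse grid of
    :func:`downsample_binary`)."""
    v = volume.values
    for ax in range(3):
        v = np.repeat(v, factor, axis=ax)
    spacing = tuple(s / factor for s in volume.spacing)
    return BinaryVolume(v, spacing, volume.origin)


def crop_below_plane(volume, plane_index: int, axis: int = 2):
    """Zero all voxels whose craniocaudal index is below ``plane_index``.

    Emulates removing bone below the Frankfort horizontal plane; the
    plane index is supplied per volume (no landmark detection). Dims
    are unchanged.
    """
    extent = volume.shape[axis]
    if not 0 <= plane_index <= extent:
        raise ValueError(f"plane_index {plane_index} outside [0, {extent}]")
    values = volume.values.copy()
    sl = [slice(None)] * 3
    sl[axis] = slice(0, plane_index)
    values[tuple(sl)] = 0
    cls = BinaryVolume if isinstance(volume, BinaryVolume) else ScalarVolume
    return cls(values, volume.spacing, volume.origin)
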