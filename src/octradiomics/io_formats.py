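"""NRRD reading/writing and grayscale collapse of 3-channel scans.

NRRD is the canonical on-disk format for this pipeline (volumes and masks
alike); it carries spacing in the header and no patient metadata.  SimpleITK
does the parsing; this module only enforces the package's contracts on top:
3D payloads, positive header spacing, binarised masks, and the fixed
``(x, y, z)`` axis order documented in :mod:`octradiomics.types`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .types import RoiMask, VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "rgb_to_grayscale",
]


def _read_array(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D payload, got {img.GetDimension()}D")
    spacing = tuple(float(s) for s in img.GetSpacing())
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive spacing in header: {spacing}")
    origin = tuple(float(o) for o in img.GetOrigin())
    # SimpleITK arrays come back (z, y, x); package convention is (x, y, z).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, spacing, origin


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a grayscale volume from NRRD, honouring header spacing."""
    arr, spacing, origin = _read_array(path)
    return VoxelVolume(arr.astype(np.uint8), spacing, origin)


def read_mask(path: str | Path) -> RoiMask:
    """Read a binary mask from NRRD; any nonzero voxel becomes foreground."""
    arr, spacing, origin = _read_array(path)
    return RoiMask(arr != 0, spacing, origin)


def _write(arr: np.ndarray, spacing, origin, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(origin))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path), useCompression=False)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    _write(volume.values.astype(np.uint8), volume.spacing, volume.origin, path)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    _write(mask.values.astype(np.uint8), mask.spacing, mask.origin, path)


def rgb_to_grayscale(values: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel monochromatic scan to one grayscale channel.

    The scanner stores monochromatic data in an RGB container, so the three
    channels should be voxelwise identical; if they are, the first channel is
    returned.  Disagreeing channels signal corrupted data: the rounded
    channel mean is returned and a warning emitted.  A plain 3D array passes
    through unchanged.
    """
    values = np.asarray(values)
    if values.ndim == 3:
        return values
    if values.ndim != 4 or values.shape[-1] != 3:
        raise ValueError(
            f"expected a 3-channel last axis, got shape {values.shape}"
        )
    first = values[..., 0]
    if (values[..., 1] == first).all() and (values[..., 2] == first).all():
        return first
    warnings.warn(
        "RGB channels disagree on a nominally monochromatic scan; "
        "collapsing to the rounded channel mean",
        stacklevel=2,
    )
    return np.rint(values.mean(axis=-1)).astype(values.dtype)
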