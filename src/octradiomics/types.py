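"""In-memory containers for OCT volumes and lesion masks.

Axis convention (the single place it is defined): arrays are indexed
``(x, y, z)`` where x/y span the 6 x 6 mm en-face scan area and z is depth
into the skin.  Voxel indices are 0-based; physical position of voxel
``(i, j, k)`` is ``origin + (i*dx, j*dy, k*dz)`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "RoiMask", "AlignmentError"]


class AlignmentError(ValueError):
    """Raised when a mask and a volume do not share shape/spacing."""


@dataclass
class VoxelVolume:
    """A 3D grayscale OCT volume with physical spacing.

    Intensities are 8-bit gray values in [0, 255] as exported by the
    scanner; spacing is (dx, dy, dz) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        lo, hi = self.values.min(), self.values.max()
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities outside 8-bit range: [{lo}, {hi}]")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class RoiMask:
    """Binary lesion mask aligned with a :class:`VoxelVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        self.values = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def require_alignment(self, volume: VoxelVolume) -> None:
        """Raise :class:`AlignmentError` unless mask and volume align."""
        if self.shape != volume.shape:
            raise AlignmentError(
                f"mask shape {self.shape} != volume shape {volume.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing):
            raise AlignmentError(
                f"mask spacing {self.spacing} != volume spacing {volume.spacing}"
            )

    def require_nonempty(self) -> None:
        if self.voxel_count == 0:
            raise ValueError("ROI mask is empty (no foreground voxels)")
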