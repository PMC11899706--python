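"""Fixed-bin-size (FBS) gray-level discretization of ROI intensities.

All texture features consume integer gray levels produced here.  With bin
width ``BW`` and the ROI minimum as anchor, a voxel of intensity ``x`` maps
to level ``floor((x - min_ROI) / BW) + 1``, so levels run 1..Ng with
``Ng = floor((max_ROI - min_ROI) / BW) + 1``.  Anchoring at the ROI minimum
(rather than a fixed global value) makes the levels invariant to a constant
intensity shift of the whole ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import RoiMask, VoxelVolume

__all__ = ["DEFAULT_BIN_WIDTHS", "QuantizedRoi", "quantize_fbs"]

# Bin-width grid of record: 5..50 in steps of 5.
DEFAULT_BIN_WIDTHS: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass(frozen=True)
class QuantizedRoi:
    """ROI gray levels cropped to the ROI bounding box.

    ``levels`` is an int32 array over the bounding box with level 0 outside
    the ROI and levels 1..``n_levels`` inside.  ``anchor`` is the ROI minimum
    intensity used to anchor the first bin.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float
    anchor: float
    spacing: tuple[float, float, float]

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def roi_levels(self) -> np.ndarray:
        """The 1D array of gray levels of ROI voxels."""
        return self.levels[self.mask]


def _bounding_box(mask: np.ndarray) -> tuple[slice, slice, slice]:
    slices = []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        slices.append(slice(idx[0], idx[-1] + 1))
    return tuple(slices)


def quantize_fbs(volume: VoxelVolume, mask: RoiMask, bin_width: float) -> QuantizedRoi:
    """Discretize the ROI of ``volume`` to integer gray levels.

    Raises ``ValueError`` for an empty ROI or non-positive bin width;
    mask/volume misalignment raises ``AlignmentError``.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    mask.require_alignment(volume)
    mask.require_nonempty()

    box = _bounding_box(mask.values)
    sub_mask = mask.values[box]
    sub_vals = volume.values[box].astype(np.float64)
    roi_vals = sub_vals[sub_mask]
    anchor = float(roi_vals.min())

    levels = np.zeros(sub_mask.shape, dtype=np.int32)
    levels[sub_mask] = np.floor((roi_vals - anchor) / bin_width).astype(np.int32) + 1
    n_levels = int(levels.max())
    return QuantizedRoi(
        levels=levels,
        mask=sub_mask,
        n_levels=n_levels,
        bin_width=float(bin_width),
        anchor=anchor,
        spacing=volume.spacing,
    )
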