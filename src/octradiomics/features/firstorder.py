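"""First-order intensity statistics of the ROI.

Seventeen of the 18 features are computed from the raw gray values; Entropy
and Uniformity are computed from the bin-width-discretized histogram, so they
are the only first-order features that respond to the quantization sweep.
Skewness and Kurtosis use population moments, Kurtosis is non-excess
(a Gaussian scores 3); both are defined as 0 for a constant ROI.
"""

from __future__ import annotations

import numpy as np

from ..quantize import quantize_fbs
from ..types import RoiMask, VoxelVolume

__all__ = ["first_order_features", "FIRST_ORDER_NAMES"]

_EPS = np.spacing(1.0)

FIRST_ORDER_NAMES = (
    "firstorder_10Percentile",
    "firstorder_90Percentile",
    "firstorder_Energy",
    "firstorder_Entropy",
    "firstorder_InterquartileRange",
    "firstorder_Kurtosis",
    "firstorder_Maximum",
    "firstorder_Mean",
    "firstorder_MeanAbsoluteDeviation",
    "firstorder_Median",
    "firstorder_Minimum",
    "firstorder_Range",
    "firstorder_RobustMeanAbsoluteDeviation",
    "firstorder_RootMeanSquared",
    "firstorder_Skewness",
    "firstorder_TotalEnergy",
    "firstorder_Uniformity",
    "firstorder_Variance",
)


def first_order_features(
    volume: VoxelVolume, mask: RoiMask, bin_width: float
) -> dict[str, float]:
    mask.require_alignment(volume)
    mask.require_nonempty()
    x = volume.values[mask.values].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    voxel_vol = float(np.prod(volume.spacing))

    qroi = quantize_fbs(volume, mask, bin_width)
    hist = np.bincount(qroi.roi_levels() - 1, minlength=qroi.n_levels) / n

    f: dict[str, float] = {}
    f["firstorder_10Percentile"] = float(p10)
    f["firstorder_90Percentile"] = float(p90)
    f["firstorder_Energy"] = float((x**2).sum())
    f["firstorder_Entropy"] = float(-(hist * np.log2(hist + _EPS)).sum())
    f["firstorder_InterquartileRange"] = float(p75 - p25)
    f["firstorder_Kurtosis"] = (
        float(((x - mean) ** 4).mean() / m2**2) if m2 > 0 else 0.0
    )
    f["firstorder_Maximum"] = float(x.max())
    f["firstorder_Mean"] = mean
    f["firstorder_MeanAbsoluteDeviation"] = float(np.abs(x - mean).mean())
    f["firstorder_Median"] = float(np.median(x))
    f["firstorder_Minimum"] = float(x.min())
    f["firstorder_Range"] = float(x.max() - x.min())
    f["firstorder_RobustMeanAbsoluteDeviation"] = (
        float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    )
    f["firstorder_RootMeanSquared"] = float(np.sqrt((x**2).mean()))
    f["firstorder_Skewness"] = (
        float(((x - mean) ** 3).mean() / m2**1.5) if m2 > 0 else 0.0
    )
    f["firstorder_TotalEnergy"] = voxel_vol * f["firstorder_Energy"]
    f["firstorder_Uniformity"] = float((hist**2).sum())
    f["firstorder_Variance"] = m2
    return f
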