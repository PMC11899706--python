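"""Handcrafted radiomics feature extraction: 107 features in 7 families.

The default feature set is the field's standard taxonomy: 18 first-order,
14 shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM features, all
computed on the original (unfiltered, unresampled) 3D ROI.  Names are
namespaced ``family_FeatureName``.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable

import pandas as pd

from ..quantize import quantize_fbs
from ..types import RoiMask, VoxelVolume
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "FEATURE_NAMES",
    "FAMILY_COUNTS",
    "extract_feature_vector",
    "extract_feature_table",
    "first_order_features",
    "shape_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

FAMILY_COUNTS = {
    "firstorder": 18,
    "shape": 14,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}


def _feature_names() -> tuple[str, ...]:
    # Build the pinned 107-name list once, in extraction order.
    from .texture import _GLCM_NAMES  # noqa: PLC0415

    names = list(FIRST_ORDER_NAMES) + list(SHAPE_NAMES)
    names += [f"glcm_{n}" for n in _GLCM_NAMES]
    names += [
        "glrlm_GrayLevelNonUniformity",
        "glrlm_GrayLevelNonUniformityNormalized",
        "glrlm_GrayLevelVariance",
        "glrlm_HighGrayLevelRunEmphasis",
        "glrlm_LongRunEmphasis",
        "glrlm_LongRunHighGrayLevelEmphasis",
        "glrlm_LongRunLowGrayLevelEmphasis",
        "glrlm_LowGrayLevelRunEmphasis",
        "glrlm_RunEntropy",
        "glrlm_RunLengthNonUniformity",
        "glrlm_RunLengthNonUniformityNormalized",
        "glrlm_RunPercentage",
        "glrlm_RunVariance",
        "glrlm_ShortRunEmphasis",
        "glrlm_ShortRunHighGrayLevelEmphasis",
        "glrlm_ShortRunLowGrayLevelEmphasis",
        "glszm_GrayLevelNonUniformity",
        "glszm_GrayLevelNonUniformityNormalized",
        "glszm_GrayLevelVariance",
        "glszm_HighGrayLevelZoneEmphasis",
        "glszm_LargeAreaEmphasis",
        "glszm_LargeAreaHighGrayLevelEmphasis",
        "glszm_LargeAreaLowGrayLevelEmphasis",
        "glszm_LowGrayLevelZoneEmphasis",
        "glszm_SizeZoneNonUniformity",
        "glszm_SizeZoneNonUniformityNormalized",
        "glszm_SmallAreaEmphasis",
        "glszm_SmallAreaHighGrayLevelEmphasis",
        "glszm_SmallAreaLowGrayLevelEmphasis",
        "glszm_ZoneEntropy",
        "glszm_ZonePercentage",
        "glszm_ZoneVariance",
        "gldm_DependenceEntropy",
        "gldm_DependenceNonUniformity",
        "gldm_DependenceNonUniformityNormalized",
        "gldm_DependenceVariance",
        "gldm_GrayLevelNonUniformity",
        "gldm_GrayLevelVariance",
        "gldm_HighGrayLevelEmphasis",
        "gldm_LargeDependenceEmphasis",
        "gldm_LargeDependenceHighGrayLevelEmphasis",
        "gldm_LargeDependenceLowGrayLevelEmphasis",
        "gldm_LowGrayLevelEmphasis",
        "gldm_SmallDependenceEmphasis",
        "gldm_SmallDependenceHighGrayLevelEmphasis",
        "gldm_SmallDependenceLowGrayLevelEmphasis",
        "ngtdm_Busyness",
        "ngtdm_Coarseness",
        "ngtdm_Complexity",
        "ngtdm_Contrast",
        "ngtdm_Strength",
    ]
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _feature_names()
assert len(FEATURE_NAMES) == sum(FAMILY_COUNTS.values()) == 107


def extract_feature_vector(
    volume: VoxelVolume, mask: RoiMask, bin_width: float
) -> "OrderedDict[str, float]":
    """Extract all 107 features of one ROI at one bin width.

    Deterministic; raises on empty or degenerate ROIs rather than emitting a
    partial vector.
    """
    qroi = quantize_fbs(volume, mask, bin_width)
    out: OrderedDict[str, float] = OrderedDict()
    out.update(first_order_features(volume, mask, bin_width))
    out.update(shape_features(mask, volume.spacing))
    out.update(glcm_features(qroi))
    out.update(glrlm_features(qroi))
    out.update(glszm_features(qroi))
    out.update(gldm_features(qroi))
    out.update(ngtdm_features(qroi))
    ordered = OrderedDict((name, out[name]) for name in FEATURE_NAMES)
    return ordered


def extract_feature_table(
    scans: Iterable, bin_widths: Iterable[float]
) -> pd.DataFrame:
    """Extract features for many scans over a bin-width grid.

    ``scans`` yields objects with ``scan_id``, ``volume`` and ``mask``
    attributes (the synthetic cohort's ``Scan``).  Returns a long-format
    DataFrame with columns (scan_id, bw, feature, value).
    """
    records = []
    for scan in scans:
        for bw in bin_widths:
            vec = extract_feature_vector(scan.volume, scan.mask, bw)
            records.extend(
                (scan.scan_id, bw, name, value) for name, value in vec.items()
            )
    return pd.DataFrame(records, columns=["scan_id", "bw", "feature", "value"])


def wide_table(long_df: pd.DataFrame, bin_width: float) -> pd.DataFrame:
    """Pivot one bin width of a long feature table to scans x features."""
    sub = long_df[long_df["bw"] == bin_width]
    return sub.pivot(index="scan_id", columns="feature", values="value")
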