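"""Texture feature formulas computed from the gray-level matrices.

Feature definitions follow the IBSI reference formulations as implemented by
the de-facto standard radiomics extraction toolchain (its default feature
set), including that toolchain's degenerate-case conventions:

* GLCM Correlation of a single-level ROI is defined as 1 (perfect
  correlation of a constant), and MCC likewise.
* NGTDM Coarseness of a perfectly flat region (denominator 0) is capped at
  1e6.
* Directional features (GLCM, GLRLM) are computed per direction on the
  normalised matrix and averaged over the directions that contain at least
  one count.

``_EPS`` guards logarithms exactly as the reference toolchain does
(machine epsilon added inside every log2).
"""

from __future__ import annotations

import numpy as np

from ..quantize import QuantizedRoi
from .matrices import (
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_EPS = np.spacing(1.0)

_COARSENESS_CAP = 1e6


# ---------------------------------------------------------------- GLCM ----

_GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)


def _glcm_single(p: np.ndarray, ng: int) -> dict[str, float]:
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    # distributions of i+j (2..2Ng) and |i-j| (0..Ng-1)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    hxy = float(-(p * np.log2(p + _EPS)).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())

    f: dict[str, float] = {}
    f["Autocorrelation"] = float((p * ii * jj).sum())
    cdiff = ii + jj - mu_x - mu_y
    f["ClusterProminence"] = float((p * cdiff**4).sum())
    f["ClusterShade"] = float((p * cdiff**3).sum())
    f["ClusterTendency"] = float((p * cdiff**2).sum())
    f["Contrast"] = float((p * (ii - jj) ** 2).sum())
    if sig_x > 0 and sig_y > 0:
        f["Correlation"] = (f["Autocorrelation"] - mu_x * mu_y) / (sig_x * sig_y)
    else:
        f["Correlation"] = 1.0  # constant ROI: perfect agreement by convention
    da = float((p_diff * k_diff).sum())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = float(-(p_diff * np.log2(p_diff + _EPS)).sum())
    f["DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    f["Id"] = float((p_diff / (1.0 + k_diff)).sum())
    f["Idm"] = float((p_diff / (1.0 + k_diff**2)).sum())
    f["Idmn"] = float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum())
    f["Idn"] = float((p_diff / (1.0 + k_diff / ng)).sum())
    div = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / div if div > 0 else 0.0
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    f["InverseVariance"] = float((p_diff[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else 0.0
    f["JointAverage"] = mu_x
    f["JointEnergy"] = float((p**2).sum())
    f["JointEntropy"] = hxy
    f["MCC"] = _glcm_mcc(p, px, py)
    f["MaximumProbability"] = float(p.max())
    f["SumAverage"] = float((p_sum * k_sum).sum())
    f["SumEntropy"] = float(-(p_sum * np.log2(p_sum + _EPS)).sum())
    f["SumSquares"] = float((p * (ii - mu_x) ** 2).sum())
    return f


def _glcm_mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    present = px > 0
    if present.sum() < 2:
        return 1.0
    pp = p[np.ix_(present, present)]
    pxp = px[present]
    pyp = py[present]
    # Q(i, j) = sum_k p(i, k) p(j, k) / (px(i) py(k))
    q = (pp / pyp[None, :]) @ pp.T / pxp[:, None]
    eig = np.linalg.eigvals(q)
    eig = np.sort(np.abs(eig))
    return float(np.sqrt(max(0.0, eig[-2].real if np.iscomplexobj(eig) else eig[-2])))


def glcm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """The 24 co-occurrence features, averaged over the 13 directions."""
    acc: dict[str, list[float]] = {n: [] for n in _GLCM_NAMES}
    for m in glcm_matrices(qroi):
        total = m.sum()
        if total == 0:
            continue
        vals = _glcm_single(m / total, qroi.n_levels)
        for n in _GLCM_NAMES:
            acc[n].append(vals[n])
    if not acc["Contrast"]:
        raise ValueError("ROI too small for any co-occurring voxel pair")
    return {f"glcm_{n}": float(np.mean(acc[n])) for n in _GLCM_NAMES}


# --------------------------------------------------------------- GLRLM ----

_GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def _weighted_matrix_features(
    m: np.ndarray,
    prefix: str,
    n_voxels: int,
    names_map: dict[str, str],
) -> dict[str, float]:
    """Shared engine for the GLRLM/GLSZM/GLDM families.

    All three are (gray level x size-like index) count matrices whose
    features are ratios of i/j-weighted sums over the total count, plus
    variance/entropy of the normalised matrix.  ``names_map`` maps generic
    keys to the family's feature names (missing keys are skipped).
    """
    n = float(m.sum())
    i = np.arange(1, m.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, m.shape[1] + 1, dtype=np.float64)
    ri = m.sum(axis=1).astype(np.float64)  # per gray level
    rj = m.sum(axis=0).astype(np.float64)  # per size index
    p = m / n
    mu_i = float((ri / n * i).sum())
    mu_j = float((rj / n * j).sum())

    g: dict[str, float] = {}
    g["small"] = float((rj / j**2).sum()) / n
    g["large"] = float((rj * j**2).sum()) / n
    g["low"] = float((ri / i**2).sum()) / n
    g["high"] = float((ri * i**2).sum()) / n
    g["small_low"] = float((m / np.outer(i**2, j**2)).sum()) / n
    g["small_high"] = float(((m * i[:, None] ** 2) / j[None, :] ** 2).sum()) / n
    g["large_low"] = float(((m * j[None, :] ** 2) / i[:, None] ** 2).sum()) / n
    g["large_high"] = float((m * np.outer(i**2, j**2)).sum()) / n
    g["gln"] = float((ri**2).sum()) / n
    g["glnn"] = float((ri**2).sum()) / n**2
    g["sn"] = float((rj**2).sum()) / n
    g["snn"] = float((rj**2).sum()) / n**2
    g["glv"] = float((ri / n * (i - mu_i) ** 2).sum())
    g["sv"] = float((rj / n * (j - mu_j) ** 2).sum())
    g["entropy"] = float(-(p * np.log2(p + _EPS)).sum())
    g["percentage"] = n / n_voxels
    return {
        f"{prefix}_{fname}": g[key] for key, fname in names_map.items()
    }


def glrlm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """The 16 run-length features, averaged over the 13 directions."""
    names_map = {
        "gln": "GrayLevelNonUniformity",
        "glnn": "GrayLevelNonUniformityNormalized",
        "glv": "GrayLevelVariance",
        "high": "HighGrayLevelRunEmphasis",
        "large": "LongRunEmphasis",
        "large_high": "LongRunHighGrayLevelEmphasis",
        "large_low": "LongRunLowGrayLevelEmphasis",
        "low": "LowGrayLevelRunEmphasis",
        "entropy": "RunEntropy",
        "sn": "RunLengthNonUniformity",
        "snn": "RunLengthNonUniformityNormalized",
        "percentage": "RunPercentage",
        "sv": "RunVariance",
        "small": "ShortRunEmphasis",
        "small_high": "ShortRunHighGrayLevelEmphasis",
        "small_low": "ShortRunLowGrayLevelEmphasis",
    }
    n_vox = qroi.voxel_count
    per_dir = [
        _weighted_matrix_features(m, "glrlm", n_vox, names_map)
        for m in glrlm_matrices(qroi)
    ]
    return {
        k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]
    }


# --------------------------------------------------------------- GLSZM ----


def glszm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """The 16 size-zone features (single 26-connected zone matrix)."""
    names_map = {
        "gln": "GrayLevelNonUniformity",
        "glnn": "GrayLevelNonUniformityNormalized",
        "glv": "GrayLevelVariance",
        "high": "HighGrayLevelZoneEmphasis",
        "large": "LargeAreaEmphasis",
        "large_high": "LargeAreaHighGrayLevelEmphasis",
        "large_low": "LargeAreaLowGrayLevelEmphasis",
        "low": "LowGrayLevelZoneEmphasis",
        "sn": "SizeZoneNonUniformity",
        "snn": "SizeZoneNonUniformityNormalized",
        "small": "SmallAreaEmphasis",
        "small_high": "SmallAreaHighGrayLevelEmphasis",
        "small_low": "SmallAreaLowGrayLevelEmphasis",
        "entropy": "ZoneEntropy",
        "percentage": "ZonePercentage",
        "sv": "ZoneVariance",
    }
    m = glszm_matrix(qroi)
    return _weighted_matrix_features(m, "glszm", qroi.voxel_count, names_map)


# ---------------------------------------------------------------- GLDM ----


def gldm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """The 14 dependence features (alpha = 0, 26-neighbourhood)."""
    names_map = {
        "entropy": "DependenceEntropy",
        "sn": "DependenceNonUniformity",
        "snn": "DependenceNonUniformityNormalized",
        "sv": "DependenceVariance",
        "gln": "GrayLevelNonUniformity",
        "glv": "GrayLevelVariance",
        "high": "HighGrayLevelEmphasis",
        "large": "LargeDependenceEmphasis",
        "large_high": "LargeDependenceHighGrayLevelEmphasis",
        "large_low": "LargeDependenceLowGrayLevelEmphasis",
        "low": "LowGrayLevelEmphasis",
        "small": "SmallDependenceEmphasis",
        "small_high": "SmallDependenceHighGrayLevelEmphasis",
        "small_low": "SmallDependenceLowGrayLevelEmphasis",
    }
    m = gldm_matrix(qroi)
    return _weighted_matrix_features(m, "gldm", qroi.voxel_count, names_map)


# --------------------------------------------------------------- NGTDM ----


def ngtdm_features(qroi: QuantizedRoi) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength."""
    table = ngtdm_table(qroi)
    n_i = table[:, 0]
    s_i = table[:, 1]
    n_vp = n_i.sum()
    if n_vp == 0:
        raise ValueError("no ROI voxel has an in-ROI neighbour")
    p_i = n_i / n_vp
    i = np.arange(1, table.shape[0] + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())

    f: dict[str, float] = {}
    denom = float((p_i * s_i).sum())
    f["ngtdm_Coarseness"] = 1.0 / denom if denom > 0 else _COARSENESS_CAP

    if ngp > 1:
        pi_p, ii_p, si_p = p_i[present], i[present], s_i[present]
        contrast = float(
            (pi_p[:, None] * pi_p[None, :] * (ii_p[:, None] - ii_p[None, :]) ** 2).sum()
        ) / (ngp * (ngp - 1))
        f["ngtdm_Contrast"] = contrast * float(s_i.sum()) / n_vp
        ipi = ii_p * pi_p
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        f["ngtdm_Busyness"] = denom / busy_den if busy_den > 0 else 0.0
        pair_sum = pi_p[:, None] + pi_p[None, :]
        adiff = np.abs(ii_p[:, None] - ii_p[None, :])
        num = (pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :])
        f["ngtdm_Complexity"] = float((adiff * num / pair_sum).sum()) / n_vp
        s_tot = float(s_i.sum())
        f["ngtdm_Strength"] = (
            float((pair_sum * adiff**2).sum()) / s_tot if s_tot > 0 else 0.0
        )
    else:
        f["ngtdm_Contrast"] = 0.0
        f["ngtdm_Busyness"] = 0.0
        f["ngtdm_Complexity"] = 0.0
        f["ngtdm_Strength"] = 0.0
    return f
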