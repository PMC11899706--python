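"""Construction of the five gray-level texture matrices from a quantized ROI.

All matrices use distance-1 neighbourhoods on the voxel grid.  GLCM and GLRLM
are directional over the 13 unique 3D offsets (one per axis pair, diagonals
included); GLSZM zones and GLDM/NGTDM neighbourhoods use full 26-connectivity.
Matrices hold raw integer counts; normalisation happens in the feature
formulas.

Conservation laws (exercised by the test suite against brute-force
enumerators):

* GLCM: each directional matrix is symmetric.
* GLRLM: sum_ij j * R(i, j) equals the ROI voxel count, per direction.
* GLSZM: zone sizes sum to the ROI voxel count.
* GLDM: matrix entries sum to the ROI voxel count.
* NGTDM: sum_i n_i equals the count of ROI voxels with >= 1 ROI neighbour.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..quantize import QuantizedRoi

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]

# The 13 unique direction vectors of the 26-neighbourhood (one of each +/- pair,
# chosen so the first nonzero component is positive).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_ALL_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def _offset_views(arr: np.ndarray, offset: tuple[int, int, int]):
    """Pair of equally-shaped views of ``arr``: centre voxels and their
    neighbours at ``offset`` (views shrink at the boundary)."""
    centre, neigh = [], []
    for n, d in zip(arr.shape, offset):
        if d == 0:
            centre.append(slice(None))
            neigh.append(slice(None))
        elif d > 0:
            centre.append(slice(0, n - d))
            neigh.append(slice(d, n))
        else:
            centre.append(slice(-d, n))
            neigh.append(slice(0, n + d))
    return arr[tuple(centre)], arr[tuple(neigh)]


def glcm_matrices(qroi: QuantizedRoi) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one (Ng x Ng) per direction.

    Directions with no in-ROI voxel pair yield an all-zero matrix.
    """
    ng = qroi.n_levels
    lev = qroi.levels
    out = []
    for off in DIRECTIONS_13:
        a, b = _offset_views(lev, off)
        valid = (a > 0) & (b > 0)
        ai, bi = a[valid], b[valid]
        m = np.bincount(
            (ai - 1) * ng + (bi - 1), minlength=ng * ng
        ).reshape(ng, ng)
        out.append(m + m.T)  # symmetric: count both voxel orders
    return out


def glrlm_matrices(qroi: QuantizedRoi) -> list[np.ndarray]:
    """Run-length count matrices R(level, run_length), one per direction.

    A run is a maximal set of collinear, consecutive ROI voxels sharing one
    gray level; non-ROI voxels break runs.  Column ``j`` (1-based) is the run
    length; the matrix has ``max_run`` columns.
    """
    lev = qroi.levels
    shape = lev.shape
    ng = qroi.n_levels
    flat = lev.ravel()
    coords = np.indices(shape).reshape(3, -1)
    out = []
    for off in DIRECTIONS_13:
        # Distance (in steps of -off) from each voxel back to its line's
        # first in-grid voxel; voxels on one line share that anchor voxel.
        steps = np.full(flat.shape, np.iinfo(np.int64).max, dtype=np.int64)
        for axis, d in enumerate(off):
            if d > 0:
                steps = np.minimum(steps, coords[axis])
            elif d < 0:
                steps = np.minimum(steps, shape[axis] - 1 - coords[axis])
        anchor = coords - np.asarray(off)[:, None] * steps
        anchor_id = np.ravel_multi_index(tuple(anchor), shape)
        order = np.lexsort((steps, anchor_id))
        s_lev = flat[order]
        s_anchor = anchor_id[order]
        new_run = np.ones(s_lev.size, dtype=bool)
        new_run[1:] = (s_anchor[1:] != s_anchor[:-1]) | (s_lev[1:] != s_lev[:-1])
        run_id = np.cumsum(new_run) - 1
        run_len = np.bincount(run_id)
        run_lev = s_lev[new_run]
        keep = run_lev > 0
        run_lev, run_len = run_lev[keep], run_len[keep]
        max_len = int(run_len.max()) if run_len.size else 1
        m = np.zeros((ng, max_len), dtype=np.int64)
        np.add.at(m, (run_lev - 1, run_len - 1), 1)
        out.append(m)
    return out


def glszm_matrix(qroi: QuantizedRoi) -> np.ndarray:
    """Size-zone count matrix Z(level, zone_size) over 26-connected zones."""
    lev = qroi.levels
    ng = qroi.n_levels
    structure = np.ones((3, 3, 3), dtype=bool)
    pairs = []  # (level, size)
    max_size = 1
    for g in np.unique(lev[qroi.mask]):
        labels, n = ndimage.label(lev == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels.ravel())[1:]
        max_size = max(max_size, int(sizes.max()))
        pairs.append((int(g), sizes))
    m = np.zeros((ng, max_size), dtype=np.int64)
    for g, sizes in pairs:
        np.add.at(m, (g - 1, sizes - 1), 1)
    return m


def _neighbour_stats(qroi: QuantizedRoi):
    """Per-voxel 26-neighbourhood tallies over ROI voxels: number of ROI
    neighbours, number of ROI neighbours with the same level, and the sum of
    neighbour levels."""
    lev = qroi.levels
    pad = np.pad(lev, 1)
    core = (slice(1, -1),) * 3
    n_roi = np.zeros(lev.shape, dtype=np.int64)
    n_same = np.zeros(lev.shape, dtype=np.int64)
    lev_sum = np.zeros(lev.shape, dtype=np.int64)
    for off in _ALL_26:
        sl = tuple(slice(1 + d, pad.shape[i] - 1 + d) for i, d in enumerate(off))
        neigh = pad[sl]
        in_roi = neigh > 0
        n_roi += in_roi
        n_same += in_roi & (neigh == lev)
        lev_sum += neigh  # non-ROI neighbours contribute 0
    del core
    return n_roi, n_same, lev_sum


def gldm_matrix(qroi: QuantizedRoi) -> np.ndarray:
    """Dependence count matrix D(level, dependence_size) with alpha = 0.

    A 26-neighbour is dependent when its level equals the centre's; the
    dependence size of a voxel is 1 + its number of dependent neighbours, so
    every ROI voxel contributes exactly one count.
    """
    _, n_same, _ = _neighbour_stats(qroi)
    lev = qroi.levels
    roi = qroi.mask
    dep = n_same[roi] + 1
    g = lev[roi]
    ng = qroi.n_levels
    max_dep = int(dep.max())
    m = np.zeros((ng, max_dep), dtype=np.int64)
    np.add.at(m, (g - 1, dep - 1), 1)
    return m


def ngtdm_table(qroi: QuantizedRoi) -> np.ndarray:
    """Neighbourhood gray-tone difference table, rows = levels 1..Ng.

    Column 0: n_i, the count of ROI voxels of level i with >= 1 ROI
    neighbour.  Column 1: s_i, the summed absolute difference between i and
    the mean level of each such voxel's ROI neighbours.
    """
    n_roi, _, lev_sum = _neighbour_stats(qroi)
    lev = qroi.levels
    valid = qroi.mask & (n_roi > 0)
    g = lev[valid]
    mean_neigh = lev_sum[valid] / n_roi[valid]
    diff = np.abs(g - mean_neigh)
    ng = qroi.n_levels
    table = np.zeros((ng, 2))
    table[:, 0] = np.bincount(g - 1, minlength=ng)
    table[:, 1] = np.bincount(g - 1, weights=diff, minlength=ng)
    return table
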