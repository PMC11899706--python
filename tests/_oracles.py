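"""Independent brute-force enumerators used as oracles by the test suite.

Everything here is deliberately naive (pure-Python loops, BFS flood fill,
line walking) and shares no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

ALL_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


def glcm_oracle(levels: np.ndarray, direction) -> np.ndarray:
    """Symmetric pair counts by exhaustive voxel-pair enumeration."""
    ng = int(levels.max())
    m = np.zeros((ng, ng), dtype=np.int64)
    for p in np.argwhere(levels > 0):
        q = tuple(p + direction)
        if _in(levels.shape, q) and levels[q] > 0:
            a, b = levels[tuple(p)], levels[q]
            m[a - 1, b - 1] += 1
            m[b - 1, a - 1] += 1
    return m


def glrlm_oracle(levels: np.ndarray, direction) -> dict[tuple[int, int], int]:
    """Run counts {(level, length): n} by walking every line voxel by voxel."""
    d = np.asarray(direction)
    runs: dict[tuple[int, int], int] = {}
    for start in np.argwhere(np.ones_like(levels, dtype=bool)):
        if _in(levels.shape, start - d):
            continue  # not a line start
        line = []
        p = start.copy()
        while _in(levels.shape, p):
            line.append(int(levels[tuple(p)]))
            p = p + d
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            if line[i] > 0:
                key = (line[i], j - i)
                runs[key] = runs.get(key, 0) + 1
            i = j
    return runs


def glszm_oracle(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Zone counts {(level, size): n} by BFS flood fill, 26-connected."""
    seen = np.zeros_like(levels, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for start in np.argwhere(levels > 0):
        start = tuple(start)
        if seen[start]:
            continue
        g = int(levels[start])
        size = 0
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            size += 1
            for off in ALL_26:
                q = tuple(np.add(p, off))
                if _in(levels.shape, q) and not seen[q] and levels[q] == g:
                    seen[q] = True
                    queue.append(q)
        zones[(g, size)] = zones.get((g, size), 0) + 1
    return zones


def gldm_oracle(levels: np.ndarray) -> dict[tuple[int, int], int]:
    """Dependence counts {(level, 1 + n_equal_neighbours): n}."""
    out: dict[tuple[int, int], int] = {}
    for p in np.argwhere(levels > 0):
        g = int(levels[tuple(p)])
        dep = 1
        for off in ALL_26:
            q = tuple(p + off)
            if _in(levels.shape, q) and levels[q] == g:
                dep += 1
        out[(g, dep)] = out.get((g, dep), 0) + 1
    return out


def ngtdm_oracle(levels: np.ndarray) -> dict[int, tuple[int, float]]:
    """Per-level (n_i, s_i) by per-voxel neighbour-mean computation."""
    out: dict[int, tuple[int, float]] = {}
    for p in np.argwhere(levels > 0):
        g = int(levels[tuple(p)])
        neigh = []
        for off in ALL_26:
            q = tuple(p + off)
            if _in(levels.shape, q) and levels[q] > 0:
                neigh.append(int(levels[q]))
        if not neigh:
            continue
        n, s = out.get(g, (0, 0.0))
        out[g] = (n + 1, s + abs(g - sum(neigh) / len(neigh)))
    return out


def ccc_oracle(x, y) -> float:
    """Lin's concordance by direct moment sums (math.fsum accumulation)."""
    n = len(x)
    m1 = math.fsum(x) / n
    m2 = math.fsum(y) / n
    v1 = math.fsum((a - m1) ** 2 for a in x) / n
    v2 = math.fsum((b - m2) ** 2 for b in y) / n
    cov = math.fsum((a - m1) * (b - m2) for a, b in zip(x, y)) / n
    denom = v1 + v2 + (m1 - m2) ** 2
    if denom == 0:
        return float("nan")
    return 2.0 * cov / denom


def histogram_entropy_oracle(values, bin_width) -> float:
    """First-order histogram entropy by explicit bin counting."""
    lo = min(values)
    counts: dict[int, int] = {}
    for v in values:
        b = int((v - lo) // bin_width)
        counts[b] = counts.get(b, 0) + 1
    n = len(values)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def random_tiny_levels(rng: np.random.Generator, max_side=5, max_level=4) -> np.ndarray:
    """A random tiny quantized ROI: levels 0 (background) .. max_level."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(0, max_level + 1, size=shape)
    if (levels > 0).sum() == 0:
        levels.flat[rng.integers(levels.size)] = 1
    return levels.astype(np.int32)
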