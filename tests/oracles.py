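"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (pure-Python loops, exhaustive
enumeration) and shares no code with the package implementation it checks.
Only usable on tiny grids.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_boundary_distance(grid: np.ndarray, spacing) -> np.ndarray:
    """All-pairs nearest-background distance, with background outside the grid."""
    padded = np.pad(grid, 1, constant_values=False)
    fg = np.argwhere(padded)
    bg = np.argwhere(~padded)
    sp = np.asarray(spacing, dtype=float)
    d = cdist(fg * sp, bg * sp).min(axis=1)
    out = np.zeros(padded.shape)
    out[tuple(fg.T)] = d
    return out[1:-1, 1:-1, 1:-1]


def brute_force_core(grid: np.ndarray, spacing, fraction: float) -> np.ndarray:
    """Sort all foreground voxels by exhaustively computed depth, take the top
    fraction (ties broken lexicographically by (z, y, x))."""
    dist = brute_force_boundary_distance(grid, spacing)
    voxels = [tuple(v) for v in np.argwhere(grid)]
    voxels.sort(key=lambda v: (-dist[v], v))
    n = int(round(fraction * len(voxels)))
    out = np.zeros_like(grid)
    for v in voxels[:n]:
        out[v] = True
    return out


def _in_bounds(v, shape) -> bool:
    return all(0 <= c < s for c, s in zip(v, shape))


def brute_force_glcm(levels: np.ndarray, ng: int, offset) -> np.ndarray:
    """Symmetrised co-occurrence counts by exhaustive ordered-pair enumeration."""
    m = np.zeros((ng, ng))
    shape = levels.shape
    for v in np.argwhere(levels > 0):
        for sign in (1, -1):
            w = tuple(v[k] + sign * offset[k] for k in range(3))
            if _in_bounds(w, shape) and levels[w] > 0:
                m[levels[tuple(v)] - 1, levels[w] - 1] += 1
    return m


def brute_force_glrlm(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Run-length counts by explicitly tracing each run."""
    shape = levels.shape
    max_len = max(shape)
    m = np.zeros((ng, max_len))
    for v in np.argwhere(levels > 0):
        v = tuple(v)
        prev = tuple(v[k] - direction[k] for k in range(3))
        if _in_bounds(prev, shape) and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[k] + direction[k] for k in range(3))
            if _in_bounds(nxt, shape) and levels[nxt] == levels[v]:
                length += 1
                cur = nxt
            else:
                break
        m[levels[v] - 1, length - 1] += 1
    return m


_NEIGHBOURS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def brute_force_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Zone sizes via flood fill (26-connectivity) per grey level."""
    shape = levels.shape
    max_size = int((levels > 0).sum())
    m = np.zeros((ng, max_size))
    seen = np.zeros(shape, dtype=bool)
    for v in np.argwhere(levels > 0):
        v = tuple(v)
        if seen[v]:
            continue
        g = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in _NEIGHBOURS_26:
                w = tuple(cur[k] + d[k] for k in range(3))
                if _in_bounds(w, shape) and not seen[w] and levels[w] == g:
                    seen[w] = True
                    stack.append(w)
        m[g - 1, size - 1] += 1
    return m


def brute_force_gldm(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts: size = 1 + matching neighbours within tolerance."""
    shape = levels.shape
    m = np.zeros((ng, 27))
    for v in np.argwhere(levels > 0):
        v = tuple(v)
        dep = 0
        for d in _NEIGHBOURS_26:
            w = tuple(v[k] + d[k] for k in range(3))
            if _in_bounds(w, shape) and levels[w] > 0 and abs(int(levels[w]) - int(levels[v])) <= alpha:
                dep += 1
        m[levels[v] - 1, dep] += 1  # column dep <-> size dep+1
    return m


def brute_force_ngtdm(levels: np.ndarray, ng: int):
    """Per-level counts and summed absolute differences to the neighbour mean."""
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for v in np.argwhere(levels > 0):
        v = tuple(v)
        nb = [
            levels[tuple(v[k] + d[k] for k in range(3))]
            for d in _NEIGHBOURS_26
            if _in_bounds(tuple(v[k] + d[k] for k in range(3)), shape)
            and levels[tuple(v[k] + d[k] for k in range(3))] > 0
        ]
        n[levels[v] - 1] += 1
        if nb:
            s[levels[v] - 1] += abs(float(levels[v]) - float(np.mean(nb)))
    return n, s
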