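"""Independent brute-force oracles for texture matrices and box counting.

Pure-python enumerations, deliberately naive: every pixel pair, run and
zone is found by explicit iteration so the vectorized builders in the
package can be checked against them on small grids.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {
    "0": (0, 1),
    "45": (-1, 1),
    "90": (-1, 0),
    "135": (-1, -1),
}


def glcm_brute(levels: np.ndarray, n_levels: int, offset, distance: int = 1):
    """Symmetric co-occurrence counts by scanning every pixel."""
    h, w = levels.shape
    dr, dc = offset[0] * distance, offset[1] * distance
    p = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0:
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and levels[r2, c2] != 0:
                i, j = levels[r, c] - 1, levels[r2, c2] - 1
                p[i, j] += 1
                p[j, i] += 1
    return p


def _lines(levels: np.ndarray, direction: str):
    h, w = levels.shape
    if direction == "0":
        return [[(r, c) for c in range(w)] for r in range(h)]
    if direction == "90":
        return [[(r, c) for r in range(h)] for c in range(w)]
    if direction == "135":  # parallel to (1, 1)
        out = []
        for s in range(-(h - 1), w):
            line = [(r, r + s) for r in range(h) if 0 <= r + s < w]
            out.append(line)
        return out
    # 45: parallel to (-1, 1) == (1, -1)
    out = []
    for s in range(h + w - 1):
        line = [(r, s - r) for r in range(h) if 0 <= s - r < w]
        out.append(line)
    return out


def glrlm_brute(levels: np.ndarray, n_levels: int, direction: str):
    """Run-length counts by explicit scanning of each line."""
    runs = []
    for line in _lines(levels, direction):
        prev = 0
        length = 0
        for r, c in line:
            v = levels[r, c]
            if v == prev and v != 0:
                length += 1
            else:
                if prev != 0:
                    runs.append((prev, length))
                prev, length = v, 1
        if prev != 0:
            runs.append((prev, length))
    lmax = max((l for _, l in runs), default=1)
    mat = np.zeros((n_levels, lmax))
    for v, l in runs:
        mat[v - 1, l - 1] += 1
    return mat


def glszm_brute(levels: np.ndarray, n_levels: int):
    """Size-zone counts by explicit 4-connected flood fill."""
    h, w = levels.shape
    seen = np.zeros_like(levels, dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            g = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    r2, c2 = rr + dr, cc + dc
                    if 0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2] and levels[r2, c2] == g:
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            zones.append((g, size))
    zmax = max((s for _, s in zones), default=1)
    mat = np.zeros((n_levels, zmax))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def box_count_brute(binary: np.ndarray, size: int) -> int:
    """Occupied boxes of one size on the grid anchored at (0, 0)."""
    h, w = binary.shape
    count = 0
    for r0 in range(0, h, size):
        for c0 in range(0, w, size):
            if binary[r0 : r0 + size, c0 : c0 + size].any():
                count += 1
    return count
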