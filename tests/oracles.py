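"""Independent brute-force oracles used only by tests.

Everything here is deliberately naive (python loops, flood fill, explicit
tallies) and shares no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OUTSIDE = -1


def flood_fill_patches(codes: np.ndarray, cls: int, connectivity: int = 8):
    """List of patches (sets of (row, col)) of value ``cls`` via BFS."""
    nrows, ncols = codes.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    patches = []
    for r in range(nrows):
        for c in range(ncols):
            if codes[r, c] != cls or (r, c) in seen:
                continue
            stack = [(r, c)]
            seen.add((r, c))
            patch = set()
            while stack:
                rr, cc = stack.pop()
                patch.add((rr, cc))
                for dr, dc in nbrs:
                    nr, nc = rr + dr, cc + dc
                    if (
                        0 <= nr < nrows
                        and 0 <= nc < ncols
                        and codes[nr, nc] == cls
                        and (nr, nc) not in seen
                    ):
                        seen.add((nr, nc))
                        stack.append((nr, nc))
            patches.append(patch)
    return patches


def patch_perimeter_sides(codes: np.ndarray, patch, count_boundary: bool = True) -> int:
    """Pixel sides of ``patch`` cells facing a different value (or the map or
    buffer edge when ``count_boundary``)."""
    nrows, ncols = codes.shape
    sides = 0
    for r, c in patch:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols) or codes[nr, nc] == OUTSIDE:
                sides += 1 if count_boundary else 0
            elif codes[nr, nc] != codes[r, c]:
                sides += 1
    return sides


def clumpy_oracle(codes: np.ndarray, cls: int, background: int = 0) -> float:
    """Direct adjacency-tally CLUMPY over in-buffer non-background pixels."""
    nrows, ncols = codes.shape
    land = lambda r, c: codes[r, c] != OUTSIDE and codes[r, c] != background
    n_cls = sum(
        1 for r in range(nrows) for c in range(ncols) if codes[r, c] == cls
    )
    n_land = sum(1 for r in range(nrows) for c in range(ncols) if land(r, c))
    if n_cls == 0:
        return math.nan
    if n_cls == n_land:
        return 1.0
    like = 0
    total = 0
    for r in range(nrows):
        for c in range(ncols):
            if not land(r, c):
                continue
            for dr, dc in ((1, 0), (0, 1)):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols) or not land(nr, nc):
                    continue
                a, b = codes[r, c], codes[nr, nc]
                if a == cls and b == cls:
                    like += 2
                    total += 2
                elif a == cls or b == cls:
                    total += 1
    if total == 0:
        return math.nan
    G = like / total
    P = n_cls / n_land
    return (G - P) / (1 - P) if G >= P else (G - P) / P


def prox_oracle(
    codes: np.ndarray, cls: int, resolution: float, search_radius: float,
    connectivity: int = 8,
) -> float:
    """Median proximity index from first principles (pairwise min center
    distances between flood-fill patches)."""
    patches = flood_fill_patches(codes, cls, connectivity)
    if not patches:
        return math.nan
    if len(patches) == 1:
        return 0.0
    centers = [
        [((c + 0.5) * resolution, (codes.shape[0] - r - 0.5) * resolution) for r, c in p]
        for p in patches
    ]
    areas = [len(p) * resolution**2 for p in patches]
    prox = []
    for i in range(len(patches)):
        s = 0.0
        for j in range(len(patches)):
            if j == i:
                continue
            d = min(
                math.hypot(x1 - x2, y1 - y2)
                for x1, y1 in centers[i]
                for x2, y2 in centers[j]
            )
            if d <= search_radius:
                s += areas[j] / d**2
        prox.append(s)
    return float(np.median(prox))


def composition_oracle(codes: np.ndarray, background: int = 0):
    """(per-class pixel counts, landscape pixel total) via explicit loops."""
    counts: dict[int, int] = {}
    n_land = 0
    for v in codes.ravel():
        v = int(v)
        if v == OUTSIDE or v == background:
            continue
        n_land += 1
        counts[v] = counts.get(v, 0) + 1
    return counts, n_land


def sidi_oracle(codes: np.ndarray, background: int = 0) -> float:
    counts, n_land = composition_oracle(codes, background)
    return 1.0 - sum((c / n_land) ** 2 for c in counts.values())
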