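"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the slowest, most literal formulation of each
operation so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def otsu_brute_force(image: np.ndarray) -> int:
    """Smallest threshold maximizing between-class variance, by explicit
    scan over every split of the 256-bin histogram."""
    hist = np.bincount(np.asarray(image, dtype=np.uint8).ravel(), minlength=256)
    total = hist.sum()
    levels = np.arange(256)
    best_t, best_v = None, -1.0
    for t in range(255):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (levels[: t + 1] * hist[: t + 1]).sum() / w0
        m1 = (levels[t + 1 :] * hist[t + 1 :]).sum() / w1
        v = (w0 / total) * (w1 / total) * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def fill_holes_flood(mask: np.ndarray) -> np.ndarray:
    """Hole filling by explicit 4-connected flood fill of the background
    from the border: anything the flood cannot reach becomes foreground."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    reach = np.zeros_like(m)
    stack = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if (r in (0, h - 1) or c in (0, w - 1)) and not m[r, c]
    ]
    for r, c in stack:
        reach[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < h and 0 <= cc < w and not m[rr, cc] and not reach[rr, cc]:
                reach[rr, cc] = True
                stack.append((rr, cc))
    return m | ~reach


def count_components_union_find(mask: np.ndarray) -> int:
    """8-connected component count by union-find over pixel pairs."""
    m = np.asarray(mask, dtype=bool)
    idx = {tuple(p): i for i, p in enumerate(np.argwhere(m))}
    parent = list(range(len(idx)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for (r, c), i in idx.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) != (0, 0) and (r + dr, c + dc) in idx:
                    union(i, idx[(r + dr, c + dc)])
    return len({find(i) for i in range(len(idx))})


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 straight from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    sstot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sstot if sstot > 0 else 1.0
    return slope, intercept, r2


def random_blob_mask(rng: np.random.Generator, shape=(40, 40), n_blobs=4) -> np.ndarray:
    """A random mask of overlapping rectangles and holes, for property tests."""
    m = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        r0, c0 = rng.integers(0, shape[0] - 8), rng.integers(0, shape[1] - 8)
        h, w = rng.integers(4, 12), rng.integers(4, 12)
        m[r0 : r0 + h, c0 : c0 + w] = True
    for _ in range(n_blobs):
        r0, c0 = rng.integers(1, shape[0] - 4), rng.integers(1, shape[1] - 4)
        m[r0 : r0 + 2, c0 : c0 + 2] = False
    return m
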