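"""Independent brute-force oracles the tests check the implementation against.

These deliberately mirror the written definitions with explicit per-pixel
loops and stay independent of the vectorized production code paths.
"""

from __future__ import annotations

import numpy as np


def loop_gradients(a: np.ndarray, b: np.ndarray):
    """Per-pixel double-loop evaluation of the 2x2x2 gradient kernels.

    Neighbors past the frame edge are taken from the replicated pad, i.e.
    clamped to the last row/column.
    """
    h, w = a.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    gt = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            x1 = min(x + 1, w - 1)
            y1 = min(y + 1, h - 1)
            gt[y, x] = 0.5 * ((b[y, x] - a[y, x]) + (b[y, x1] - a[y, x1]))
            gx[y, x] = 0.5 * ((b[y, x1] - b[y, x]) + (a[y, x1] - a[y, x]))
            gy[y, x] = 0.5 * ((b[y1, x] - b[y, x]) + (a[y1, x] - a[y, x]))
    return gx, gy, gt


def loop_hs(gx, gy, gt, alpha2: float, n_iters: int):
    """Scalar-loop relaxation: u <- u - gx*D, v <- v - gy*D, from u=v=0."""
    h, w = gx.shape
    u = np.zeros((h, w))
    v = np.zeros((h, w))
    for _ in range(n_iters):
        for y in range(h):
            for x in range(w):
                d = (gx[y, x] * u[y, x] + gy[y, x] * v[y, x] + gt[y, x]) / (
                    alpha2 + gx[y, x] ** 2 + gy[y, x] ** 2
                )
                u[y, x] = u[y, x] - gx[y, x] * d
                v[y, x] = v[y, x] - gy[y, x] * d
    return u, v


def flood_count(mask: np.ndarray, connectivity: int, min_area: int = 1) -> int:
    """Brute-force flood-fill component count with a size filter."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    h, w = mask.shape
    count = 0
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                stack = [(sy, sx)]
                seen[sy, sx] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                if size >= min_area:
                    count += 1
    return count
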