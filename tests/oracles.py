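"""Independent brute-force oracles used to validate the fast implementations.

Each function here recomputes a quantity from its definition with naive
loops (or closed-form scalar math), deliberately sharing no code with the
package's vectorized paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- colorimetry
def cie_luv_scalar(r8: int, g8: int, b8: int) -> tuple[float, float, float]:
    """Scalar sRGB -> XYZ -> L*u*v* per the CIE definitions."""

    def lin(c: float) -> float:
        c = c / 255.0
        return c / 12.92 if c <= 0.04045 else ((c + 0.055) / 1.055) ** 2.4

    m = [
        (0.4124564, 0.3575761, 0.1804375),
        (0.2126729, 0.7151522, 0.0721750),
        (0.0193339, 0.1191920, 0.9503041),
    ]
    rl, gl, bl = lin(r8), lin(g8), lin(b8)
    x, y, z = (row[0] * rl + row[1] * gl + row[2] * bl for row in m)
    xn, yn, zn = (sum(row) for row in m)  # matrix white
    eps = (6.0 / 29.0) ** 3
    yr = y / yn
    L = 116.0 * yr ** (1.0 / 3.0) - 16.0 if yr > eps else (29.0 / 3.0) ** 3 * yr
    dn = xn + 15.0 * yn + 3.0 * zn
    un, vn = 4.0 * xn / dn, 9.0 * yn / dn
    d = x + 15.0 * y + 3.0 * z
    if d <= 0:
        return L, 0.0, 0.0
    up, vp = 4.0 * x / d, 9.0 * y / d
    return L, 13.0 * L * (up - un), 13.0 * L * (vp - vn)


# ------------------------------------------------------------------ filtering
def brute_median(image: np.ndarray, window: int) -> np.ndarray:
    """Windowed median with edge replication by explicit sorting."""
    half = window // 2
    padded = np.pad(image, half, mode="edge")
    out = np.empty_like(image)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            patch = padded[r : r + window, c : c + window]
            out[r, c] = np.median(patch)
    return out


def brute_bilinear(image: np.ndarray, target: int) -> np.ndarray:
    """Direct bilinear interpolation, pixel-center convention, edge clamp."""
    src = image.astype(np.float64)
    n = src.shape[0]
    scale = target / n
    out = np.empty((target, target))
    for i in range(target):
        for j in range(target):
            y = (i + 0.5) / scale - 0.5
            x = (j + 0.5) / scale - 0.5
            y0, x0 = math.floor(y), math.floor(x)
            fy, fx = y - y0, x - x0

            def at(r: int, c: int) -> float:
                return src[min(max(r, 0), n - 1), min(max(c, 0), n - 1)]

            out[i, j] = (
                at(y0, x0) * (1 - fy) * (1 - fx)
                + at(y0 + 1, x0) * fy * (1 - fx)
                + at(y0, x0 + 1) * (1 - fy) * fx
                + at(y0 + 1, x0 + 1) * fy * fx
            )
    return out


# ------------------------------------------------------------------- box scan
def brute_box_scan(
    L: np.ndarray, domain: np.ndarray, side: int, ref: float | None
) -> tuple[int, int] | None:
    """First row-major position maximizing the box score over full placements."""
    best, best_pos = -np.inf, None
    area = side * side
    for top in range(L.shape[0] - side + 1):
        for left in range(L.shape[1] - side + 1):
            if not domain[top : top + side, left : left + side].all():
                continue
            m = L[top : top + side, left : left + side].sum() / area
            s = m if ref is None else abs(m - ref)
            if s > best:
                best, best_pos = s, (top, left)
    return best_pos


# ----------------------------------------------------------------- morphology
def disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2


def brute_morph(mask: np.ndarray, radius: int, op: str) -> np.ndarray:
    """Min/max filter over the disk footprint; outside the image is background."""
    fp = disk_footprint(radius)
    offs = np.argwhere(fp) - radius
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            vals = []
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                vals.append(
                    mask[rr, cc] if 0 <= rr < h and 0 <= cc < w else False
                )
            out[r, c] = all(vals) if op == "erode" else any(vals)
    if op == "open":
        return brute_morph(brute_morph(mask, radius, "erode"), radius, "dilate")
    return out


# -------------------------------------------------------------------- contours
def brute_min_dists(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.array(
        [min(np.linalg.norm(pi - qj) for qj in q) for pi in p]
    )


def brute_hausdorff(p: np.ndarray, q: np.ndarray) -> float:
    return max(brute_min_dists(p, q).max(), brute_min_dists(q, p).max())


# --------------------------------------------------------------- region score
def brute_region_scores(
    mask: np.ndarray, center: tuple[float, float], sigma_px: float
) -> list[tuple[int, float]]:
    """(pixel_count, score) per 8-connected region, by flood fill + scalar sums."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    results = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, pixels = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                pixels.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            pixels.sort()  # row-major, matching the implementation's ordering
            fs = np.array(
                [
                    np.exp(
                        -(
                            (r - center[0]) ** 2 / (2 * sigma_px**2)
                            + (c - center[1]) ** 2 / (2 * sigma_px**2)
                        )
                    )
                    for r, c in pixels
                ]
            )
            results.append((len(pixels), float(fs.sum())))
    return results


# ------------------------------------------------------------- 1-D clustering
def brute_kpartition(values: np.ndarray, k: int) -> float:
    """Minimal within-cluster SSE over all ordered k-partitions (sorted data)."""
    xs = np.sort(values)
    n = len(xs)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        sse = 0.0
        for i in range(k):
            seg = xs[bounds[i] : bounds[i + 1]]
            sse += ((seg - seg.mean()) ** 2).sum()
        best = min(best, sse)
    return best
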