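"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit loops,
elementary geometry), sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def windowed_mean_oracle(pixels: np.ndarray, size: int) -> np.ndarray:
    """Mean over the centred size x size window, truncated at borders."""
    h, w = pixels.shape
    half = size // 2
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            r0, r1 = max(0, r - half), min(h, r + half + 1)
            c0, c1 = max(0, c - half), min(w, c + half + 1)
            out[r, c] = pixels[r0:r1, c0:c1].mean()
    return out


def adaptive_oracle(pixels: np.ndarray, block_size: int, mean_shift: float) -> np.ndarray:
    mean = windowed_mean_oracle(pixels, block_size)
    return pixels > mean + mean_shift


def double_adaptive_oracle(pixels: np.ndarray, nh: int, bound_drop: float) -> np.ndarray:
    """Growing-square mean-drop rule, evaluated pixel by pixel."""
    h, w = pixels.shape
    k_max = (nh - 1) // 2
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            best = pixels[r, c]  # m(0)
            for k in range(1, k_max + 1):
                r0, r1 = max(0, r - k), min(h, r + k + 1)
                c0, c1 = max(0, c - k), min(w, c + k + 1)
                best = min(best, pixels[r0:r1, c0:c1].mean())
            out[r, c] = best <= pixels[r, c] - bound_drop
    return out


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                    and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                components.append(comp)
    return components


def filter_components_oracle(mask: np.ndarray, min_size: int) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    for comp in flood_fill_components(mask):
        if len(comp) >= min_size:
            for r, c in comp:
                out[r, c] = True
    return out


def row_counts_oracle(mask: np.ndarray) -> list[int]:
    """Per-row maximal-run counts over the vertical extent of the mask."""
    rows = [r for r in range(mask.shape[0]) if mask[r].any()]
    counts = []
    for r in range(rows[0], rows[-1] + 1):
        runs, inside = 0, False
        for px in mask[r]:
            if px and not inside:
                runs += 1
            inside = bool(px)
        counts.append(runs)
    return counts


def count_traits_oracle(counts) -> tuple[int, int, float]:
    """(MedR, MaxR, Bush) via explicit sort / nearest rank / half-up round."""
    s = sorted(int(c) for c in counts)
    n = len(s)
    median = s[n // 2] if n % 2 == 1 else (s[n // 2 - 1] + s[n // 2]) / 2
    medr = math.floor(median + 0.5)
    maxr = s[math.ceil(0.84 * n) - 1]
    return medr, maxr, (maxr / medr if medr else float("nan"))


def extent_oracle(mask: np.ndarray) -> dict[str, float]:
    """Ndepth/Nwidth/WDRatio/NwA/Perim/Ldist by exhaustive enumeration."""
    h, w = mask.shape
    pts = [(r, c) for r in range(h) for c in range(w) if mask[r, c]]
    rows = sorted({r for r, _ in pts})
    top, bottom = rows[0], rows[-1]
    ndepth = bottom - top + 1
    nwidth = 0
    for r in rows:
        cs = [c for rr, c in pts if rr == r]
        nwidth = max(nwidth, max(cs) - min(cs) + 1)
    perim = 0
    for r, c in pts:
        on_border = False
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                ny, nx = r + dy, c + dx
                if not (0 <= ny < h and 0 <= nx < w) or not mask[ny, nx]:
                    on_border = True
        perim += on_border
    boundary = top + math.ceil(ndepth / 3)
    lower = sum(1 for r, _ in pts if r >= boundary)
    return {
        "Ndepth": float(ndepth), "Nwidth": float(nwidth),
        "WDRatio": nwidth / ndepth, "NwA": float(len(pts)),
        "Perim": float(perim), "Ldist": lower / len(pts),
    }


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull_polygon(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Andrew's monotone chain; returns the hull counter-clockwise."""
    pts = sorted(set(map(tuple, points)))
    if len(pts) <= 2:
        return pts
    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def hull_pixel_count_oracle(mask: np.ndarray) -> int:
    """Pixels whose centres are inside/on the hull, by half-plane tests."""
    points = [tuple(p) for p in np.argwhere(mask)]
    hull = convex_hull_polygon(points)
    if len(hull) == 1:
        return 1
    if len(hull) == 2:
        (r0, c0), (r1, c1) = hull
        return math.gcd(abs(r1 - r0), abs(c1 - c0)) + 1
    rs = [r for r, _ in points]
    cs = [c for _, c in points]
    centroid = (sum(r for r, _ in hull) / len(hull), sum(c for _, c in hull) / len(hull))
    edges = [(hull[i], hull[(i + 1) % len(hull)]) for i in range(len(hull))]
    signs = [1.0 if _cross(a, b, centroid) > 0 else -1.0 for a, b in edges]
    count = 0
    for r in range(min(rs), max(rs) + 1):
        for c in range(min(cs), max(cs) + 1):
            inside = True
            for (a, b), s in zip(edges, signs):
                if s * _cross(a, b, (r, c)) < -1e-9:
                    inside = False
                    break
            count += inside
    return count
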