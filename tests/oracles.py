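"""Independent brute-force reference implementations used only by tests.

Each oracle is written in the most direct way possible (explicit loops,
exhaustive scans) so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def otsu_brute_force(pixels: np.ndarray, levels: np.ndarray | None = None) -> float:
    """Exhaustive Otsu: scan every candidate threshold, maximize
    between-class variance, lowest threshold wins ties."""
    values = pixels.ravel().astype(float)
    if levels is None:
        levels = np.arange(256.0)
    best_t, best_v = None, -1.0
    for t in levels:
        fg = values > t
        n1 = fg.sum()
        n0 = values.size - n1
        if n0 == 0 or n1 == 0:
            continue
        mu0 = values[~fg].mean()
        mu1 = values[fg].mean()
        v = n0 * n1 * (mu0 - mu1) ** 2
        if v > best_v + 1e-9 * max(best_v, 1.0):
            best_v, best_t = v, t
    return float(best_t)


def median_brute_force(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel sorted-neighborhood median, square window, edge replication."""
    h, w = pixels.shape
    out = np.empty_like(pixels, dtype=float)
    for r in range(h):
        for c in range(w):
            vals = []
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    rr = min(max(r + dr, 0), h - 1)
                    cc = min(max(c + dc, 0), w - 1)
                    vals.append(pixels[rr, cc])
            vals.sort()
            out[r, c] = vals[len(vals) // 2]
    return out


def gaussian_blur_brute_force(pixels: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2-D convolution with a sampled, normalized Gaussian kernel
    (radius = int(4*sigma + 0.5)), edge replication."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    h, w = pixels.shape
    padded = np.pad(pixels.astype(float), radius, mode="edge")
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = (padded[r : r + 2 * radius + 1,
                                c : c + 2 * radius + 1] * kernel).sum()
    return out


def unsharp_brute_force(pixels: np.ndarray, sigma: float, weight: float,
                        max_value: float) -> np.ndarray:
    blur = gaussian_blur_brute_force(pixels, sigma)
    out = (pixels - weight * blur) / (1.0 - weight)
    return np.clip(out, 0.0, max_value)


def branch_lengths_by_walk(pixel_set: set[tuple[int, int]],
                           pixel_size: float = 1.0) -> list[float]:
    """Exhaustive path-walk branch lengths on a thin 8-connected pixel set.

    Recomputes node pixels (degree != 2 under shortcut-free adjacency)
    and walks every chain, summing 1/sqrt(2) steps.
    """
    def neighbors(p):
        r, c = p
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q not in pixel_set:
                    continue
                if dr != 0 and dc != 0:
                    if (r + dr, c) in pixel_set or (r, c + dc) in pixel_set:
                        continue  # diagonal shortcut
                out.append(q)
        return out

    deg = {p: len(neighbors(p)) for p in pixel_set}
    node_px = {p for p in pixel_set if deg[p] != 2}
    lengths = []
    visited = set()
    for start in sorted(node_px):
        for first in neighbors(start):
            if frozenset((start, first)) in visited:
                continue
            visited.add(frozenset((start, first)))
            length = np.hypot(start[0] - first[0], start[1] - first[1])
            prev, cur = start, first
            while cur not in node_px:
                nxts = [q for q in neighbors(cur)
                        if frozenset((cur, q)) not in visited]
                if not nxts:
                    break
                nxt = nxts[0]
                visited.add(frozenset((cur, nxt)))
                length += np.hypot(cur[0] - nxt[0], cur[1] - nxt[1])
                prev, cur = cur, nxt
            lengths.append(length * pixel_size)
    return lengths


def anova_sums_of_squares(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """From-scratch one-way ANOVA: returns (F, df_between, df_within)."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n = len(all_vals)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, k - 1, n - k
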