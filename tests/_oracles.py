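"""Independent brute-force oracles used to validate the implementations.

Everything here is written as plain loops over textbook definitions, kept
deliberately free of the package's own vectorized code paths.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def glcm_correlation_bruteforce(view, n_levels, offsets):
    """Haralick correlation by explicit pair enumeration."""
    view = np.asarray(view, dtype=float)
    hmax = view.max()
    if hmax <= 0:
        return math.nan
    nr, nc = view.shape
    levels = [[min(int(view[i, j] / hmax * n_levels), n_levels - 1)
               for j in range(nc)] for i in range(nr)]
    per_offset = []
    for dr, dc in offsets:
        counts = [[0.0] * n_levels for _ in range(n_levels)]
        total = 0
        for i in range(nr):
            for j in range(nc):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < nr and 0 <= j2 < nc:
                    a, b = levels[i][j], levels[i2][j2]
                    counts[a][b] += 1  # forward
                    counts[b][a] += 1  # symmetric
                    total += 2
        p = [[c / total for c in row] for row in counts]
        mu = sum(i * sum(p[i]) for i in range(n_levels))
        var = sum((i - mu) ** 2 * sum(p[i]) for i in range(n_levels))
        if var <= 0:
            per_offset.append(math.nan)
            continue
        cov = sum((i - mu) * (j - mu) * p[i][j]
                  for i in range(n_levels) for j in range(n_levels))
        per_offset.append(cov / var)
    finite = [v for v in per_offset if not math.isnan(v)]
    return sum(finite) / len(finite) if finite else math.nan


def brown_forsythe_formula(groups):
    """W = ((N-k)/(k-1)) * sum n_i (Zbar_i - Zbar)^2 / sum sum (Z_ij - Zbar_i)^2
    with Z_ij = |x_ij - median_i|."""
    k = len(groups)
    z = [[abs(v - float(np.median(g))) for v in g] for g in groups]
    n = [len(g) for g in z]
    big_n = sum(n)
    zbar_i = [sum(g) / len(g) for g in z]
    zbar = sum(sum(g) for g in z) / big_n
    between = sum(ni * (zi - zbar) ** 2 for ni, zi in zip(n, zbar_i))
    within = sum(sum((v - zi) ** 2 for v in g) for g, zi in zip(z, zbar_i))
    return ((big_n - k) / (k - 1)) * between / within


def welch_formula(a, b):
    """Welch t and Satterthwaite df from the textbook formulas."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    t = (ma - mb) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def flood_fill_labels(mask):
    """8-connected component labelling by breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    nr, nc = mask.shape
    labels = np.zeros((nr, nc), dtype=int)
    current = 0
    for si in range(nr):
        for sj in range(nc):
            if not mask[si, sj] or labels[si, sj]:
                continue
            current += 1
            queue = deque([(si, sj)])
            labels[si, sj] = current
            while queue:
                i, j = queue.popleft()
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        i2, j2 = i + di, j + dj
                        if (0 <= i2 < nr and 0 <= j2 < nc
                                and mask[i2, j2] and not labels[i2, j2]):
                            labels[i2, j2] = current
                            queue.append((i2, j2))
    return labels


def naive_local_mean(heights, win_px):
    """Edge-clipped box mean by explicit window summation."""
    heights = np.asarray(heights, dtype=float)
    nr, nc = heights.shape
    lo = win_px // 2
    hi = win_px - lo
    out = np.empty_like(heights)
    for i in range(nr):
        for j in range(nc):
            r0, r1 = max(0, i - lo), min(nr, i + hi)
            c0, c1 = max(0, j - lo), min(nc, j + hi)
            out[i, j] = heights[r0:r1, c0:c1].mean()
    return out


def naive_segment(heights, win_px, k_hi, k_lo, h_min):
    """Reference per-pixel classification (0 bare, 1 trough, 2 base, 3 cluster)."""
    heights = np.asarray(heights, dtype=float)
    m = naive_local_mean(heights, win_px)
    labels = np.empty(heights.shape, dtype=int)
    nr, nc = heights.shape
    for i in range(nr):
        for j in range(nc):
            h = heights[i, j]
            if h < h_min:
                labels[i, j] = 0
            elif h >= k_hi * m[i, j]:
                labels[i, j] = 3
            elif h <= m[i, j] / k_lo:
                labels[i, j] = 1
            else:
                labels[i, j] = 2
    return labels
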