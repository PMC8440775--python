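"""Naive double-loop reference implementations used as independent oracles.

These deliberately mirror the written definitions pixel by pixel, with no
shared code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_diamond_average(x: np.ndarray, s_w: int) -> np.ndarray:
    m, n = x.shape
    radius = (s_w - 1) // 2
    out = np.full((m, n), np.nan)
    denom = (s_w * s_w + 1) / 2
    for i in range(radius, m - radius):
        for j in range(radius, n - radius):
            total = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    if abs(di) + abs(dj) <= radius:
                        total += x[i + di, j + dj]
            out[i, j] = total / denom
    return out


def naive_directional_diffs(ave: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m, n = ave.shape
    d1 = np.full((m, n), np.nan)
    d2 = np.full((m, n), np.nan)
    for i in range(1, m - 1):
        for j in range(1, n - 1):
            a = ave[i - 1, j - 1]
            b = ave[i + 1, j + 1]
            c = ave[i - 1, j + 1]
            d = ave[i + 1, j - 1]
            if not (np.isnan(a) or np.isnan(b)):
                d1[i, j] = abs(a - b)
            if not (np.isnan(c) or np.isnan(d)):
                d2[i, j] = abs(c - d)
    return d1, d2


def naive_detect_boundaries(d1: np.ndarray, d2: np.ndarray, th: float):
    m, n = d1.shape
    p1, p2 = set(), set()
    for i in range(1, m - 1):
        for j in range(1, n - 1):
            vals = (d1[i, j], d1[i - 1, j - 1], d1[i + 1, j + 1])
            if not any(np.isnan(v) for v in vals):
                if vals[0] > vals[1] and vals[0] > vals[2] and vals[0] > th:
                    p1.add((i, j))
            vals = (d2[i, j], d2[i - 1, j + 1], d2[i + 1, j - 1])
            if not any(np.isnan(v) for v in vals):
                if vals[0] > vals[1] and vals[0] > vals[2] and vals[0] > th:
                    p2.add((i, j))
    return p1, p2


def naive_dark_fraction(x: np.ndarray, top: int, left: int, d0: int,
                        t_dp: float) -> float:
    count = 0
    for i in range(top, top + d0):
        for j in range(left, left + d0):
            if x[i, j] < t_dp:
                count += 1
    return count / (d0 * d0)


def naive_window_mean(x: np.ndarray, top: int, left: int, d0: int) -> float:
    total = 0.0
    for i in range(top, top + d0):
        for j in range(left, left + d0):
            total += x[i, j]
    return total / (d0 * d0)


def naive_select_center(x: np.ndarray, i: int, j: int, d0: int):
    """Minimum-mean candidate square; first listed wins ties."""
    candidates = [
        (i - d0, j - d0), (i - d0, j - d0 // 2), (i - d0, j),
        (i, j - d0), (i, j - d0 // 2), (i, j),
    ]
    best = None
    best_mean = math.inf
    for top, left in candidates:
        mean = naive_window_mean(x, top, left, d0)
        if mean < best_mean:
            best_mean = mean
            best = (top, left)
    return best, best_mean


def naive_testsquare_std(x: np.ndarray, top: int, left: int, d: int) -> float:
    vals = []
    for i in range(top, top + d):
        for j in range(left, left + d):
            vals.append(x[i, j])
    mean = sum(vals) / len(vals)
    return math.sqrt(sum((v - mean) ** 2 for v in vals) / (d * d - 1))


def naive_components(points, radius: int) -> int:
    """Number of single-linkage components under Chebyshev distance."""
    pts = sorted(points)
    parent = list(range(len(pts)))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            da = abs(pts[a][0] - pts[b][0])
            db = abs(pts[a][1] - pts[b][1])
            if max(da, db) <= radius:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    return len({find(a) for a in range(len(pts))})
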