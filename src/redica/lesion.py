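"""Red-lesion discrimination by directional chains of dark/light windows.

A red lesion is a compact dark blob: around one of its boundary pixels,
the darkest nearby d_0 x d_0 window sits on the lesion while the windows
one step further out in *every* direction sit on bright background.  A
vessel, by contrast, has at least one direction (along the vessel) in
which the flanking windows stay dark.  For each boundary pixel the stage

1. picks the center window ``W^{0,0}``: the minimum-mean square among six
   d_0 x d_0 candidates touching the pixel (above/below x left/center/
   right);
2. builds chains of windows ``W^{k,theta}`` for k = -num..num in the
   horizontal direction (theta = 0) and in a set of oblique directions
   (first quarter for 135-degree boundary pixels, second quarter for
   45-degree ones, both for pixels in both families);
3. labels each window dark (dark-pixel fraction > T_D), light
   (fraction < T_L) or neither, where a dark pixel has intensity < T_dp;
4. accepts the pixel iff the center window is dark and every flanking
   window of every tested chain is light.

Chain geometry (0-based rows/cols, window top-left (x, y)):

    theta = 0:          (x0,          y0 + k*r)
    0 < theta < 90:     (x0 - k*r,    y0 + floor(k*r*tan(theta)))
    90 < theta < 180:   (x0 - k*r,    y0 - floor(k*r*tan(theta)))

The floor is taken on the signed product (rounded to 9 decimals first so
that e.g. tan(135 deg) = -1 + 1e-16 cannot shift a window by a pixel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .boundary import BoundarySet
from .config import LesionConfig
from .preprocess import PreprocessedImage

__all__ = [
    "WindowSpec",
    "PatchLabel",
    "LesionPixelSet",
    "Spot",
    "WindowOutOfBounds",
    "classify_patch",
    "select_center_window",
    "build_window_chain",
    "is_lesion_boundary",
    "extract_lesions",
    "extract_lesions_multiscale",
    "cluster_spots",
]


class WindowOutOfBounds(ValueError):
    """A window (or candidate square) does not fit inside the image."""


@dataclass(frozen=True)
class WindowSpec:
    """A d_0 x d_0 window: half-open row/col span starting at its top-left."""

    top_row: int
    left_col: int
    size: int
    k: int = 0
    theta: float = 0.0

    def fits(self, shape: tuple[int, int]) -> bool:
        m, n = shape
        return (0 <= self.top_row and self.top_row + self.size <= m
                and 0 <= self.left_col and self.left_col + self.size <= n)


@dataclass(frozen=True)
class PatchLabel:
    """Dark-pixel fraction of a window and its dark/light/neither label."""

    dark_fraction: float
    label: str  # "dark" | "light" | "neither"


@dataclass(frozen=True)
class Spot:
    """A cluster of detected pixels: one candidate lesion."""

    pixels: tuple
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (inclusive)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def to_dict(self) -> dict:
        return {
            "centroid": [round(self.centroid[0], 3), round(self.centroid[1], 3)],
            "bbox": list(self.bbox),
            "n_pixels": self.n_pixels,
        }


@dataclass(frozen=True)
class LesionPixelSet:
    """Pixels accepted as red-lesion boundary pixels, with diagnostics.

    ``scales`` maps each pixel to the window widths d_0 at which it was
    accepted; ``records`` holds per-pixel decision diagnostics (center
    window, per-direction labels, or the rejection reason).
    """

    pixels: frozenset
    scales: Mapping = field(default_factory=dict)
    records: Mapping = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pixels)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (r, c) in sorted(self.pixels):
            for d0 in sorted(self.scales.get((r, c), ())):
                rows.append((r, c, d0))
        return pd.DataFrame(rows, columns=["row", "col", "d_0_scale"])

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class _WindowStats:
    """O(1) window sums via summed-area tables (intensity and dark counts)."""

    def __init__(self, x: np.ndarray, t_dp: float):
        x = np.asarray(x, dtype=np.float64)
        self.shape = x.shape
        self._sum = np.zeros((x.shape[0] + 1, x.shape[1] + 1))
        self._sum[1:, 1:] = np.cumsum(np.cumsum(x, axis=0), axis=1)
        dark = (x < t_dp).astype(np.int64)
        self._dark = np.zeros((x.shape[0] + 1, x.shape[1] + 1), dtype=np.int64)
        self._dark[1:, 1:] = np.cumsum(np.cumsum(dark, axis=0), axis=1)

    def _box(self, table, top, left, size):
        return (table[top + size, left + size] - table[top, left + size]
                - table[top + size, left] + table[top, left])

    def mean(self, top, left, size):
        return self._box(self._sum, top, left, size) / (size * size)

    def dark_fraction(self, top, left, size):
        return self._box(self._dark, top, left, size) / (size * size)


def _label_fraction(frac: float, cfg: LesionConfig) -> str:
    if frac > cfg.t_d:
        return "dark"
    if frac < cfg.t_l:
        return "light"
    return "neither"


def classify_patch(
    img: PreprocessedImage, spec: WindowSpec, cfg: LesionConfig = LesionConfig()
) -> PatchLabel:
    """Label one window dark/light/neither by its dark-pixel fraction.

    dark_fraction = #(pixels with intensity < T_dp) / d_0^2; the window
    is dark when the fraction exceeds T_D and light when it falls below
    T_L.  Windows partially outside the image raise; callers must skip
    such candidates rather than pad.
    """
    if not spec.fits(img.shape):
        raise WindowOutOfBounds(
            f"window {spec.top_row}:{spec.top_row + spec.size}, "
            f"{spec.left_col}:{spec.left_col + spec.size} outside {img.shape}"
        )
    patch = img.intensity[spec.top_row: spec.top_row + spec.size,
                          spec.left_col: spec.left_col + spec.size]
    frac = float(np.count_nonzero(patch < cfg.t_dp)) / (spec.size * spec.size)
    return PatchLabel(dark_fraction=frac, label=_label_fraction(frac, cfg))


_CANDIDATE_OFFSETS = (
    # (row offset factor, col offset) in units of d_0; order defines tie-break
    ("above", "left"), ("above", "center"), ("above", "right"),
    ("below", "left"), ("below", "center"), ("below", "right"),
)


def _candidate_corners(i: int, j: int, d_0: int):
    tops = {"above": i - d_0, "below": i}
    lefts = {"left": j - d_0, "center": j - d_0 // 2, "right": j}
    return [(tops[a], lefts[b]) for a, b in _CANDIDATE_OFFSETS]


def select_center_window(
    img: PreprocessedImage, i: int, j: int, d_0: int = 10
) -> WindowSpec:
    """Pick the minimum-mean square among the six candidates around (i, j).

    The candidates are the above/below x left/center/right d_0 x d_0
    squares touching the pixel; ties keep the first candidate in that
    listed order.  All six must fit in the image, otherwise the pixel
    cannot be evaluated and ``WindowOutOfBounds`` is raised (callers
    skip and record such pixels).
    """
    m, n = img.shape
    if not (i - d_0 >= 0 and i + d_0 <= m and j - d_0 >= 0 and j + d_0 <= n):
        raise WindowOutOfBounds(
            f"candidate squares around ({i}, {j}) with d_0={d_0} leave the image"
        )
    corners = _candidate_corners(i, j, d_0)
    means = [float(np.mean(img.intensity[t: t + d_0, l: l + d_0]))
             for t, l in corners]
    best = int(np.argmin(means))  # first occurrence wins ties
    top, left = corners[best]
    return WindowSpec(top_row=top, left_col=left, size=d_0, k=0, theta=0.0)


def _chain_offset(k: int, r: int, theta: float) -> tuple[int, int]:
    """(row, col) offset of the k-th chain window's top-left from (x0, y0)."""
    if theta == 0.0:
        return 0, k * r
    t = math.tan(math.radians(theta))
    lateral = math.floor(round(k * r * t, 9))
    if 0.0 < theta < 90.0:
        return -k * r, lateral
    if 90.0 < theta < 180.0:
        return -k * r, -lateral
    raise ValueError(f"direction theta={theta} outside [0, 180) or equal to 90")


def build_window_chain(
    center: WindowSpec, theta: float, cfg: LesionConfig = LesionConfig()
) -> list[WindowSpec]:
    """Windows W^{k,theta} for k = -num..num along direction ``theta``.

    k = 0 reproduces the center window for every direction.  theta = 90
    is rejected (tan undefined; the config invariant already excludes it).
    """
    if theta == 90.0:
        raise ValueError("theta = 90 degrees is not a valid chain direction")
    r = cfg.step
    chain = []
    for k in range(-cfg.num, cfg.num + 1):
        drow, dcol = _chain_offset(k, r, theta)
        chain.append(
            WindowSpec(
                top_row=center.top_row + drow,
                left_col=center.left_col + dcol,
                size=center.size,
                k=k,
                theta=theta,
            )
        )
    return chain


def _tested_directions(in_p1: bool, in_p2: bool, cfg: LesionConfig) -> tuple[float, ...]:
    dirs: list[float] = [0.0]
    if in_p1:
        dirs.extend(cfg.angles_first_quarter)
    if in_p2:
        dirs.extend(cfg.angles_second_quarter)
    return tuple(dirs)


def is_lesion_boundary(
    img: PreprocessedImage,
    pixel: tuple[int, int],
    membership: tuple[bool, bool],
    cfg: LesionConfig = LesionConfig(),
    _stats: "_WindowStats | None" = None,
) -> tuple[bool, dict]:
    """Decide whether one boundary pixel lies on a red-lesion boundary.

    Accepts iff the center window is dark and every flanking window of
    every tested chain is light; a flanking window falling off the image
    rejects the pixel (its lightness cannot be verified).  Returns the
    decision plus a diagnostics record.
    """
    i, j = pixel
    in_p1, in_p2 = membership
    stats = _stats if _stats is not None else _WindowStats(img.intensity, cfg.t_dp)
    d_0 = cfg.d_0
    m, n = img.shape
    diag: dict = {"pixel": (i, j), "d_0": d_0}
    if not (i - d_0 >= 0 and i + d_0 <= m and j - d_0 >= 0 and j + d_0 <= n):
        diag["reason"] = "center_candidates_off_image"
        return False, diag
    corners = _candidate_corners(i, j, d_0)
    means = [stats.mean(t, l, d_0) for t, l in corners]
    best = int(np.argmin(means))
    top, left = corners[best]
    center = WindowSpec(top_row=top, left_col=left, size=d_0, k=0, theta=0.0)
    center_frac = stats.dark_fraction(top, left, d_0)
    diag["center"] = (top, left)
    diag["center_dark_fraction"] = float(center_frac)
    if not center_frac > cfg.t_d:
        diag["reason"] = "center_not_dark"
        return False, diag
    flank_labels: dict = {}
    diag["flanks"] = flank_labels
    for theta in _tested_directions(in_p1, in_p2, cfg):
        for w in build_window_chain(center, theta, cfg):
            if w.k == 0:
                continue
            if not w.fits(img.shape):
                diag["reason"] = "flank_off_image"
                diag["failed_at"] = (theta, w.k)
                return False, diag
            frac = stats.dark_fraction(w.top_row, w.left_col, d_0)
            label = _label_fraction(frac, cfg)
            flank_labels[(theta, w.k)] = (float(frac), label)
            if label != "light":
                diag["reason"] = "flank_not_light"
                diag["failed_at"] = (theta, w.k)
                return False, diag
    diag["reason"] = "accepted"
    return True, diag


def _vectorized_center_stage(
    stats: _WindowStats, pts: np.ndarray, d_0: int, cfg: LesionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Return (survivor mask, skip mask) for the center-window dark test.

    Pixels whose six candidate squares leave the image are skipped; for
    the rest the minimum-mean candidate is located and its dark-pixel
    fraction compared with T_D.  Only survivors need the (python-level)
    per-direction chain verification.
    """
    m, n = stats.shape
    i = pts[:, 0]
    j = pts[:, 1]
    ok = (i >= d_0) & (i + d_0 <= m) & (j >= d_0) & (j + d_0 <= n)
    survivors = np.zeros(len(pts), dtype=bool)
    if ok.any():
        ii, jj = i[ok], j[ok]
        tops = np.stack([ii - d_0] * 3 + [ii] * 3)
        lefts = np.stack([jj - d_0, jj - d_0 // 2, jj] * 2)
        means = stats.mean(tops, lefts, d_0)
        best = np.argmin(means, axis=0)
        sel = np.arange(len(ii))
        ctop = tops[best, sel]
        cleft = lefts[best, sel]
        frac = stats.dark_fraction(ctop, cleft, d_0)
        survivors[np.nonzero(ok)[0]] = frac > cfg.t_d
    return survivors, ~ok


def extract_lesions(
    img: PreprocessedImage,
    boundaries: BoundarySet,
    cfg: LesionConfig = LesionConfig(),
) -> LesionPixelSet:
    """Run the lesion decision over every boundary pixel (single scale)."""
    pts = sorted(boundaries.p)
    if not pts:
        return LesionPixelSet(pixels=frozenset(), scales={}, records={})
    stats = _WindowStats(img.intensity, cfg.t_dp)
    arr = np.asarray(pts, dtype=np.int64)
    survivors, skipped = _vectorized_center_stage(stats, arr, cfg.d_0, cfg)
    accepted = []
    records: dict = {}
    for idx in np.nonzero(survivors)[0]:
        pixel = pts[idx]
        membership = (pixel in boundaries.p1, pixel in boundaries.p2)
        ok, diag = is_lesion_boundary(img, pixel, membership, cfg, _stats=stats)
        records[pixel] = diag
        if ok:
            accepted.append(pixel)
    for idx in np.nonzero(skipped)[0]:
        records[pts[idx]] = {"pixel": pts[idx], "d_0": cfg.d_0,
                             "reason": "center_candidates_off_image"}
    pixels = frozenset(accepted)
    scales = {p: (cfg.d_0,) for p in pixels}
    return LesionPixelSet(pixels=pixels, scales=scales, records=records)


def extract_lesions_multiscale(
    img: PreprocessedImage,
    boundaries: BoundarySet,
    cfg: LesionConfig = LesionConfig(),
    d_0_scales: Sequence[int] = (10, 16, 22),
) -> LesionPixelSet:
    """Union of single-scale extractions over several window widths d_0."""
    pixels: set = set()
    scales: dict = {}
    records: dict = {}
    for d_0 in d_0_scales:
        res = extract_lesions(img, boundaries, cfg.replace(d_0=d_0))
        for p in res.pixels:
            pixels.add(p)
            scales[p] = tuple(sorted(set(scales.get(p, ())) | {d_0}))
        records[d_0] = res.records
    return LesionPixelSet(pixels=frozenset(pixels), scales=scales, records=records)


def cluster_spots(
    pixels: Iterable[tuple[int, int]] | LesionPixelSet,
    linking_radius: int = 10,
) -> list[Spot]:
    """Single-linkage clustering under Chebyshev distance <= linking_radius.

    Spots are returned sorted by (min_row, min_col) of their bounding box.
    """
    if isinstance(pixels, LesionPixelSet):
        pts = sorted(pixels.pixels)
    else:
        pts = sorted(set(pixels))
    if not pts:
        return []
    arr = np.asarray(pts, dtype=np.float64)
    tree = cKDTree(arr)
    pairs = tree.query_pairs(r=linking_radius, p=np.inf, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list] = {}
    for idx in range(len(pts)):
        groups.setdefault(find(idx), []).append(pts[idx])
    spots = []
    for members in groups.values():
        members = sorted(members)
        rows = [r for r, _ in members]
        cols = [c for _, c in members]
        spots.append(
            Spot(
                pixels=tuple(members),
                centroid=(float(np.mean(rows)), float(np.mean(cols))),
                bbox=(min(rows), min(cols), max(rows), max(cols)),
            )
        )
    return sorted(spots, key=lambda s: s.bbox)
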