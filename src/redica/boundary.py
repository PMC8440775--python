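"""Boundary-pixel determination by diagonal local-maximum differences.

Each pixel p_{i,j} gets the mean intensity ``ave`` of its s_w x s_w
diamond neighborhood (Manhattan radius (s_w-1)/2, center included; the
diamond holds (s_w^2+1)/2 pixels).  Two diagonal difference maps are
formed,

    Diff1_{i,j} = |ave_{i-1,j-1} - ave_{i+1,j+1}|      (135 degrees)
    Diff2_{i,j} = |ave_{i-1,j+1} - ave_{i+1,j-1}|      (45 degrees)

and a pixel is a boundary pixel of the corresponding family when its
Diff value is a strict local maximum along that diagonal and exceeds
th_Diff.  Margin cells where the diamond or a diagonal neighbor leaves
the image are NaN, never zero, so threshold sweeps cannot recruit them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import BoundaryConfig
from .preprocess import PreprocessedImage

__all__ = [
    "DiffMaps",
    "BoundarySet",
    "diamond_average",
    "directional_diffs",
    "detect_boundaries",
    "compute_boundaries",
]


def _diamond_footprint(s_w: int) -> np.ndarray:
    radius = (s_w - 1) // 2
    di, dj = np.mgrid[-radius: radius + 1, -radius: radius + 1]
    return (np.abs(di) + np.abs(dj)) <= radius


@dataclass(frozen=True)
class DiffMaps:
    """Diamond-mean map and the two diagonal difference maps (NaN = undefined)."""

    ave: np.ndarray
    diff1: np.ndarray
    diff2: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.ave.shape


@dataclass(frozen=True)
class BoundarySet:
    """Boundary pixels with membership in the 135-degree (P1) and
    45-degree (P2) families; P = P1 | P2."""

    p1: frozenset
    p2: frozenset

    @property
    def p(self) -> frozenset:
        return self.p1 | self.p2

    def __len__(self) -> int:
        return len(self.p)

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.p)
        return pd.DataFrame(
            {
                "row": [r for r, _ in rows],
                "col": [c for _, c in rows],
                "in_p1": [int((r, c) in self.p1) for r, c in rows],
                "in_p2": [int((r, c) in self.p2) for r, c in rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BoundarySet":
        df = pd.read_csv(path)
        p1 = frozenset(
            (int(r), int(c))
            for r, c, f in zip(df["row"], df["col"], df["in_p1"]) if f
        )
        p2 = frozenset(
            (int(r), int(c))
            for r, c, f in zip(df["row"], df["col"], df["in_p2"]) if f
        )
        return cls(p1=p1, p2=p2)


def diamond_average(img: PreprocessedImage | np.ndarray, s_w: int = 5) -> np.ndarray:
    """Mean intensity over the s_w x s_w diamond neighborhood of each pixel.

    The divisor is (s_w^2 + 1)/2 — the number of pixels in the diamond
    (13 for s_w = 5).  Cells whose diamond leaves the image are NaN.
    """
    x = img.intensity if isinstance(img, PreprocessedImage) else np.asarray(img, float)
    if s_w % 2 == 0 or s_w < 3:
        raise ValueError(f"s_w must be odd and >= 3, got {s_w}")
    m, n = x.shape
    if m < s_w or n < s_w:
        raise ValueError(f"image {m}x{n} smaller than the {s_w}x{s_w} neighborhood")
    radius = (s_w - 1) // 2
    fp = _diamond_footprint(s_w).astype(np.float64)
    count = (s_w * s_w + 1) // 2
    ave = ndimage.correlate(x, fp, mode="constant", cval=0.0) / count
    ave[:radius, :] = np.nan
    ave[m - radius:, :] = np.nan
    ave[:, :radius] = np.nan
    ave[:, n - radius:] = np.nan
    return ave


def directional_diffs(ave: np.ndarray) -> DiffMaps:
    """Absolute diagonal differences of the diamond-mean map.

    diff1 uses the NW/SE neighbors (135 degrees), diff2 the NE/SW
    neighbors (45 degrees); cells lacking a valid neighbor are NaN.
    """
    ave = np.asarray(ave, dtype=np.float64)
    m, n = ave.shape
    diff1 = np.full((m, n), np.nan)
    diff2 = np.full((m, n), np.nan)
    diff1[1:-1, 1:-1] = np.abs(ave[:-2, :-2] - ave[2:, 2:])
    diff2[1:-1, 1:-1] = np.abs(ave[:-2, 2:] - ave[2:, :-2])
    return DiffMaps(ave=ave, diff1=diff1, diff2=diff2)


def _strict_diagonal_maxima(diff: np.ndarray, sign: int, th: float) -> np.ndarray:
    """Mask of strict local maxima of ``diff`` along one diagonal.

    ``sign=+1`` compares against the (i-1,j-1)/(i+1,j+1) neighbors,
    ``sign=-1`` against (i-1,j+1)/(i+1,j-1).  NaN cells never qualify
    and never let a neighbor qualify (comparisons with NaN are False,
    so a cell next to an undefined margin is excluded).
    """
    m, n = diff.shape
    mask = np.zeros((m, n), dtype=bool)
    center = diff[1:-1, 1:-1]
    if sign > 0:
        prev_n = diff[:-2, :-2]
        next_n = diff[2:, 2:]
    else:
        prev_n = diff[:-2, 2:]
        next_n = diff[2:, :-2]
    with np.errstate(invalid="ignore"):
        ok = (center > prev_n) & (center > next_n) & (center > th)
    ok &= np.isfinite(prev_n) & np.isfinite(next_n)
    mask[1:-1, 1:-1] = ok
    return mask


def detect_boundaries(
    maps: DiffMaps,
    cfg: BoundaryConfig = BoundaryConfig(),
    fov_mask: np.ndarray | None = None,
) -> BoundarySet:
    """Select boundary pixels from the difference maps.

    (i,j) joins P1 iff Diff1 is a strict local maximum along the 135°
    diagonal and exceeds th_Diff; P2 analogously along 45°.  A pixel may
    belong to both.  When a field-of-view mask is given, pixels whose
    neighborhood footprint touches the outside of the FOV are discarded.
    """
    m1 = _strict_diagonal_maxima(maps.diff1, +1, cfg.th_diff)
    m2 = _strict_diagonal_maxima(maps.diff2, -1, cfg.th_diff)
    if fov_mask is not None and not fov_mask.all():
        reach = (cfg.s_w - 1) // 2 + 1  # diamond radius plus the diff offset
        side = 2 * reach + 1
        inside = ndimage.binary_erosion(
            fov_mask, structure=np.ones((side, side), dtype=bool)
        )
        m1 &= inside
        m2 &= inside
    p1 = frozenset(zip(*np.nonzero(m1)))
    p2 = frozenset(zip(*np.nonzero(m2)))
    p1 = frozenset((int(r), int(c)) for r, c in p1)
    p2 = frozenset((int(r), int(c)) for r, c in p2)
    return BoundarySet(p1=p1, p2=p2)


def compute_boundaries(
    img: PreprocessedImage, cfg: BoundaryConfig = BoundaryConfig(),
    use_fov: bool = True,
) -> BoundarySet:
    """Convenience wrapper: diamond means -> diagonal diffs -> boundary set."""
    ave = diamond_average(img, cfg.s_w)
    maps = directional_diffs(ave)
    fov = img.fov_mask if use_fov else None
    return detect_boundaries(maps, cfg, fov_mask=fov)
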