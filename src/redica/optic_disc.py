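"""Optic-disc localization by intensity-variance ranking of test-squares.

The optic disc is the brightest region of a fundus image and is crossed
by dark vessels, so the intensity standard deviation inside a disc-sized
square peaks there.  The image is scanned with d_od x d_od test-squares
on an r_d-strided grid; squares are ranked by their sample standard
deviation and the starting rows/columns of the top alpha percent are
averaged to place the final square, which is then used to suppress
lesion candidates inside it (the disc contains no red lesions).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import DiscConfig
from .lesion import LesionPixelSet
from .preprocess import PreprocessedImage

__all__ = ["DiscZone", "testsquare_std", "localize_disc", "filter_inside_disc"]


@dataclass(frozen=True)
class DiscZone:
    """The d_od x d_od square selected as the optic-disc region."""

    top_row: int
    left_col: int
    size: int
    score: float  # std_t evaluated at the final (averaged) position

    def contains(self, row: int, col: int) -> bool:
        return (self.top_row <= row < self.top_row + self.size
                and self.left_col <= col < self.left_col + self.size)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"top_row": self.top_row, "left_col": self.left_col,
             "size": self.size, "score": round(self.score, 9)},
            sort_keys=True) + "\n")


def testsquare_std(
    img: PreprocessedImage | np.ndarray, top_row: int, left_col: int, d_od: int
) -> float:
    """Sample standard deviation (denominator d_od^2 - 1) of one square."""
    x = img.intensity if isinstance(img, PreprocessedImage) else np.asarray(img, float)
    m, n = x.shape
    if not (0 <= top_row and top_row + d_od <= m
            and 0 <= left_col and left_col + d_od <= n):
        raise ValueError(
            f"test-square at ({top_row}, {left_col}) with side {d_od} "
            f"outside image {x.shape}"
        )
    patch = x[top_row: top_row + d_od, left_col: left_col + d_od]
    return float(np.std(patch, ddof=1))


def _grid_positions(extent: int, d_od: int, r_d: int) -> np.ndarray:
    return np.arange(0, extent - d_od + 1, r_d, dtype=np.int64)


def localize_disc(
    img: PreprocessedImage, cfg: DiscConfig = DiscConfig()
) -> DiscZone:
    """Locate the optic-disc square by top-alpha variance averaging.

    All grid test-squares are scored by std_t; ties in the descending
    sort are broken by (top_row, left_col) for determinism.  At least
    one square is always kept (ceil of alpha percent).  When the image
    carries a partial field-of-view mask, squares with more than
    ``cfg.max_fov_outside`` of their area outside the FOV are excluded
    (the dark aperture rim otherwise wins on variance).
    """
    x = img.intensity
    m, n = x.shape
    d_od = cfg.d_od
    if m < d_od or n < d_od:
        raise ValueError(f"image {m}x{n} smaller than the disc square {d_od}")
    tops = _grid_positions(m, d_od, cfg.r_d)
    lefts = _grid_positions(n, d_od, cfg.r_d)

    # summed-area tables for mean and mean of squares
    s1 = np.zeros((m + 1, n + 1))
    s1[1:, 1:] = np.cumsum(np.cumsum(x, axis=0), axis=1)
    s2 = np.zeros((m + 1, n + 1))
    s2[1:, 1:] = np.cumsum(np.cumsum(x * x, axis=0), axis=1)

    def box(table, t, l):
        return (table[t + d_od][:, l + d_od] - table[t, :][:, l + d_od]
                - table[t + d_od][:, l] + table[t, :][:, l])

    tt = tops[:, None] * np.ones(len(lefts), dtype=np.int64)[None, :]
    ll = np.ones(len(tops), dtype=np.int64)[:, None] * lefts[None, :]
    count = d_od * d_od
    sums = box(s1, tops, lefts)
    sq = box(s2, tops, lefts)
    var = np.maximum(sq - sums * sums / count, 0.0) / (count - 1)
    std = np.sqrt(var)

    if not img.fov_mask.all():
        f = np.zeros((m + 1, n + 1))
        f[1:, 1:] = np.cumsum(np.cumsum(img.fov_mask.astype(np.float64), 0), 1)
        inside_frac = box(f, tops, lefts) / count
        usable = inside_frac >= 1.0 - cfg.max_fov_outside
        if not usable.any():
            usable = inside_frac >= inside_frac.max()
        std = np.where(usable, std, -np.inf)

    order = sorted(
        ((float(std[a, b]), int(tt[a, b]), int(ll[a, b]))
         for a in range(len(tops)) for b in range(len(lefts))
         if np.isfinite(std[a, b])),
        key=lambda rec: (-rec[0], rec[1], rec[2]),
    )
    n_top = max(1, math.ceil(cfg.alpha / 100.0 * len(order)))
    chosen = order[:n_top]
    top = int(math.floor(np.mean([r[1] for r in chosen]) + 0.5))
    left = int(math.floor(np.mean([r[2] for r in chosen]) + 0.5))
    top = int(np.clip(top, 0, m - d_od))
    left = int(np.clip(left, 0, n - d_od))
    return DiscZone(top_row=top, left_col=left, size=d_od,
                    score=testsquare_std(x, top, left, d_od))


def filter_inside_disc(pixels: LesionPixelSet, zone: DiscZone) -> LesionPixelSet:
    """Remove exactly the lesion pixels falling inside the disc square."""
    kept = frozenset(p for p in pixels.pixels if not zone.contains(*p))
    return LesionPixelSet(
        pixels=kept,
        scales={p: s for p, s in pixels.scales.items() if p in kept},
        records=pixels.records,
    )
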