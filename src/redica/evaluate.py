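"""Lesion-level evaluation: confusion counting, SE/SP, ROC over T_D.

All four confusion counts are at the level of lesions/spots, not pixels:

* TP — annotated lesion regions containing at least one detected pixel;
* FN — annotated regions containing none;
* FP — detected spots none of whose pixels fall inside any region;
* TN — rejected candidate spots (boundary-pixel clusters not labeled
  lesion) lying entirely outside every annotated region.

SE = TP/(TP+FN) and SP = TN/(TN+FP); a zero denominator leaves the
metric undefined (None), never silently zero.  The ROC curve sweeps the
dark-window threshold T_D: raising it makes the center-window darkness
test harder, so detections (and with them SE and FP) shrink while the
rejected pool (TN) grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .boundary import BoundarySet, compute_boundaries
from .config import BoundaryConfig, LesionConfig
from .lesion import LesionPixelSet, Spot, cluster_spots, extract_lesions_multiscale
from .preprocess import PreprocessedImage

__all__ = [
    "Region",
    "AnnotationSet",
    "ConfusionCounts",
    "RocCurve",
    "read_mask_annotations",
    "read_box_annotations",
    "partition_candidate_spots",
    "match_lesions",
    "sensitivity_specificity",
    "roc_by_td",
]


@dataclass(frozen=True)
class Region:
    """One annotated lesion region: a pixel set or an axis-aligned box.

    Boxes are (min_row, min_col, max_row, max_col), inclusive.
    """

    pixels: frozenset | None = None
    box: tuple[int, int, int, int] | None = None
    region_id: int = 0

    def __post_init__(self) -> None:
        if (self.pixels is None) == (self.box is None):
            raise ValueError("a region is either a pixel set or a box")
        if self.pixels is not None and not self.pixels:
            raise ValueError("empty region mask")

    def contains(self, row: int, col: int) -> bool:
        if self.pixels is not None:
            return (row, col) in self.pixels
        r0, c0, r1, c1 = self.box
        return r0 <= row <= r1 and c0 <= col <= c1

    def bounds(self) -> tuple[int, int, int, int]:
        if self.box is not None:
            return self.box
        rows = [r for r, _ in self.pixels]
        cols = [c for _, c in self.pixels]
        return min(rows), min(cols), max(rows), max(cols)


@dataclass(frozen=True)
class AnnotationSet:
    """Ground-truth lesion regions for one image."""

    regions: tuple[Region, ...]
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.image_shape is not None:
            m, n = self.image_shape
            for reg in self.regions:
                r0, c0, r1, c1 = reg.bounds()
                if r0 < 0 or c0 < 0 or r1 >= m or c1 >= n:
                    raise ValueError(
                        f"region {reg.region_id} bounds {reg.bounds()} outside "
                        f"image {self.image_shape}"
                    )

    def __len__(self) -> int:
        return len(self.regions)

    def contains_any(self, row: int, col: int) -> bool:
        return any(reg.contains(row, col) for reg in self.regions)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def se(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None

    @property
    def sp(self) -> float | None:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) > 0 else None

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)


@dataclass(frozen=True)
class RocCurve:
    """(1-SP, SE) operating points indexed by T_D, plus trapezoidal AUC."""

    td_values: tuple[float, ...]
    points: tuple[tuple[float, float], ...]
    auc: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_D": self.td_values,
                "one_minus_sp": [p[0] for p in self.points],
                "se": [p[1] for p in self.points],
            }
        )


def read_mask_annotations(
    path: str | Path, soft_threshold: float | None = None
) -> AnnotationSet:
    """Read a lesion annotation raster; connected components become regions.

    Binary masks: any nonzero pixel is lesion.  Soft confidence maps:
    pass ``soft_threshold`` (0.75 is the conventional cut) applied on
    the [0, 1]-normalized values.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / float(np.iinfo(np.uint8).max if arr.max() <= 255 else arr.max())
    binary = arr > (0.0 if soft_threshold is None else soft_threshold)
    labels, n_comp = ndimage.label(binary)
    regions = []
    for rid in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == rid)
        regions.append(Region(
            pixels=frozenset(zip(rows.tolist(), cols.tolist())), region_id=rid))
    return AnnotationSet(regions=tuple(regions), image_shape=arr.shape)


def read_box_annotations(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> AnnotationSet:
    """Read bounding boxes from a CSV with x_min, y_min, x_max, y_max columns.

    x is the column coordinate, y the row; bounds are inclusive.
    """
    df = pd.read_csv(path)
    regions = []
    for rid, rec in enumerate(df.itertuples(index=False), start=1):
        regions.append(Region(
            box=(int(rec.y_min), int(rec.x_min), int(rec.y_max), int(rec.x_max)),
            region_id=rid,
        ))
    return AnnotationSet(regions=tuple(regions), image_shape=image_shape)


def _spot_hits_region(spot: Spot, reg: Region) -> bool:
    r0, c0, r1, c1 = reg.bounds()
    sr0, sc0, sr1, sc1 = spot.bbox
    if sr1 < r0 or sr0 > r1 or sc1 < c0 or sc0 > c1:
        return False
    return any(reg.contains(r, c) for r, c in spot.pixels)


def match_lesions(
    spots: Sequence[Spot],
    candidates_rejected: Sequence[Spot],
    annotations: AnnotationSet,
) -> ConfusionCounts:
    """Lesion-level confusion counts for one image.

    ``spots`` are the detected lesion clusters, ``candidates_rejected``
    the boundary-pixel clusters that were *not* labeled lesion (the
    negatives the specificity is measured on).
    """
    tp = sum(1 for reg in annotations.regions
             if any(_spot_hits_region(s, reg) for s in spots))
    fn = len(annotations.regions) - tp
    fp = sum(1 for s in spots
             if not any(_spot_hits_region(s, reg) for reg in annotations.regions))
    tn = sum(1 for s in candidates_rejected
             if not any(_spot_hits_region(s, reg) for reg in annotations.regions))
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """SE = TP/(TP+FN), SP = TN/(TN+FP); None where the denominator is 0."""
    return c.se, c.sp


def partition_candidate_spots(
    boundaries: BoundarySet,
    lesions: LesionPixelSet,
    linking_radius: int = 10,
) -> tuple[list[Spot], list[Spot]]:
    """Cluster detected lesion pixels and rejected boundary pixels into spots."""
    detected = cluster_spots(lesions.pixels, linking_radius)
    rejected = cluster_spots(boundaries.p - lesions.pixels, linking_radius)
    return detected, rejected


def _spot_from_pixels(pixels) -> Spot:
    members = sorted(pixels)
    rows = [r for r, _ in members]
    cols = [c for _, c in members]
    return Spot(pixels=tuple(members),
                centroid=(float(np.mean(rows)), float(np.mean(cols))),
                bbox=(min(rows), min(cols), max(rows), max(cols)))


def label_candidates(
    candidates: Sequence[Spot], lesion_pixels: frozenset
) -> tuple[list[Spot], list[Spot]]:
    """Split a fixed candidate pool into detected and rejected spots.

    A candidate (a cluster of boundary pixels) is *detected* when at
    least one of its pixels was labeled a red-lesion boundary pixel, and
    keeps its full footprint for matching.  Keeping the pool fixed while
    only the labels change makes threshold sweeps behave monotonically:
    candidates can only flip from detected to rejected as the
    dark-window test tightens, so TP/FP can only fall and TN only rise.
    """
    detected, rejected = [], []
    for cand in candidates:
        if any(p in lesion_pixels for p in cand.pixels):
            detected.append(cand)
        else:
            rejected.append(cand)
    return detected, rejected


def _trapezoid_auc(points: Sequence[tuple[float, float]]) -> float:
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.trapezoid(ys, xs))


def roc_by_td(
    images: Sequence[tuple[PreprocessedImage, AnnotationSet]],
    td_grid: Sequence[float],
    cfg: LesionConfig = LesionConfig(),
    boundary_cfg: BoundaryConfig = BoundaryConfig(),
    d_0_scales: Sequence[int] = (10, 16, 22),
    linking_radius: int | None = None,
    use_fov: bool = False,
) -> RocCurve:
    """ROC curve by sweeping the dark-window threshold T_D.

    Boundary detection does not depend on T_D and is computed once per
    image, as is the candidate-spot pool (clusters of boundary pixels);
    lesion extraction is rerun per grid value, relabels the fixed
    candidates, and confusion counts are pooled over all images.
    """
    td_grid = [float(t) for t in td_grid]
    if sorted(td_grid) != td_grid:
        raise ValueError("td_grid must be sorted ascending")
    for td in td_grid:
        if not (cfg.t_l < td <= 1.0):
            raise ValueError(f"T_D grid value {td} not in (T_L={cfg.t_l}, 1]")
    radius = min(d_0_scales) if linking_radius is None else linking_radius
    cached = []
    for img, ann in images:
        bset = compute_boundaries(img, boundary_cfg, use_fov=use_fov)
        candidates = cluster_spots(bset.p, radius)
        cached.append((img, ann, bset, candidates))
    points = []
    for td in td_grid:
        total = ConfusionCounts(0, 0, 0, 0)
        for img, ann, bset, candidates in cached:
            lesions = extract_lesions_multiscale(
                img, bset, cfg.replace(t_d=td), d_0_scales)
            detected, rejected = label_candidates(candidates, lesions.pixels)
            total = total + match_lesions(detected, rejected, ann)
        se = total.se if total.se is not None else 0.0
        sp = total.sp if total.sp is not None else 1.0
        points.append((1.0 - sp, se))
    return RocCurve(
        td_values=tuple(td_grid),
        points=tuple(points),
        auc=_trapezoid_auc(points),
    )
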