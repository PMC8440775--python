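"""Synthetic fundus-like scenes with exact ground truth.

A scene emulates the structures the detector must tell apart: a bright
quasi-uniform background, dark compact circular blobs (red lesions),
dark elongated strips along polylines (vessels) and one bright square
crossed by dark lines (the optic disc), plus additive Gaussian noise.
Blobs and vessels are rendered with uniform depth and a one-pixel
anti-aliased rim so that window dark-pixel fractions are analytically
predictable; the rendered image doubles as a pre-processed intensity
grid (values in [0, 1]) and feeds the pipeline unchanged.

Every scene is bit-exactly reproducible from its seed, and ground-truth
lesion regions / vessel masks are derived from the noiseless render, so
evaluation against "truth" is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluate import AnnotationSet, Region
from .optic_disc import DiscZone
from .preprocess import PreprocessedImage

__all__ = ["Blob", "Vessel", "DiscSpec", "SceneSpec", "SceneTruth",
           "generate_scene", "scene_battery"]


class SceneValidationError(ValueError):
    """Scene geometry is out of bounds, overlapping, or not dark enough."""


@dataclass(frozen=True)
class Blob:
    """A filled disc of uniform depth: center (row, col), radius, depth."""

    center: tuple[float, float]
    radius: float
    depth: float


@dataclass(frozen=True)
class Vessel:
    """A strip of half-width width/2 swept along a control polyline."""

    control_points: tuple[tuple[float, float], ...]
    width: float
    depth: float


@dataclass(frozen=True)
class DiscSpec:
    """Bright square of side ``side`` crossed by dark lines."""

    center: tuple[float, float]
    side: int
    brightness: float = 0.98
    n_crossing_lines: int = 3
    line_width: float = 4.0
    line_depth: float = 0.85


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (384, 500)
    background_level: float = 0.85
    noise_sd: float = 0.02
    blobs: tuple[Blob, ...] = ()
    vessels: tuple[Vessel, ...] = ()
    disc: DiscSpec | None = None
    seed: int = 0
    t_dp_ref: float = 0.2  # dark-pixel threshold the structures must undercut


@dataclass(frozen=True)
class SceneTruth:
    image: np.ndarray  # noisy render, [0, 1]
    noiseless: np.ndarray
    lesion_regions: AnnotationSet
    vessel_mask: np.ndarray
    disc_zone: DiscZone | None
    spec: SceneSpec

    def as_preprocessed(self) -> PreprocessedImage:
        return PreprocessedImage.from_array(self.image, synthetic=True,
                                            seed=self.spec.seed)


def _blob_coverage(shape, blob: Blob) -> np.ndarray:
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]]
    dist = np.hypot(rr - blob.center[0], cc - blob.center[1])
    return np.clip(blob.radius + 0.5 - dist, 0.0, 1.0)


def _segment_distance(rr, cc, p0, p1) -> np.ndarray:
    v = np.array(p1, float) - np.array(p0, float)
    L2 = float(v @ v)
    dr = rr - p0[0]
    dc = cc - p0[1]
    if L2 == 0.0:
        return np.hypot(dr, dc)
    t = np.clip((dr * v[0] + dc * v[1]) / L2, 0.0, 1.0)
    return np.hypot(dr - t * v[0], dc - t * v[1])


def _vessel_coverage(shape, vessel: Vessel) -> np.ndarray:
    rr, cc = np.mgrid[0: shape[0], 0: shape[1]].astype(float)
    dist = np.full(shape, np.inf)
    pts = vessel.control_points
    for p0, p1 in zip(pts[:-1], pts[1:]):
        dist = np.minimum(dist, _segment_distance(rr, cc, p0, p1))
    return np.clip(vessel.width / 2.0 + 0.5 - dist, 0.0, 1.0)


def _render_disc(img: np.ndarray, disc: DiscSpec) -> tuple[int, int]:
    m, n = img.shape
    top = int(round(disc.center[0] - disc.side / 2.0))
    left = int(round(disc.center[1] - disc.side / 2.0))
    if top < 0 or left < 0 or top + disc.side > m or left + disc.side > n:
        raise SceneValidationError("disc square outside the image")
    sl = (slice(top, top + disc.side), slice(left, left + disc.side))
    img[sl] = disc.brightness
    rr, cc = np.mgrid[sl].astype(float)
    rng_like = np.linspace(0.0, np.pi, disc.n_crossing_lines, endpoint=False)
    for angle in rng_like + np.pi / 7.0:  # avoid axis-aligned degeneracy
        # distance to the infinite line through the disc center at `angle`
        nr, nc = -np.sin(angle), np.cos(angle)
        dist = np.abs((rr - disc.center[0]) * nc - (cc - disc.center[1]) * nr)
        cov = np.clip(disc.line_width / 2.0 + 0.5 - dist, 0.0, 1.0)
        img[sl] = np.minimum(img[sl], disc.brightness - disc.line_depth * cov)
    return top, left


def _validate(spec: SceneSpec, blob_covs, vessel_covs, disc_corner) -> None:
    m, n = spec.shape
    margin_dark = spec.background_level - spec.t_dp_ref + 3.0 * spec.noise_sd
    for blob in spec.blobs:
        r0, c0 = blob.center
        if not (blob.radius <= r0 <= m - 1 - blob.radius
                and blob.radius <= c0 <= n - 1 - blob.radius):
            raise SceneValidationError(f"blob at {blob.center} out of bounds")
        if blob.depth <= margin_dark:
            raise SceneValidationError(
                f"blob depth {blob.depth} too shallow: interior would not stay "
                f"below T_dp={spec.t_dp_ref} at 3 sigma noise")
    for vessel in spec.vessels:
        if vessel.depth <= margin_dark:
            raise SceneValidationError("vessel depth too shallow for T_dp")
    supports = [cov > 0 for cov in blob_covs]
    vsupport = np.zeros(spec.shape, dtype=bool)
    for cov in vessel_covs:
        vsupport |= cov > 0
    for a in range(len(supports)):
        if (supports[a] & vsupport).any():
            raise SceneValidationError(f"blob {a} overlaps a vessel")
        for b in range(a + 1, len(supports)):
            if (supports[a] & supports[b]).any():
                raise SceneValidationError(f"blobs {a} and {b} overlap")
    if disc_corner is not None and spec.disc is not None:
        top, left = disc_corner
        side = spec.disc.side
        box = np.zeros(spec.shape, dtype=bool)
        box[top: top + side, left: left + side] = True
        for idx, sup in enumerate(supports):
            if (sup & box).any():
                raise SceneValidationError(f"blob {idx} overlaps the disc square")
        if (vsupport & box).any():
            raise SceneValidationError("a vessel crosses the disc square")


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Render a scene and derive its ground truth (deterministic per seed)."""
    m, n = spec.shape
    img = np.full((m, n), spec.background_level, dtype=np.float64)

    disc_corner = None
    if spec.disc is not None:
        disc_corner = _render_disc(img, spec.disc)

    blob_covs = [_blob_coverage(spec.shape, b) for b in spec.blobs]
    vessel_covs = [_vessel_coverage(spec.shape, v) for v in spec.vessels]
    _validate(spec, blob_covs, vessel_covs, disc_corner)

    for blob, cov in zip(spec.blobs, blob_covs):
        img -= blob.depth * cov
    for vessel, cov in zip(spec.vessels, vessel_covs):
        img -= vessel.depth * cov
    noiseless = np.clip(img, 0.0, 1.0)

    rng = np.random.default_rng(spec.seed)
    noisy = noiseless + rng.normal(0.0, spec.noise_sd, size=noiseless.shape) \
        if spec.noise_sd > 0 else noiseless.copy()
    noisy = np.clip(noisy, 0.0, 1.0)

    regions = []
    for rid, cov in enumerate(blob_covs, start=1):
        dark = (cov > 0) & (noiseless < spec.t_dp_ref)
        rows, cols = np.nonzero(dark)
        regions.append(Region(
            pixels=frozenset(zip(rows.tolist(), cols.tolist())), region_id=rid))
    vessel_mask = np.zeros(spec.shape, dtype=bool)
    for cov in vessel_covs:
        vessel_mask |= cov > 0.5

    disc_zone = None
    if disc_corner is not None:
        disc_zone = DiscZone(top_row=disc_corner[0], left_col=disc_corner[1],
                             size=spec.disc.side, score=0.0)
    return SceneTruth(
        image=noisy,
        noiseless=noiseless,
        lesion_regions=AnnotationSet(regions=tuple(regions), image_shape=spec.shape),
        vessel_mask=vessel_mask,
        disc_zone=disc_zone,
        spec=spec,
    )


def _line_through(point, angle_deg, shape) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of the chord through ``point`` at ``angle_deg`` (measured
    from the column axis), clipped to the image rectangle."""
    theta = np.radians(angle_deg)
    drow, dcol = -np.sin(theta), np.cos(theta)
    t_lo, t_hi = -np.inf, np.inf
    for p, d, hi in ((point[0], drow, shape[0] - 1.0),
                     (point[1], dcol, shape[1] - 1.0)):
        if abs(d) < 1e-12:
            continue
        t0, t1 = (0.0 - p) / d, (hi - p) / d
        t_lo = max(t_lo, min(t0, t1))
        t_hi = min(t_hi, max(t0, t1))
    p0 = (point[0] + t_lo * drow, point[1] + t_lo * dcol)
    p1 = (point[0] + t_hi * drow, point[1] + t_hi * dcol)
    return p0, p1


def _point_line_distance(point, line_point, angle_deg) -> float:
    theta = np.radians(angle_deg)
    drow, dcol = -np.sin(theta), np.cos(theta)
    dr = point[0] - line_point[0]
    dc = point[1] - line_point[1]
    return abs(dr * dcol - dc * drow)


def scene_battery(
    n_scenes: int,
    master_seed: int,
    shape: tuple[int, int] = (384, 500),
    n_blobs: int = 5,
    radius_range: tuple[float, float] = (3.0, 15.0),
    width_range: tuple[float, float] = (3.0, 12.0),
    noise_sd: float = 0.02,
    disc_side: int = 60,
    clearance: float = 50.0,
    n_vessels: int = 1,
) -> list[SceneTruth]:
    """Generate ``n_scenes`` varied scenes with reproducible derived seeds.

    Each scene holds one straight vessel at a (deterministically) varied
    orientation spanning the frame, ``n_blobs`` isolated blobs with radii
    spanning ``radius_range``, and one randomly placed line-crossed disc
    square.  ``clearance`` keeps blobs away from vessels, the disc and
    each other so that the flanking windows of a blob measure pure
    background — the regime the window-chain rule is designed for.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    master = np.random.default_rng(master_seed)
    scenes = []
    for s in range(n_scenes):
        seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        m, n = shape
        bg = 0.85
        # disc square placed randomly but, as in a real fundus photograph,
        # well inside the frame (the disc never touches the aperture rim)
        half = disc_side / 2.0
        disc_center = (
            float(rng.uniform(3 * half, m - 3 * half)),
            float(rng.uniform(3 * half, n - 3 * half)),
        )
        disc = DiscSpec(center=disc_center, side=disc_side)
        # straight vessels spanning the frame, orientations varied over
        # 0-180 degrees; resampled until they clear the disc square
        vessels: list[Vessel] = []
        vessel_lines: list[tuple[tuple[float, float], float, float]] = []
        for _ in range(n_vessels):
            width = float(rng.uniform(*width_range))
            for _ in range(200):
                angle = float(rng.uniform(0.0, 180.0))
                anchor = (float(rng.uniform(0.15 * m, 0.85 * m)),
                          float(rng.uniform(0.15 * n, 0.85 * n)))
                d_disc = _point_line_distance(disc_center, anchor, angle)
                if d_disc > half * np.sqrt(2.0) + width / 2.0 + 10.0:
                    break
            vessels.append(Vessel(control_points=_line_through(anchor, angle, shape),
                                  width=width, depth=float(rng.uniform(0.72, 0.8))))
            vessel_lines.append((anchor, angle, width))
        # isolated blobs
        blobs: list[Blob] = []
        lo, hi = radius_range
        radii = [float(rng.uniform(lo, hi)) for _ in range(n_blobs)]
        for radius in radii:
            margin = radius + 30.0
            for _ in range(500):
                center = (float(rng.uniform(margin, m - margin)),
                          float(rng.uniform(margin, n - margin)))
                if any(_point_line_distance(center, a2, g2) <
                       radius + w2 / 2.0 + clearance
                       for a2, g2, w2 in vessel_lines):
                    continue
                dr = abs(center[0] - disc_center[0])
                dc = abs(center[1] - disc_center[1])
                if max(dr, dc) < half + radius + clearance:
                    continue
                if any(np.hypot(center[0] - b.center[0], center[1] - b.center[1])
                       < radius + b.radius + clearance for b in blobs):
                    continue
                blobs.append(Blob(center=center, radius=radius,
                                  depth=float(rng.uniform(0.72, 0.8))))
                break
        spec = SceneSpec(
            shape=shape, background_level=bg, noise_sd=noise_sd,
            blobs=tuple(blobs), vessels=tuple(vessels), disc=disc, seed=seed,
        )
        scenes.append(generate_scene(spec))
    return scenes
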