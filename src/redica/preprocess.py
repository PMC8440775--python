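"""Pre-processing: green-channel extraction, CLAHE, field-of-view mask.

The green channel of a color fundus photograph carries the best contrast
between the retinal background and dark structures (vessels, red
lesions); contrast-limited adaptive histogram equalization (CLAHE) with a
uniform target distribution then amplifies local contrast without
over-boosting noise.  All downstream stages operate on the resulting
single-channel [0, 1] grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = [
    "FundusImage",
    "PreprocessedImage",
    "load_image",
    "load_preprocessed",
    "extract_green",
    "apply_clahe",
    "compute_fov_mask",
    "preprocess",
]


class ImageFormatError(ValueError):
    """Raised when an input raster is not a 3-channel color image."""


@dataclass(frozen=True)
class FundusImage:
    """An RGB fundus photograph with values scaled to [0, 1]."""

    pixels: np.ndarray  # (m, n, 3) float64 in [0, 1]
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ImageFormatError(
                f"expected a 3-channel image, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ImageFormatError("empty image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class PreprocessedImage:
    """Single-channel intensity grid in [0, 1] with a field-of-view mask.

    ``intensity[i, j]`` is the value X_{i,j} of pixel p_{i,j} (0-based,
    origin at the top-left).  ``fov_mask`` is True inside the retinal
    field of view; full-frame synthetic scenes carry an all-True mask.
    """

    intensity: np.ndarray
    fov_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D")
        if self.fov_mask.shape != self.intensity.shape:
            raise ValueError("fov_mask shape must match intensity shape")
        lo, hi = float(self.intensity.min()), float(self.intensity.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensity outside [0, 1]: min={lo}, max={hi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, fov_mask: np.ndarray | None = None,
                   **provenance) -> "PreprocessedImage":
        """Wrap an already-preprocessed [0, 1] grid (e.g. a synthetic scene)."""
        arr = np.asarray(arr, dtype=np.float64)
        if fov_mask is None:
            fov_mask = np.ones(arr.shape, dtype=bool)
        return cls(intensity=arr, fov_mask=np.asarray(fov_mask, dtype=bool),
                   provenance=dict(provenance))


def load_image(path: str | Path) -> FundusImage:
    """Load a PNG/TIFF/JPEG raster as an RGB fundus image scaled to [0, 1].

    Single-channel (grayscale) rasters are rejected: channel selection is a
    meaningful step of the method and must not be silently skipped.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ImageFormatError(
            f"{path} has 1 channel; a 3-channel color image is required"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"{path} has shape {arr.shape}; a 3-channel color image is required"
        )
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        pixels = arr.astype(np.float64) / scale
    else:
        pixels = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return FundusImage(pixels=pixels, source_path=str(path))


def load_preprocessed(path: str | Path) -> PreprocessedImage:
    """Load a single-channel raster as an already-preprocessed intensity grid.

    For inputs that have no color channels and need no equalization — such
    as synthetic scenes, which are rendered directly as [0, 1] intensity
    grids.  Integer rasters are scaled by their dtype maximum; the field of
    view is the full frame.
    """
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ImageFormatError(
            f"{path} has shape {arr.shape}; a single-channel raster is required"
        )
    if np.issubdtype(arr.dtype, np.integer):
        intensity = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    else:
        intensity = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return PreprocessedImage.from_array(intensity, source=str(path))


def extract_green(img: FundusImage) -> np.ndarray:
    """Return the green channel as an m x n grid in [0, 1]."""
    return np.ascontiguousarray(img.pixels[:, :, 1])


def apply_clahe(
    green: np.ndarray,
    clip_limit: float = 0.02,
    tiles: tuple[int, int] = (8, 8),
    fov_mask: np.ndarray | None = None,
) -> PreprocessedImage:
    """Contrast-limited adaptive histogram equalization (uniform distribution).

    ``clip_limit`` is the normalized clipping fraction of the local
    histogram (default 0.02); ``tiles`` the contextual-region grid.
    Deterministic: identical input and parameters give identical output.
    """
    if clip_limit <= 0:
        raise ValueError(f"clip_limit must be positive, got {clip_limit}")
    green = np.asarray(green, dtype=np.float64)
    m, n = green.shape
    kernel = (max(1, m // tiles[0]), max(1, n // tiles[1]))
    out = exposure.equalize_adapthist(green, kernel_size=kernel, clip_limit=clip_limit)
    out = np.clip(out, 0.0, 1.0)
    if fov_mask is None:
        fov_mask = np.ones(out.shape, dtype=bool)
    return PreprocessedImage(
        intensity=out,
        fov_mask=fov_mask,
        provenance={"clip_limit": clip_limit, "distribution": "uniform",
                    "tiles": tuple(tiles)},
    )


def compute_fov_mask(green: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Estimate the retinal field of view (the bright aperture disc).

    Pixels brighter than ``threshold`` are kept; the largest connected
    bright component is selected and its holes filled.  A full-frame
    bright image yields an all-True mask; an all-dark image all-False.
    """
    green = np.asarray(green, dtype=np.float64)
    bright = green > threshold
    if not bright.any():
        return np.zeros(green.shape, dtype=bool)
    labels, n_comp = ndimage.label(bright)
    if n_comp > 1:
        sizes = ndimage.sum_labels(bright, labels, index=np.arange(1, n_comp + 1))
        keep = 1 + int(np.argmax(sizes))
        bright = labels == keep
    return ndimage.binary_fill_holes(bright)


def preprocess(
    path: str | Path,
    clip_limit: float = 0.02,
    tiles: tuple[int, int] = (8, 8),
    use_fov: bool = True,
    fov_threshold: float = 0.05,
) -> PreprocessedImage:
    """Load a fundus photograph and run the full pre-processing stage."""
    img = load_image(path)
    green = extract_green(img)
    fov = compute_fov_mask(green, fov_threshold) if use_fov else None
    return apply_clahe(green, clip_limit=clip_limit, tiles=tiles, fov_mask=fov)
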