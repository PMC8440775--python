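"""Parameter containers for the red-lesion extraction pipeline.

All intensities are floating point on the [0, 1] scale; every threshold
below is interpreted on that scale.  Defaults follow the published
operating point of the method (window span ``s_w = 5``, difference
threshold ``th_Diff = 0.12``, patch width ``d_0 = 10``, dark-pixel
threshold ``T_dp = 0.2``, dark/light window fractions ``T_D = 0.7`` /
``T_L = 0.4``, disc square ``d_od = 180`` with grid stride ``r_d = 10``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "BoundaryConfig",
    "LesionConfig",
    "DiscConfig",
    "PipelineConfig",
]


@dataclass(frozen=True)
class BoundaryConfig:
    """Parameters of the boundary-pixel determination stage.

    s_w : odd span (pixels) of the diamond neighborhood used for local
        intensity averaging.
    th_diff : minimum directional difference for a local maximum to be
        kept as a boundary pixel.
    """

    s_w: int = 5
    th_diff: float = 0.12

    def __post_init__(self) -> None:
        if self.s_w < 3 or self.s_w % 2 == 0:
            raise ValueError(f"s_w must be odd and >= 3, got {self.s_w}")
        if self.th_diff < 0:
            raise ValueError(f"th_diff must be >= 0, got {self.th_diff}")


@dataclass(frozen=True)
class LesionConfig:
    """Parameters of the window-chain red-lesion discrimination stage.

    d_0 : side (pixels) of the square neighborhood windows.
    r : step between consecutive windows along a chain; ``None`` means
        ``d_0`` (flanking windows exactly adjacent to the center window).
    num : number of flanking windows on each side of the center window.
    t_dp : intensity below which a pixel counts as dark.
    t_d : dark-pixel fraction above which a window is *dark*.
    t_l : dark-pixel fraction below which a window is *light*; fractions
        in ``[t_l, t_d]`` are *neither* and fail both labels.
    angles_first_quarter / angles_second_quarter : chain directions in
        degrees tested for boundary pixels of the 135° / 45° families;
        direction 0 is always tested.  90° is excluded (tan undefined).
    """

    d_0: int = 10
    r: int | None = None
    num: int = 1
    t_dp: float = 0.2
    t_d: float = 0.7
    t_l: float = 0.4
    angles_first_quarter: tuple[float, ...] = (30.0, 45.0, 60.0)
    angles_second_quarter: tuple[float, ...] = (120.0, 135.0, 150.0)

    def __post_init__(self) -> None:
        if self.d_0 < 2:
            raise ValueError(f"d_0 must be >= 2, got {self.d_0}")
        if self.num < 1:
            raise ValueError(f"num must be >= 1, got {self.num}")
        if not (0.0 < self.t_dp < 1.0):
            raise ValueError(f"t_dp must be in (0, 1), got {self.t_dp}")
        if not (0.0 <= self.t_l < self.t_d <= 1.0):
            raise ValueError(
                f"need 0 <= t_l < t_d <= 1, got t_l={self.t_l}, t_d={self.t_d}"
            )
        for theta in (*self.angles_first_quarter, *self.angles_second_quarter):
            if theta == 90.0:
                raise ValueError("direction 90 degrees is not allowed (tan undefined)")
        for theta in self.angles_first_quarter:
            if not (0.0 < theta < 90.0):
                raise ValueError(f"first-quarter angle {theta} outside (0, 90)")
        for theta in self.angles_second_quarter:
            if not (90.0 < theta < 180.0):
                raise ValueError(f"second-quarter angle {theta} outside (90, 180)")

    @property
    def step(self) -> int:
        """Effective inter-window step (``r`` defaulting to ``d_0``)."""
        return self.d_0 if self.r is None else self.r

    def replace(self, **kwargs) -> "LesionConfig":
        d = asdict(self)
        d["angles_first_quarter"] = self.angles_first_quarter
        d["angles_second_quarter"] = self.angles_second_quarter
        d.update(kwargs)
        return LesionConfig(**d)


@dataclass(frozen=True)
class DiscConfig:
    """Parameters of the variance-based optic-disc localization.

    d_od : side (pixels) of the candidate disc square.
    r_d : stride of the test-square grid.
    alpha : percentage of top-variance test-squares averaged to place the
        final square.
    max_fov_outside : test-squares with a larger fraction of pixels
        outside the field of view are excluded from ranking.
    """

    d_od: int = 180
    r_d: int = 10
    alpha: float = 5.0
    max_fov_outside: float = 0.2

    def __post_init__(self) -> None:
        if not (1 <= self.r_d <= self.d_od):
            raise ValueError(f"need 1 <= r_d <= d_od, got r_d={self.r_d}, d_od={self.d_od}")
        if not (0.0 < self.alpha <= 100.0):
            raise ValueError(f"alpha must be in (0, 100], got {self.alpha}")


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration.

    ``d_0_scales`` lists the window widths run independently and unioned
    (multi-scale detection of small and large lesions).  ``use_fov``
    gates the field-of-view mask: on for real fundus photographs with a
    dark aperture rim, off for synthetic full-frame scenes.
    """

    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    lesion: LesionConfig = field(default_factory=LesionConfig)
    disc: DiscConfig = field(default_factory=DiscConfig)
    d_0_scales: tuple[int, ...] = (10, 16, 22)
    clip_limit: float = 0.02
    clahe_tiles: tuple[int, int] = (8, 8)
    use_fov: bool = True
    fov_threshold: float = 0.05
    linking_radius: int | None = None  # None -> smallest d_0 scale
    disc_filter: bool = True

    @property
    def effective_linking_radius(self) -> int:
        if self.linking_radius is not None:
            return self.linking_radius
        return min(self.d_0_scales)

    # -- flat YAML round trip; keys mirror the published parameter symbols --

    _YAML_KEYS = {
        "s_w": ("boundary", "s_w"),
        "th_Diff": ("boundary", "th_diff"),
        "d_0": (None, "d_0_scales"),
        "r": ("lesion", "r"),
        "num": ("lesion", "num"),
        "T_dp": ("lesion", "t_dp"),
        "T_D": ("lesion", "t_d"),
        "T_L": ("lesion", "t_l"),
        "angles_first_quarter": ("lesion", "angles_first_quarter"),
        "angles_second_quarter": ("lesion", "angles_second_quarter"),
        "d_od": ("disc", "d_od"),
        "r_d": ("disc", "r_d"),
        "alpha": ("disc", "alpha"),
        "clip_limit": (None, "clip_limit"),
        "use_fov": (None, "use_fov"),
        "disc_filter": (None, "disc_filter"),
    }

    def to_yaml(self, path: str | Path) -> None:
        flat = {
            "s_w": self.boundary.s_w,
            "th_Diff": self.boundary.th_diff,
            "d_0": list(self.d_0_scales),
            "r": self.lesion.r,
            "num": self.lesion.num,
            "T_dp": self.lesion.t_dp,
            "T_D": self.lesion.t_d,
            "T_L": self.lesion.t_l,
            "angles_first_quarter": list(self.lesion.angles_first_quarter),
            "angles_second_quarter": list(self.lesion.angles_second_quarter),
            "d_od": self.disc.d_od,
            "r_d": self.disc.r_d,
            "alpha": self.disc.alpha,
            "clip_limit": self.clip_limit,
            "use_fov": self.use_fov,
            "disc_filter": self.disc_filter,
        }
        Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        flat = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(flat) - set(cls._YAML_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        b: dict = {}
        l: dict = {}
        d: dict = {}
        top: dict = {}
        groups = {"boundary": b, "lesion": l, "disc": d, None: top}
        for key, value in flat.items():
            group, attr = cls._YAML_KEYS[key]
            if isinstance(value, list):
                value = tuple(value)
            groups[group][attr] = value
        return cls(
            boundary=BoundaryConfig(**b),
            lesion=LesionConfig(**l),
            disc=DiscConfig(**d),
            **top,
        )
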