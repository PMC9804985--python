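"""Core containers shared across the pipeline.

Conventions: pixel grids are row-major 2D numpy arrays with 0-based indices;
physical sizes are micrometres (``pixel_size`` is um/pixel) and areas are
converted to um^2 before any size filter so configurations transfer across
magnifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

IF_CHANNELS = ("dapi", "synaptophysin", "insulin")


class NoTissueError(ValueError):
    """Raised when an image contains no detectable tissue."""


@dataclass
class MultiChannelImage:
    """A 2D fluorescence field with named channels.

    Channels are stored as non-negative float arrays on the intensity scale
    implied by ``bit_depth`` (0..2**bit_depth - 1); integer inputs are
    converted.  All channels must share one shape.
    """

    channels: Mapping[str, np.ndarray]
    pixel_size: float  # um / pixel
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        chans = {}
        shape = None
        for name, arr in dict(self.channels).items():
            a = np.asarray(arr, dtype=np.float64)
            if a.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError("channels do not share one shape")
            if a.min() < 0:
                raise ValueError(f"channel {name!r} has negative intensities")
            chans[name] = a
        if not chans:
            raise ValueError("image has no channels")
        object.__setattr__(self, "channels", chans)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def max_value(self) -> float:
        return float(2**self.bit_depth - 1)

    def channel_sum(self) -> np.ndarray:
        return np.sum(list(self.channels.values()), axis=0)

    def pixel_area(self) -> float:
        """Area of one pixel in um^2."""
        return self.pixel_size**2


@dataclass
class SegmentationConfig:
    """Parameters controlling tissue / islet / insulin mask extraction.

    Lengths are um, areas um^2 and intensities are on the image scale; this
    keeps one config valid across magnifications.
    """

    blur_sigma: float = 1.0  # um, smoothing before tissue thresholding
    tissue_threshold_method: str = "otsu_capped"  # otsu_capped | triangle | otsu | fixed
    tissue_fixed_threshold: float = 10.0
    islet_threshold_method: str = "otsu"  # otsu | fixed
    islet_fixed_threshold: float = 50.0
    insulin_threshold_method: str = "otsu"  # otsu | fixed
    insulin_fixed_threshold: float = 50.0
    closing_radius: float = 2.0  # um
    min_islet_area: float = 300.0  # um^2; rejects stray single positive cells
    min_tissue_area: float = 5000.0  # um^2
    background_subtraction: str = "none"  # none | median | rolling_ball
    background_radius: float = 50.0  # um, for rolling_ball
    dab_od_threshold: float = 0.15  # OD units
    min_contrast_sd: float = 4.0  # Otsu guard: required class separation
    exclude_border_islets: bool = False

    _THRESHOLD_METHODS = {"otsu_capped", "triangle", "otsu", "fixed"}
    _BG_METHODS = {"none", "median", "rolling_ball"}

    def __post_init__(self) -> None:
        if self.tissue_threshold_method not in self._THRESHOLD_METHODS:
            raise ValueError(
                f"unknown tissue_threshold_method {self.tissue_threshold_method!r}"
            )
        if self.islet_threshold_method not in {"otsu", "fixed"}:
            raise ValueError(
                f"unknown islet_threshold_method {self.islet_threshold_method!r}"
            )
        if self.insulin_threshold_method not in {"otsu", "fixed"}:
            raise ValueError(
                f"unknown insulin_threshold_method {self.insulin_threshold_method!r}"
            )
        if self.background_subtraction not in self._BG_METHODS:
            raise ValueError(
                f"unknown background_subtraction {self.background_subtraction!r}"
            )
        for name in ("blur_sigma", "closing_radius", "min_islet_area",
                     "min_tissue_area", "background_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MaskSet:
    """Nested binary masks produced by segmentation of one IF image.

    The nesting invariant insulin_positive <= islet <= tissue holds pixelwise
    and is checked on construction.
    """

    tissue: np.ndarray
    islet: np.ndarray
    insulin_positive: np.ndarray
    config_used: SegmentationConfig | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.tissue, dtype=bool)
        i = np.asarray(self.islet, dtype=bool)
        b = np.asarray(self.insulin_positive, dtype=bool)
        if not (t.shape == i.shape == b.shape):
            raise ValueError("masks do not share one shape")
        if np.any(i & ~t):
            raise ValueError("islet mask is not contained in the tissue mask")
        if np.any(b & ~i):
            raise ValueError("insulin-positive mask is not contained in the islet mask")
        object.__setattr__(self, "tissue", t)
        object.__setattr__(self, "islet", i)
        object.__setattr__(self, "insulin_positive", b)


@dataclass(frozen=True)
class StainMatrix:
    """Three unit-norm optical-density vectors in RGB space.

    Rows are stains in the order (haematoxylin, DAB, AP-magenta); columns are
    R, G, B.  Chromogen contributions add linearly in OD space, so unmixing a
    brightfield tile is multiplication by the matrix inverse.
    """

    vectors: np.ndarray
    names: tuple[str, str, str] = ("haematoxylin", "dab", "ap_magenta")

    MAX_CONDITION = 1e6

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3 (stains x RGB)")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"stain vectors must be unit-norm, got norms {norms}")
        if np.linalg.cond(v) >= self.MAX_CONDITION:
            raise ValueError("stain matrix is not invertible (condition number too high)")
        object.__setattr__(self, "vectors", v)

    @classmethod
    def from_rows(cls, h, dab, ap, names=("haematoxylin", "dab", "ap_magenta")):
        """Build from three RGB OD directions, normalising each to unit length."""
        rows = np.array([h, dab, ap], dtype=np.float64)
        norms = np.linalg.norm(rows, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        return cls(rows / norms[:, None], tuple(names))

    @classmethod
    def default(cls) -> "StainMatrix":
        # Ruifrok & Johnston haematoxylin and DAB directions; the AP-magenta
        # direction (green-absorbing) matches the synthetic renderer and is
        # user-overridable since real kits vary.
        return cls.from_rows(
            h=(0.650, 0.704, 0.286),
            dab=(0.268, 0.570, 0.776),
            ap=(0.210, 0.950, 0.230),
        )

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)


@dataclass
class IsletMetrics:
    """Per-image read-outs: area fractions and insulin intensity statistics.

    Intensity fields are NaN (and ``islet_found`` False) when the image has
    no detected islet; missing values propagate, they are never silently
    zeroed.
    """

    image_id: str
    tissue_area: float  # um^2
    islet_area: float  # um^2
    islet_area_pct_of_tissue: float  # %
    insulin_pos_area_pct_of_islet: float  # % (NaN if no islet)
    insulin_integrated_intensity: float  # intensity * pixels
    insulin_mean_intensity: float  # per islet pixel
    background_intensity: float  # median insulin over tissue \ islet
    insulin_integrated_bgsub: float
    insulin_mean_bgsub: float
    islet_found: bool = True

    def __post_init__(self) -> None:
        if self.islet_area > self.tissue_area + 1e-9:
            raise ValueError("islet_area exceeds tissue_area")
        for name in ("islet_area_pct_of_tissue", "insulin_pos_area_pct_of_islet"):
            v = getattr(self, name)
            if np.isfinite(v) and not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"{name} outside [0, 100]: {v}")

    def to_dict(self) -> dict:
        return asdict(self)
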