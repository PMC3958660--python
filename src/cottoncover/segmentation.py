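"""Four-class pixel segmentation of canopy photographs.

Each pixel is labeled sunlit canopy (SC), shaded canopy (ShC), sunlit soil
(SS) or shaded soil (ShS). A pixel is canopy when green dominates both red
and blue by configurable margins; the sunlit/shaded split within each class
is a brightness threshold on R+G+B. Canopy cover is the canopy pixel
fraction

    CC = P_SC + P_ShC,      P_SC + P_ShC + P_SS + P_ShS = 1,

so CC depends only on the canopy/soil decision, never on the brightness
thresholds that split sunlit from shaded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .image_io import RGBImage

__all__ = [
    "PixelClass",
    "ThresholdConfig",
    "SegmentationMap",
    "ClassFractions",
    "classify_pixel",
    "segment_image",
    "class_fractions",
    "canopy_cover_fraction",
]


class PixelClass(enum.IntEnum):
    """Pixel labels. Integer codes index the label axis of count arrays."""

    SC = 0   # sunlit canopy
    ShC = 1  # shaded canopy
    SS = 2   # sunlit soil
    ShS = 3  # shaded soil


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision-rule constants for the four-class segmentation.

    Attributes
    ----------
    green_over_red_margin, green_over_blue_margin : int
        A pixel is canopy only if G - R and G - B each meet these margins
        (inclusive: G - R exactly at the margin counts as canopy). Units
        are 8-bit channel counts.
    canopy_brightness_threshold : int
        R+G+B split between sunlit and shaded canopy.
    soil_brightness_threshold : int
        R+G+B split between sunlit and shaded soil (sunlit when strictly
        above).
    canopy_brightness_sunlit_below : bool
        If True (default), canopy pixels strictly below the canopy
        brightness threshold are labeled sunlit. This polarity reads oddly
        (sunlit leaves are usually brighter) but canopy cover is provably
        unaffected by it, so both polarities are supported.
    max_red_chromaticity : float or None
        Optional extra canopy requirement r/(r+g+b) < value. Disabled by
        default; a pure-black pixel never satisfies it (no division).
    """

    green_over_red_margin: int = 5
    green_over_blue_margin: int = 5
    canopy_brightness_threshold: int = 200
    soil_brightness_threshold: int = 250
    canopy_brightness_sunlit_below: bool = True
    max_red_chromaticity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.green_over_red_margin < 0 or self.green_over_blue_margin < 0:
            raise ValueError("greenness margins must be >= 0")
        for name in ("canopy_brightness_threshold", "soil_brightness_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 765:
                raise ValueError(f"{name} must be in [0, 765], got {v}")
        if self.max_red_chromaticity is not None and not (
            0 < self.max_red_chromaticity <= 1
        ):
            raise ValueError("max_red_chromaticity must be in (0, 1] or None")


@dataclass(frozen=True)
class SegmentationMap:
    """Per-pixel labels plus the configuration that produced them."""

    labels: np.ndarray  # H x W of PixelClass codes (uint8)
    config_used: ThresholdConfig

    @property
    def n_pixels(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class ClassFractions:
    """Proportions of the four pixel classes; they always sum to 1.

    When built from a segmentation map the raw pixel counts are kept so
    that canopy cover can be computed as an exact count ratio instead of
    a sum of two rounded fractions.
    """

    p_sc: float
    p_shc: float
    p_ss: float
    p_shs: float
    counts: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        total = self.p_sc + self.p_shc + self.p_ss + self.p_shs
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total!r}")
        for name in ("p_sc", "p_shc", "p_ss", "p_shs"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"{name} out of [0, 1]: {v}")


def _canopy_mask(
    r: np.ndarray, g: np.ndarray, b: np.ndarray, config: ThresholdConfig
) -> np.ndarray:
    canopy = (g - r >= config.green_over_red_margin) & (
        g - b >= config.green_over_blue_margin
    )
    if config.max_red_chromaticity is not None:
        total = r + g + b
        with np.errstate(invalid="ignore", divide="ignore"):
            red_chroma = np.where(total > 0, r / np.maximum(total, 1), 1.0)
        canopy &= red_chroma < config.max_red_chromaticity
    return canopy


def classify_pixel(
    r: int, g: int, b: int, config: ThresholdConfig | None = None
) -> PixelClass:
    """Classify a single (R, G, B) triplet.

    Raises a domain error for channel values outside [0, 255].
    """
    config = config or ThresholdConfig()
    for name, v in (("r", r), ("g", g), ("b", b)):
        if not (0 <= v <= 255) or int(v) != v:
            raise ValueError(f"channel {name}={v!r} is not an integer in [0, 255]")
    arr = np.array([[[r, g, b]]], dtype=np.int64)
    labels = _segment_array(arr, config)
    return PixelClass(int(labels[0, 0]))


def _segment_array(pixels: np.ndarray, config: ThresholdConfig) -> np.ndarray:
    px = pixels.astype(np.int64)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    brightness = r + g + b
    canopy = _canopy_mask(r, g, b, config)

    labels = np.empty(canopy.shape, dtype=np.uint8)
    if config.canopy_brightness_sunlit_below:
        canopy_sunlit = brightness < config.canopy_brightness_threshold
    else:
        canopy_sunlit = brightness >= config.canopy_brightness_threshold
    soil_sunlit = brightness > config.soil_brightness_threshold

    labels[canopy & canopy_sunlit] = PixelClass.SC
    labels[canopy & ~canopy_sunlit] = PixelClass.ShC
    labels[~canopy & soil_sunlit] = PixelClass.SS
    labels[~canopy & ~soil_sunlit] = PixelClass.ShS
    return labels


def segment_image(
    image: RGBImage, config: ThresholdConfig | None = None
) -> SegmentationMap:
    """Label every pixel of ``image``; deterministic and vectorized.

    Equivalent to mapping :func:`classify_pixel` over all pixels.
    """
    config = config or ThresholdConfig()
    labels = _segment_array(image.pixels, config)
    return SegmentationMap(labels=labels, config_used=config)


def class_fractions(segmap: SegmentationMap) -> ClassFractions:
    """Count-based proportions of the four classes; exact sum of 1."""
    n = segmap.n_pixels
    if n == 0:
        raise ValueError("cannot compute class fractions of an empty map")
    counts = np.bincount(segmap.labels.ravel(), minlength=4)
    p = counts / n
    return ClassFractions(
        p_sc=float(p[PixelClass.SC]),
        p_shc=float(p[PixelClass.ShC]),
        p_ss=float(p[PixelClass.SS]),
        p_shs=float(p[PixelClass.ShS]),
        counts=tuple(int(c) for c in counts),
    )


def canopy_cover_fraction(fractions: ClassFractions) -> float:
    """Canopy cover as the canopy pixel fraction: CC = P_SC + P_ShC.

    Computed from the pixel counts when available, so the result is the
    exact canopy-count ratio regardless of how the sunlit/shaded split
    rounded the individual fractions.
    """
    if fractions.counts is not None:
        sc, shc, ss, shs = fractions.counts
        return (sc + shc) / (sc + shc + ss + shs)
    return fractions.p_sc + fractions.p_shc
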