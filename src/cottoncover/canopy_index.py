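"""Canopy cover from the soil-adjusted green-red vegetation index.

The index treats the image's green and red bands as reflectance proxies
and adjusts for soil background the way SAVI-family indices do:

    CC = (1 + L) * (G - R) / (G + R + L)

with G and R on a [0, 1] scale (8-bit channel means divided by 255) and
soil baseline L, 0 for full canopy and 1 for bare soil; L = 0.5 is the
conventional intermediate value and the default. With L = 0 the index
reduces to the normalized green-red difference (G - R)/(G + R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import RGBImage

__all__ = ["IndexConfig", "canopy_cover_index"]

logger = logging.getLogger(__name__)

_BAND_STATISTICS = ("mean-of-bands", "per-pixel-mean")


@dataclass(frozen=True)
class IndexConfig:
    """Options for the green-red index.

    Attributes
    ----------
    soil_baseline_L : float
        Soil adjustment constant in [0, 1]; default 0.5.
    band_statistic : str
        ``"mean-of-bands"`` (default) computes band means first and one
        index per image, matching the single-G, single-R form of the
        definition; ``"per-pixel-mean"`` computes the index per pixel and
        averages, offered for sensitivity analysis.
    clip_to_unit : bool
        Canopy cover is defined on [0, 1]; by default out-of-range index
        values (red-dominant scenes) are clamped with a logged warning.
        Disable for diagnostics.
    """

    soil_baseline_L: float = 0.5
    band_statistic: str = "mean-of-bands"
    clip_to_unit: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.soil_baseline_L <= 1.0:
            raise ValueError(
                f"soil_baseline_L must be in [0, 1], got {self.soil_baseline_L}"
            )
        if self.band_statistic not in _BAND_STATISTICS:
            raise ValueError(
                f"band_statistic must be one of {_BAND_STATISTICS}, "
                f"got {self.band_statistic!r}"
            )


def canopy_cover_index(image: RGBImage, config: IndexConfig | None = None) -> float:
    """Canopy cover of ``image`` by the soil-adjusted green-red index."""
    config = config or IndexConfig()
    L = config.soil_baseline_L
    px = image.pixels.astype(np.float64) / 255.0
    r_band, g_band = px[..., 0], px[..., 1]

    if config.band_statistic == "mean-of-bands":
        g = float(g_band.mean())
        r = float(r_band.mean())
        denom = g + r + L
        if denom == 0.0:
            raise ValueError(
                "index undefined: G + R + L = 0 (all-black image with L = 0)"
            )
        cc = (1.0 + L) * (g - r) / denom
    else:
        denom = g_band + r_band + L
        if np.any(denom == 0.0):
            raise ValueError(
                "index undefined: G + R + L = 0 at some pixel with L = 0"
            )
        cc = float(((1.0 + L) * (g_band - r_band) / denom).mean())

    if config.clip_to_unit and not 0.0 <= cc <= 1.0:
        clipped = min(max(cc, 0.0), 1.0)
        logger.warning(
            "green-red index %.4f outside [0, 1] for image %r; clamped to %.1f",
            cc, image.source_id, clipped,
        )
        cc = clipped
    return cc
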