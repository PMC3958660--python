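"""Reading canopy photographs and writing per-image result tables.

Images are 8-bit RGB throughout the package (channel counts 0-255);
normalization to reflectance-like [0, 1] values happens only inside
:mod:`cottoncover.canopy_index`. Pixels are addressed row-major with the
origin at the top-left; no computed statistic depends on pixel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

__all__ = ["RGBImage", "ImageFormatError", "load_image", "write_cover_table"]


class ImageFormatError(ValueError):
    """Raised when a file decodes but is not an 8-bit color image."""


@dataclass(frozen=True)
class RGBImage:
    """An H x W grid of 8-bit (R, G, B) triplets.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        Channel counts in [0, 255], row-major, top-left origin.
    source_id : str
        Label carried into output tables (usually the file stem).
    """

    pixels: np.ndarray
    source_id: str = field(default="")

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ImageFormatError(
                f"expected an H x W x 3 array, got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ImageFormatError("image must contain at least one pixel")
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise ImageFormatError(
                    "channel values must be integers in [0, 255]"
                )
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def downsample(self, factor: int) -> "RGBImage":
        """Integer-factor decimation (every ``factor``-th row/column).

        A convenience for very large photographs; all package statistics
        are per-pixel, so this only trades resolution for speed.
        """
        if factor < 1 or int(factor) != factor:
            raise ValueError(f"downsample factor must be a positive integer, got {factor}")
        return RGBImage(self.pixels[::factor, ::factor], source_id=self.source_id)


def load_image(path: str | Path) -> RGBImage:
    """Load a JPEG or PNG photograph as an :class:`RGBImage`.

    An alpha channel, if present, is dropped. Grayscale or palette images
    without color information are rejected: the segmentation and index
    methods both require distinct R, G, B bands.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ImageFormatError
        If the file is not a decodable color image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode in ("L", "LA", "I", "I;16", "F", "1"):
                raise ImageFormatError(
                    f"{path.name}: single-channel ({mode}) image has no color "
                    "bands; an RGB photograph is required"
                )
            if mode == "P":
                # palette images may encode color; expand and keep RGB
                im = im.convert("RGB")
            elif mode == "RGBA":
                im = im.convert("RGB")
            elif mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ImageFormatError(f"{path.name}: not a decodable image file") from exc
    return RGBImage(arr, source_id=path.stem)


def write_cover_table(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write per-image results (one row per image/method) to CSV.

    Each row dict carries ``source_id``, ``method``, ``canopy_cover`` and,
    for the fraction method, the four class proportions. Returns the frame
    that was written.
    """
    columns = [
        "source_id", "method", "canopy_cover",
        "p_sc", "p_shc", "p_ss", "p_shs",
    ]
    df = pd.DataFrame(rows)
    for col in columns:
        if col not in df.columns:
            df[col] = np.nan
    df = df[columns]
    df.to_csv(path, index=False)
    return df
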