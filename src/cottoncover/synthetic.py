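"""Synthetic scenes and calibration data with known ground truth.

Real validation data for this method is destructive field sampling, so the
test bed is simulated instead. Two generators cover the two halves of the
pipeline:

* :func:`generate_canopy_image` paints a row-crop scene — horizontal bands
  of overlapping green ellipses on a soil background, mimicking nadir
  photographs of drip-irrigated cotton rows — with an exact binary canopy
  mask, so segmentation output can be compared against pixel-perfect truth.
  Brightness jitter is applied as a single per-pixel offset added to all
  three channels, which perturbs the sunlit/shaded splits while leaving
  the green-minus-red and green-minus-blue margins intact: with the
  default colors the canopy/soil decision is exactly recoverable.
  Shadows scale pixel brightness by 0.4, which straddles the default
  200/250 brightness thresholds so all four pixel classes occur.

* :func:`generate_calibration_data` draws (CC, y) pairs from the
  exponential model y = k*e^(b*CC) with multiplicative lognormal noise,
  y = k*e^(b*CC) * exp(eps), eps ~ N(0, sigma^2) — multiplicative so y
  stays positive, as the model's range requires.

All randomness flows from the explicit seed in each spec; a fixed seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .calibration import CalibrationDataset, ExpModel
from .image_io import RGBImage

__all__ = [
    "SceneSpec",
    "NoiseSpec",
    "SceneSample",
    "GenerationError",
    "generate_canopy_image",
    "generate_calibration_data",
]

#: Brightness multiplier for shadowed pixels; chosen so shadowed canopy
#: and soil fall below the 200/250 sunlit thresholds at default colors.
SHADOW_SCALE = 0.4


class GenerationError(ValueError):
    """The requested scene cannot be realized (e.g. cover > 0 with no rows)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic row-crop scene.

    Defaults emulate the study conditions: six crop rows per frame, green
    canopy on a brownish soil background, moderate brightness variation
    and a quarter of pixels in shadow.
    """

    width: int = 320
    height: int = 240
    true_cover: float = 0.5
    n_rows: int = 6
    canopy_color: tuple[int, int, int] = (50, 140, 60)
    soil_color: tuple[int, int, int] = (120, 110, 100)
    brightness_jitter: float = 8.0
    shadow_fraction: float = 0.25
    antialias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_cover <= 1.0:
            raise ValueError(f"true_cover must be in [0, 1], got {self.true_cover}")
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must be at least 1 x 1 pixels")
        if self.n_rows < 0:
            raise ValueError("n_rows must be >= 0")
        for c in (*self.canopy_color, *self.soil_color):
            if not 0 <= c <= 255:
                raise ValueError("colors must be 8-bit channel counts")
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ValueError("shadow_fraction must be in [0, 1]")
        if self.brightness_jitter < 0:
            raise ValueError("brightness_jitter must be >= 0")


class SceneSample(NamedTuple):
    image: RGBImage
    mask: np.ndarray  # H x W bool, True where canopy was painted
    achieved_cover: float


def _paint_mask(spec: SceneSpec, rng: np.random.Generator, scale: int) -> np.ndarray:
    """Paint ellipses on row centerlines until the target pixel count is hit.

    Works at ``scale``-fold supersampling (1 = pixel grid). The painted
    count is trimmed to the target exactly, removing surplus pixels from
    the last ellipse, so the achieved fraction equals the target fraction
    of the working grid.
    """
    h, w = spec.height * scale, spec.width * scale
    target = round(spec.true_cover * h * w)
    mask = np.zeros((h, w), dtype=bool)
    if target == 0:
        return mask
    if spec.n_rows == 0:
        raise GenerationError(
            f"true_cover={spec.true_cover} is unreachable with n_rows=0"
        )
    row_h = h / spec.n_rows
    painted = 0
    for iteration in range(200_000):
        if painted >= target:
            break
        row = int(rng.integers(spec.n_rows))
        cy = (row + 0.5) * row_h + rng.normal(0, row_h / 4)
        cx = rng.uniform(0, w)
        ry = row_h * rng.uniform(0.25, 0.55)
        rx = ry * rng.uniform(1.0, 3.0)
        rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=mask.shape)
        new = ~mask[rr, cc]
        if not new.any():
            continue
        overshoot = painted + int(new.sum()) - target
        if overshoot > 0:
            # trim surplus pixels of this ellipse to land exactly on target
            new_idx = np.flatnonzero(new)
            keep = rng.choice(new_idx, size=new_idx.size - overshoot, replace=False)
            sel = np.zeros(rr.size, dtype=bool)
            sel[keep] = True
            rr, cc = rr[sel], cc[sel]
        mask[rr, cc] = True
        painted = int(mask.sum())
    if painted < target:
        # pathological geometry (e.g. near-full cover with few rows):
        # top up with individual background pixels, still seeded
        empty = np.flatnonzero(~mask.ravel())
        fill = rng.choice(empty, size=target - painted, replace=False)
        mask.ravel()[fill] = True
    return mask


def generate_canopy_image(spec: SceneSpec) -> SceneSample:
    """Render a row-crop scene with exact canopy ground truth.

    Returns the image, the binary canopy mask (before shadow/jitter, the
    segmentation-relevant truth) and the achieved cover = mask fraction.
    With ``antialias`` off the achieved cover equals ``true_cover`` to
    within half a pixel; with it on, boundary pixels are blended and the
    binary mask is the majority-coverage pixel set.
    """
    rng = np.random.default_rng(spec.seed)
    scale = 3 if spec.antialias else 1
    fine = _paint_mask(spec, rng, scale)

    if spec.antialias:
        cov = fine.reshape(spec.height, scale, spec.width, scale).mean(axis=(1, 3))
        mask = cov >= 0.5
    else:
        cov = fine.astype(np.float64)
        mask = fine

    canopy = np.asarray(spec.canopy_color, dtype=np.float64)
    soil = np.asarray(spec.soil_color, dtype=np.float64)
    img = cov[..., None] * canopy + (1.0 - cov[..., None]) * soil

    if spec.shadow_fraction > 0:
        shadowed = rng.random((spec.height, spec.width)) < spec.shadow_fraction
        img[shadowed] *= SHADOW_SCALE
    if spec.brightness_jitter > 0:
        jitter = rng.normal(0, spec.brightness_jitter, (spec.height, spec.width))
        img += jitter[..., None]

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = RGBImage(pixels, source_id=f"synthetic-seed{spec.seed}")
    return SceneSample(image=image, mask=mask, achieved_cover=float(mask.mean()))


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of a synthetic calibration dataset."""

    model: ExpModel
    n: int = 200
    cc_range: tuple[float, float] = (0.05, 0.95)
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3 (minimum fittable dataset)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        lo, hi = self.cc_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("cc_range must be ordered and within [0, 1]")


def generate_calibration_data(spec: NoiseSpec) -> CalibrationDataset:
    """Draw (CC, y) pairs from the exponential model with lognormal noise."""
    rng = np.random.default_rng(spec.seed)
    cc = rng.uniform(spec.cc_range[0], spec.cc_range[1], spec.n)
    eps = rng.normal(0.0, spec.sigma, spec.n) if spec.sigma > 0 else np.zeros(spec.n)
    y = spec.model.k * np.exp(spec.model.b * cc) * np.exp(eps)
    return CalibrationDataset(
        cc=cc,
        y=y,
        group=np.full(spec.n, spec.model.group, dtype=object),
        property=spec.model.property,
    )
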