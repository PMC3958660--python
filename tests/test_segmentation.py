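"""Four-class pixel segmentation: decision rule, fractions, canopy cover."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cottoncover import (
    ClassFractions,
    PixelClass,
    RGBImage,
    ThresholdConfig,
    canopy_cover_fraction,
    class_fractions,
    classify_pixel,
    segment_image,
)


def reference_classify(r, g, b, cfg):
    """Plain conditional-table restatement of the decision rule (oracle)."""
    canopy = (g - r >= cfg.green_over_red_margin) and (g - b >= cfg.green_over_blue_margin)
    if canopy and cfg.max_red_chromaticity is not None:
        total = r + g + b
        canopy = total > 0 and (r / total) < cfg.max_red_chromaticity
    s = r + g + b
    if canopy:
        sunlit = (s < cfg.canopy_brightness_threshold) if cfg.canopy_brightness_sunlit_below \
            else (s >= cfg.canopy_brightness_threshold)
        return PixelClass.SC if sunlit else PixelClass.ShC
    return PixelClass.SS if s > cfg.soil_brightness_threshold else PixelClass.ShS


class TestClassifyPixel:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((30, 120, 40), PixelClass.SC),    # green-dominant, sum 190 < 200
            ((120, 121, 119), PixelClass.SS),  # g-r = 1 < 5 -> soil; 360 > 250
            ((40, 40, 40), PixelClass.ShS),    # achromatic, dim
            ((30, 120, 40), PixelClass.SC),
            ((60, 120, 40), PixelClass.ShC),   # green-dominant, sum 220 >= 200
            ((0, 5, 0), PixelClass.SC),        # g-r exactly at the margin: canopy
            ((0, 4, 0), PixelClass.ShS),       # one count short of the margin
            ((0, 0, 0), PixelClass.ShS),       # pure black is shaded soil
            ((255, 255, 255), PixelClass.SS),  # pure white is sunlit soil
        ],
    )
    def test_hand_traced_examples(self, rgb, expected):
        assert classify_pixel(*rgb) is expected

    def test_brightness_polarity_flip(self):
        flipped = ThresholdConfig(canopy_brightness_sunlit_below=False)
        assert classify_pixel(30, 120, 40, flipped) is PixelClass.ShC
        assert classify_pixel(60, 160, 40, flipped) is PixelClass.SC

    def test_red_chromaticity_clause(self):
        cfg = ThresholdConfig(max_red_chromaticity=0.1)
        # green-dominant but red share 30/190 > 0.1 -> not canopy
        assert classify_pixel(30, 120, 40, cfg) in (PixelClass.SS, PixelClass.ShS)
        # red share 5/235 < 0.1 -> canopy
        assert classify_pixel(5, 200, 30, cfg) in (PixelClass.SC, PixelClass.ShC)

    @pytest.mark.parametrize("rgb", [(-1, 0, 0), (0, 256, 0), (0, 0, 300), (0.5, 1, 2)])
    def test_out_of_range_rejected(self, rgb):
        with pytest.raises(ValueError):
            classify_pixel(*rgb)

    @settings(max_examples=300, deadline=None)
    @given(
        r=st.integers(0, 255), g=st.integers(0, 255), b=st.integers(0, 255),
        gor=st.integers(0, 30), gob=st.integers(0, 30),
        cb=st.integers(0, 765), sb=st.integers(0, 765),
        pol=st.booleans(),
        chroma=st.one_of(st.none(), st.floats(0.01, 1.0)),
    )
    def test_matches_reference_table(self, r, g, b, gor, gob, cb, sb, pol, chroma):
        cfg = ThresholdConfig(
            green_over_red_margin=gor, green_over_blue_margin=gob,
            canopy_brightness_threshold=cb, soil_brightness_threshold=sb,
            canopy_brightness_sunlit_below=pol, max_red_chromaticity=chroma,
        )
        assert classify_pixel(r, g, b, cfg) is reference_classify(r, g, b, cfg)


class TestSegmentImage:
    def test_uniform_image_single_class(self, uniform_image):
        segmap = segment_image(uniform_image((30, 120, 40)))
        assert (segmap.labels == PixelClass.SC).all()

    def test_half_green_half_gray_counts(self):
        arr = np.empty((10, 10, 3), dtype=np.uint8)
        arr[:6] = (30, 120, 40)   # canopy region: 60 pixels
        arr[6:] = (100, 100, 100)  # soil region: 40 pixels
        frac = class_fractions(segment_image(RGBImage(arr)))
        assert frac.p_sc + frac.p_shc == pytest.approx(0.6, abs=0)
        assert frac.p_ss + frac.p_shs == pytest.approx(0.4, abs=0)

    def test_agrees_with_per_pixel_classification(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(0, 256, (4, 4, 3), dtype=np.uint8)
        cfg = ThresholdConfig()
        segmap = segment_image(RGBImage(arr), cfg)
        for i in range(4):
            for j in range(4):
                assert segmap.labels[i, j] == classify_pixel(*arr[i, j].tolist(), cfg)


class TestClassFractions:
    def test_one_pixel_per_class(self):
        arr = np.array(
            [[(30, 120, 40), (60, 160, 40)], [(255, 255, 255), (0, 0, 0)]],
            dtype=np.uint8,
        )
        frac = class_fractions(segment_image(RGBImage(arr)))
        assert (frac.p_sc, frac.p_shc, frac.p_ss, frac.p_shs) == (0.25, 0.25, 0.25, 0.25)

    def test_all_canopy(self, uniform_image):
        frac = class_fractions(segment_image(uniform_image((30, 120, 40))))
        assert (frac.p_sc, frac.p_shc, frac.p_ss, frac.p_shs) == (1.0, 0.0, 0.0, 0.0)

    def test_61_of_100_canopy(self):
        arr = np.full((10, 10, 3), (100, 100, 100), dtype=np.uint8)
        flat = arr.reshape(-1, 3)
        flat[:41] = (30, 120, 40)   # sunlit canopy
        flat[41:61] = (60, 160, 40)  # shaded canopy (sum 260 >= 200)
        frac = class_fractions(segment_image(RGBImage(arr)))
        assert frac.p_sc + frac.p_shc == pytest.approx(0.61, abs=0)

    def test_invalid_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ClassFractions(0.5, 0.5, 0.5, 0.5)


class TestCanopyCover:
    def test_fig2_style_cover(self):
        frac = ClassFractions(0.4, 0.2119, 0.3, 0.0881)
        assert canopy_cover_fraction(frac) == pytest.approx(0.6119, abs=1e-12)

    @pytest.mark.parametrize(
        "frac,expected",
        [(ClassFractions(0, 0, 1, 0), 0.0), (ClassFractions(0.5, 0.5, 0, 0), 1.0)],
    )
    def test_extremes(self, frac, expected):
        assert canopy_cover_fraction(frac) == expected

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           cb=st.integers(0, 765), sb=st.integers(0, 765), pol=st.booleans())
    def test_cover_invariant_to_brightness_thresholds(self, seed, cb, sb, pol):
        """CC = P_SC + P_ShC depends only on the canopy/soil decision."""
        rng = np.random.default_rng(seed)
        img = RGBImage(rng.integers(0, 256, (8, 8, 3), dtype=np.uint8))
        base = canopy_cover_fraction(class_fractions(segment_image(img)))
        varied = ThresholdConfig(
            canopy_brightness_threshold=cb, soil_brightness_threshold=sb,
            canopy_brightness_sunlit_below=pol,
        )
        alt = canopy_cover_fraction(class_fractions(segment_image(img, varied)))
        assert alt == base

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1),
           lo=st.integers(0, 20), hi=st.integers(0, 20))
    def test_cover_monotone_in_green_red_margin(self, seed, lo, hi):
        """A stricter greenness requirement can only shrink the canopy."""
        lo, hi = min(lo, hi), max(lo, hi)
        rng = np.random.default_rng(seed)
        img = RGBImage(rng.integers(0, 256, (8, 8, 3), dtype=np.uint8))
        cc_lo = canopy_cover_fraction(class_fractions(
            segment_image(img, ThresholdConfig(green_over_red_margin=lo))))
        cc_hi = canopy_cover_fraction(class_fractions(
            segment_image(img, ThresholdConfig(green_over_red_margin=hi))))
        assert cc_hi <= cc_lo

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_fraction_conservation(self, seed):
        rng = np.random.default_rng(seed)
        img = RGBImage(rng.integers(0, 256, (6, 7, 3), dtype=np.uint8))
        frac = class_fractions(segment_image(img))
        total = frac.p_sc + frac.p_shc + frac.p_ss + frac.p_shs
        assert abs(total - 1.0) <= 1e-12
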