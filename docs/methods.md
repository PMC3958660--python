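# Methods

## Scope and model

The package estimates canopy cover (CC ∈ [0, 1]) of a row crop from a
nadir 8-bit RGB photograph and maps it to three crop properties through
the exponential model

    y = k · e^(b·CC),

where y is aboveground total N content (g m⁻²), leaf area index
(m² m⁻²) or aboveground biomass (g m⁻²); k > 0 is the curve's initial
value (the property at zero cover, in the property's units) and b the
unitless shaping parameter. The model is monotone in CC for b > 0 and is
calibrated for the window from crop emergence to full bloom: past that,
a closed canopy stops gaining cover while the plant keeps growing, so
predictions at CC > 0.95 carry a `SaturationWarning` (the 0.95 threshold
is a package choice; saturation is a gradual phenomenon).

## Canopy cover

**Method 1 — soil-adjusted green–red index.** CC = (1+L)(G−R)/(G+R+L)
with band values on a [0, 1] scale. The source definition leaves the
scale of G and R unstated; we divide the 8-bit band means by 255 so that
the soil baseline L = 0.5 has the magnitude conventional for
soil-adjusted indices (L ∈ [0, 1], 0 = full canopy, 1 = bare soil). Two
band statistics are offered: `mean-of-bands` (default — band means
first, one index per image, matching the single-G/single-R form of the
definition) and `per-pixel-mean` for sensitivity analysis. The index can
leave [0, 1] on red-dominant scenes; by default it is clamped with a
logged warning, and clamping can be disabled for diagnostics. With
L = 0 the index reduces to the normalized green–red difference.

**Method 2 — four-class pixel segmentation.** A pixel is canopy when
green dominates both other bands: G − R ≥ 5 and G − B ≥ 5 (margins in
channel counts, inclusive at the margin, both configurable). The
published pseudocode for this rule is internally inconsistent (it
contains an unsatisfiable clause and a threshold with no stated scale);
we read it as symmetric greenness dominance, and expose the leftover
red-threshold clause as an optional normalized-red-chromaticity test
r/(r+g+b) < t, disabled by default (a pure-black pixel is treated as
non-canopy, avoiding the 0/0). Within canopy, brightness R+G+B < 200
labels a pixel sunlit (SC) and otherwise shaded (ShC); within soil,
R+G+B > 250 labels sunlit soil (SS), else shaded (ShS). The printed
sunlit-when-darker polarity is suspicious but is implemented as printed,
with a boolean to flip it; cover is provably independent of the
sunlit/shaded split either way, since

    CC = P_SC + P_ShC

depends only on the canopy/soil decision. This sublabel independence is
asserted property-style over random images and thresholds. CC is
computed as the exact pixel-count ratio (canopy count / total count)
rather than a sum of two rounded fractions, so it is bit-identical under
any brightness-threshold setting.

Ties and degenerate inputs: greenness margins use ≥; brightness
comparisons are strict (< 200, > 250) as printed; grayscale images are
rejected at load time (no color information); an all-black image with
L = 0 makes the index undefined and raises a domain error.

## Calibration fitting

`fit_exponential` minimizes Σ(y − k·e^(b·cc))² on the original y scale
by nonlinear least squares (`scipy.optimize.curve_fit`, trust-region
reflective with k bounded positive, b free, parameter tolerance 1e-10,
~200 iteration budget). Fitting on the original scale matches how RMSE
and R² are reported — in property units. The initializer is the
closed-form OLS of ln y on cc, computed independently via the normal
equations; on noiseless exponential data the two routes coincide to
machine precision, which the tests use as an oracle. Non-convergence
raises an error carrying the initializer's fit. R² is the residual-based
1 − SS_res/SS_tot of observed against fitted y (this definition
penalizes bias and can be negative); the squared Pearson correlation is
reported alongside, and the linear-fit utility for cover-vs-sensor-index
comparisons (NDVI, RVI) uses squared Pearson, the natural quantity for a
regression scatter. Fits are unweighted and replicates are pooled.
Grouped fitting (`fit_by_group`) fits each group label independently,
sorted by label; groups failing the preconditions (n < 3, non-positive
y, constant cc) are reported as skipped, not fatal.

The shipped parameter sets (pooled, two cultivars, five N rates; 24
entries) are plain JSON data with a SHA-256 over the canonical entry
list, verified at load, and double-entered as literals in the test
suite; users can supply their own model files through the same
interface. The N-rate sets show k and b increasing with fertilizer rate,
which is why per-group calibration matters in practice.

## Synthetic data

No public image or plant dataset exists for this method (validation in
the field is destructive sampling), so the test bed is synthetic with
exact ground truth.

**Scenes.** `generate_canopy_image` paints horizontal crop rows (six per
frame by default, matching typical drip-irrigated cotton plantings) as
overlapping ellipses of canopy color on a soil background, at 320×240 by
default. Ellipses are added until the painted-pixel count reaches the
requested cover, with the surplus of the last ellipse trimmed so the
achieved cover equals the request to within half a pixel; the exact
binary mask and achieved cover are returned. Brightness jitter (default
σ = 8 counts) is a single per-pixel offset added to all three channels:
it perturbs the sunlit/shaded brightness splits while leaving G−R and
G−B unchanged, so with the default colors the canopy/soil decision is
exactly recoverable and segmentation equals the mask pixel for pixel.
Shadows (default fraction 0.25) scale brightness by 0.4, chosen to
straddle the 200/250 thresholds so all four classes occur. Optional
antialiasing blends boundary pixels from a 3× supersampled mask; cover
recovery is then within 0.02 (boundary pixels only). What these scenes
do **not** emulate: leaf-level color variation, specular highlights,
mixed soil textures, perspective and within-canopy mutual shading of a
real 3-D crop — so a passing exactness test shows the decision rule and
bookkeeping are correct, not that real photographs segment perfectly.

**Calibration pairs.** `generate_calibration_data` draws CC uniform on a
range (default 0.05–0.95) and y = k·e^(b·CC)·exp(ε), ε ~ N(0, σ²):
multiplicative lognormal noise keeps y positive, as the model's range
requires. Default σ = 0.05 and n = 200 represent a low-noise,
well-sampled calibration campaign. Under this noise the original-scale
least-squares estimate of k has a relative bias of order σ²/2 ≈ 0.1%,
well inside the 2% recovery band the tests use. All randomness flows
from one explicit seed per spec; fixed seed means bit-identical output.

## Problem sizes and reproducibility

The recovery study (`scripts/acceptance.py` and the corresponding test)
uses 50 replicates of n = 200 per property — enough that the replicate
mean of (k̂, b̂) is stable to a few tenths of a percent — and completes
in seconds. The script derives its 150 replicate seeds from the single
`--seed` argument via `numpy.random.SeedSequence`, so results are
reproducible per seed and statistically equivalent across seeds.

## Known limitations

- The two cover methods agree only approximately; the index method is
  sensitive to canopy color saturation and soil hue (on dull-green,
  shadowed scenes it reads lower than the pixel count), while the pixel
  method is sensitive to the greenness margins. On clean
  saturated-green fixtures they track within 0.15 across cover 0.1–0.9.
- Calibration parameters are crop-, cultivar- and site-specific; the
  shipped cotton values should not be applied to other crops without
  refitting.
- No growth-stage input exists, so the emergence-to-full-bloom
  applicability window is metadata plus a saturation warning, not an
  enforced check.
- JPEG input is supported but decoding is codec-dependent; bit-exact
  workflows should use PNG.
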