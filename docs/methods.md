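# Methods

## Color conversion

The forward chain from an 8-bit photograph to CIELAB is
channel normalization (÷255), the piecewise sRGB gamma, the 3×3
linear-RGB→XYZ matrix (IEC 61966-2-1 sRGB primaries, D65), white-point
normalization, and the CIELAB `f(t)` nonlinearity with threshold
(6/29)³. All operations are element-wise; pixels are assumed
sRGB-encoded and embedded ICC profiles are ignored, matching how
smartphone JPEG output is normally treated.

Two modes exist because the published equation set this toolkit follows
contains three departures from the CIE definitions, and we chose to
reproduce them *explicitly* rather than silently or not at all:

1. **Gamma direction.** The printed piecewise function uses the
   exponent 1/2.4 — the sRGB *encoding* curve — while describing a
   linearization step. The downstream XYZ matrix requires linear RGB,
   so `standard` mode applies the correct decoding (exponent 2.4,
   knee at u = 0.04045 with 0.04045/12.92 = 0.0031308);
   `paper_literal` applies the printed function verbatim, including its
   odd extension for negative inputs.
2. **Double white-point division.** The printed chain divides the
   tristimulus values by the white point twice before `f(t)`.
   `standard` divides once, which is the CIELAB definition and is
   required for white to map to L\* = 100.
3. **Δ = 128 chroma offset.** The printed a\*/b\* equations add 128
   (an 8-bit storage convention). Carried into the ITA formula this
   makes b\* ≈ 128 for every pixel and collapses all skin tones toward
   ITA ≈ 0, so `standard` mode sets Δ = 0; `paper_literal` keeps 128.
   The collapse is demonstrated in the acceptance suite on a dark
   fixture patch.

`paper_literal` is pure and bit-deterministic but produces non-CIELAB
output and has no inverse; `lab_to_rgb` therefore refuses it.

**White point.** The default is the matrix-consistent D65 — the row
sums (0.9504700, 1.0000001, 1.0888300) — so that RGB white maps exactly
to (100, 0, 0). The rounded (0.95, 1, 1.09) sometimes quoted alongside
the matrix is selectable (`white_point="rounded"`). The difference is
below 0.3 ΔE76 anywhere in the gamut but matters for exact neutrality
of the gray axis.

**Inverse chain.** `lab_to_rgb` inverts `f` analytically, applies the
matrix inverse, clips linear RGB to [0, 1] (returning an out-of-gamut
mask; a 1e-9 tolerance absorbs float round-off at the boundary),
re-encodes and rounds to 8 bits. Round-tripping an 8-bit image through
Lab and back is identity to ±1 per channel; random in-gamut colors
survive Lab→RGB8→Lab within ΔE76 ≤ 1, the quantization floor.

## ITA mapping and classification

ITA is computed with `atan2(L*−50, b*)` rather than a bare arctangent:
pixels with b\* < 0 (a blue cast that healthy skin does not produce)
then land outside [−90°, 90°] and are **masked invalid** instead of
being folded back into the scale; the degenerate pivot (50, 0) is
likewise masked, not zero-filled, since a zero would bias the mean
toward the "brown" bin. The representative value is the arithmetic
mean over defined ROI pixels (not the histogram mode).

The six phenotype bins are half-open intervals (lower, upper], with the
lowest closed at −90 so the partition is exact: boundary values belong
to the bin whose upper edge they touch (0 → brown, 25 → fair,
−50 → very dark).

Defaults: if no ROI is given, a centered square of side
⌊min(H, W)/4⌋ is used; the histogram bin width is 1°, matching the
2-decimal reporting precision of the degree outputs. Both are
configurable.

## Exposure-response fitting

`BoltzmannModel.fit()` runs unweighted nonlinear least squares
(scipy's trust-region reflective solver) on the four-parameter sigmoid.
Initialization: A1 = first reading, A2 = last reading, x0 = median
exposure, dx = exposure range / 4; dx is bounded to (10⁻⁴, 10] to keep
the solver away from the singular dx → 0 limit on five-point sweeps.
Per-reading ITA SDs are not used as weights — the protocol reports only
mean ITA per exposure, and on 5-point sweeps weighting adds variance
without reducing bias.

Degenerate (flat) sweeps leave dx unidentifiable; the fit returns
`converged=True`, `degenerate=True`, rmse ≈ 0, and dx at its bounded
initial value rather than raising, so batch runs survive uniform
images. Genuine solver failure returns `converged=False` with the
start parameters, never an exception.

`optimal_exposure` selects among *measured* settings (the acquired
grid, default {0.3, 0.7, 1.0, 1.3, 1.7}), not the continuous fit
minimum, because the recommendation is an exposure a camera can
actually be set to; ties break toward the lower exposure (less sensor
saturation). `hysteresis_gap` is the mean absolute mean-ITA difference
between two conditions on an identical grid.

## Reference series and agreement

Reference-colorimeter series follow the clinical protocol: 20
consecutive L\*a\*b\* readings per site. ITA is computed per reading and
then averaged — matching how the instrument reports per-measurement
ITA — rather than from the averaged Lab triple; for the dispersions
involved (≤1°) the two differ negligibly, but the per-reading SD is
only defined the first way. SDs over readings use the sample
convention (ddof = 1, small-n repeated measurements); per-pixel map SDs
use the population convention (ddof = 0, the ROI is the whole
population of interest). Color difference is CIE76 (Euclidean distance
in Lab, via scikit-image); the primary agreement metric is the signed
ITA error, which clinicians can read directly in degrees.

## Synthetic data

The generator exists so every stage is testable offline with known
ground truth; its defaults are the study conditions.

* **Patches**: a uniform Lab color on the ray of angle ITA about the
  pivot, at radius 30 (in-gamut across the whole scale except
  |ITA| > 80) with a\* = 12 (typical reddish skin chroma; ITA ignores
  a\*), plus i.i.d. Gaussian Lab texture noise, encoded through the
  standard inverse chain and quantized to 8 bits. This emulates the
  color statistics of a skin ROI, **not** spatially correlated skin
  microstructure, camera noise, or the ISP: a passing round-trip test
  validates the color pipeline, not photograph realism.
* **Sweeps**: the Boltzmann curve on the acquired exposure grid
  {0.3, 0.7, 1.0, 1.3, 1.7} plus Gaussian noise on mean ITA. The
  recovery experiments use noise σ = 0.5°, the order of the observed
  per-site ITA SDs, and slope dx = 0.23, the observed across-subject
  mean.
* **Reference series**: Gaussian draws about a mean Lab triple,
  n = 20 by default. Isotropic L/b noise of SD σ at radius r from the
  pivot yields an angular SD ≈ (180/π)·σ/r, which is how the test
  suite calibrates a series to a prescribed ITA dispersion.

All generators are deterministic under a fixed seed
(`numpy.random.default_rng`).

## Problem sizes and tolerances

The slope-recovery experiment uses 100 replicates of 5-point sweeps —
enough to estimate the mean recovered dx to ±0.005 (SE), an order
tighter than the ±0.05 band it is checked against. Round-trip checks
use 64² patches noise-free (quantization error is pixel-independent,
so size does not matter) and 256² with σ = 2 noise, where averaging
reduces the per-pixel angular noise (~4°) to ~0.015° SE. Conversion
oracle agreement is checked on 1000 random pixels at ΔE76 < 0.02;
the measured maximum against scikit-image is ≈ 0.006, attributable to
sixth-decimal differences in the published matrix roundings.

## Known limitations

* No skin-region segmentation: the ROI is user-specified, and nothing
  prevents measuring a tattoo or scar.
* No chromatic adaptation, no illuminants other than D65, no CIEDE2000,
  no RAW/HEIC decoding, no modeling of flash/ambient light mixing.
* The phenotype scale is a uniform partition of the angle; it inherits
  ITA's known insensitivity to a\* (redness).
* Paper-literal mode is for provenance experiments only; every
  scientific output should use standard mode.
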