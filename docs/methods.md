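# Methods

## Densitometry model

A lateral-flow strip read is modeled as a 1-D densitometry problem. The
RGB capture is reduced to luminance with the BT.601 weights
(`Gray = 0.299R + 0.587G + 0.114B`), kept as real numbers end to end;
rounding happens only at display. The cassette carrier fixes the geometry,
so the ROI is a configured rectangle (pixels or image fractions, 0-based
half-open bounds) and no image registration is attempted. Averaging the
ROI across the transverse axis yields the longitudinal profile; this mean
is exact (the profile mean equals the ROI mean), and with per-pixel noise
of SD σ a profile row over W columns has noise σ/√W.

**Band detection.** Bands are dark dips near known expected positions.
The center is the argmin, within a ±`search_halfwidth` window (default 20
px), of the profile smoothed by a moving average of the measurement-window
width (`2·band_halfwidth + 1`, default 7 px). The smoothing is a matched
filter for the flat-bottomed band profile: a raw per-sample argmin on a
flat dip lands uniformly anywhere in the core under noise, dragging the
centered measurement window onto the band edge and biasing the mean by
several gray levels; the filtered argmin is the window position with the
darkest mean, which is the quantity actually measured. Ties break toward
the expected position, so a featureless profile degrades gracefully to the
expected layout. The band mean is taken over the raw profile; the baseline
is the median of the profile outside both search windows (robust to the
two dips); the *relative grayscale* is `max(0, baseline − band mean)`.
Baseline subtraction makes the contrast invariant under additive
illumination shifts and exactly linear under multiplicative gain — which
is why the device correction (below) suffices.

**Validity.** A read is valid iff the C-line contrast reaches
`c_min_relative` (default 5 gray levels). The absolute band mean
(`measure_band_gray`) is kept distinct from the relative contrast: printed
grayscale strips are characterized by the absolute quantity, while the
calibration curve consumes the relative one; the two are never collapsed.

## Calibration curve and decision rule

The dose response is carried as monotone (concentration, relative
grayscale) knots — for the FOB lot, the seven triplicate averages from
0 to 1000 ng/mL — interpolated piecewise-linearly in `log10(c + 1)`.
LFA dose responses are strongly sublinear in concentration; knot
interpolation reproduces the calibration points exactly without asserting
a parametric form the seven points cannot pin down. Inversion clamps below
the blank knot to 0 (`below_blank`) and above the top knot to the upper
detection limit (`above_upper`). The qualitative call is strict:
positive iff concentration > threshold ("exceeds"); exactly 50 ng/mL is
negative. Borderline calls flip on this strictness, so it is applied and
documented exactly.

Replicate summaries use the sample SD (n−1) and CV = 100·SD/mean.
Display convention: means and SDs round half-up to 2 decimals; CVs
truncate to 2 decimals. The truncation is deliberate — it is the
convention under which the reference replicate table's printed CV column
is self-consistent (e.g. 100·3.89004/52.43 = 7.4195 prints as 7.41, and
0.7155 as 0.71); half-up rounding reproduces the means and SDs but not the
CVs. When replicates are read through the pipeline, contrasts are averaged
first and the average inverted once, mirroring how the calibration table
itself was summarized (and avoiding the upward bias of averaging the
convex inverse).

## Device correction

LED intensity and darkroom differences make the same strip read
differently across devices and sessions. A calibration cassette with ≥ 2
patches of distinct known grays is read at session start;
`target ≈ gain·measured + offset` is fitted by least squares and applied
elementwise (clamped to [0, 255]) to every subsequent profile before band
detection. Affine is the minimal model that absorbs exposure offset and
illumination gain; the offset cancels in baseline subtraction, the gain is
exactly what the relative contrast needs corrected. Identical patch
measurements are rejected as degenerate. The correction is stored as JSON
with a timestamp and an id that is recorded in every result it touches.
The correction cannot recover sensor saturation: a device whose gain
pushes the membrane past 255 clips irreversibly, so calibration-patch
targets should sit inside the device's linear range.

## QR payload

Assay metadata is a five-field schema (test items, sample-hole count,
calibration curve, upper detection limit, lower threshold) with a version
tag, validated with pydantic: threshold below the detection limit, curve
knots spanning [0, upper limit], strict monotonicity. The wire format is
canonical JSON (key-sorted, minimal separators), so equal payloads encode
byte-identically, and the curve travels as explicit knots plus an
interpolation-form tag — the reader interpolates, it never refits.
Rendering to an actual QR barcode and reading one from a photo are
delegated to the optional `qrcode`/`pyzbar` packages; the codec itself is
pure JSON.

## Synthetic cassette generator

The generator replaces the camera/darkroom with a renderer whose ground
truth is known, and emulates:

* a light membrane (default gray 230; printed simulated strips use a white
  255 background) with two transverse bands — a rectangular core of
  `band_width` rows (default 8) with 1-px half-weight edge ramps;
* band color: `fixed_red_channel` keeps R = 255 and varies G = B so the
  BT.601 luminance hits the requested gray (colloidal gold is
  red-dominant); `gray_patch` renders neutral pixels and is exact for
  integer grays;
* illumination as a multiplicative gain (scalar, or a top-to-bottom linear
  gradient), applied before 8-bit clipping;
* sensor noise as additive Gaussian on the grayscale field (SD in gray
  levels), clipped to [0, 255];
* dose series: the T band renders at `background − curve(c)`, so the
  nominal contrast equals the curve value; the blank's nonzero contrast is
  a faint T band — the curve, not binding chemistry, drives darkness.

Quantization: with noise, plain rounding (the noise itself dithers); at
zero noise, deterministic per-row Bresenham dithering spreads the
fractional part so a band row's transverse mean matches a fractional
nominal gray to ≤ 0.5/width gray levels. This matters because the
log-scale curve is steep at the top of the range (≈ 41 ng/mL per gray
level near 400 ng/mL), so plain ±0.5 rounding error would alias into
±20 ng/mL. Per-pixel values stay within one quantization step (0.5 gray
neutral, 0.701 in fixed-red mode, where only G = B can move).

Every generator is bit-reproducible under a fixed seed; replicate seeds
are spawned from a root `SeedSequence`. Ground truth (centers, nominal
grays, gain, clamping, seed) is serialized as JSON alongside each image
and round-trips losslessly.

**What the generator does not emulate:** optical physics of colloidal
gold, lens distortion, perspective, motion blur, non-uniform transverse
illumination, membrane texture, or chemistry-driven nonspecific binding.
Passing tests therefore demonstrate the correctness of the *software*
chain — geometry, photometry, statistics, inversion — under an idealized
image model, not robustness to real capture artifacts.

## Study conditions used by tests and the acceptance script

Default strip: 360×200 px image, ROI rows [30, 330) × cols [40, 160)
(300-px longitudinal window), C line at row 110, T line at row 230,
C-band gray 150. The printed-strip experiment sweeps the T band from 125
to 255 in steps of 10 on a white background with pixel noise SD 1 and
reads each image through the full pipeline (regression R² of detected vs
nominal), plus 5 replicate reads at each of 5 levels for the maximum
per-level CV. Dose recovery reads triplicates at the seven lot
concentrations with noise SD 1. These sizes run the whole suite in a few
seconds while leaving the noise averaging (≈ 840 band pixels) realistic
for a desk camera.

Numerical conventions and edge cases: grayscale floats end to end;
0-based half-open windows; argmin ties toward the expected position;
relative contrasts floored at 0; curve inversion exact at knots (≤ 1e−9);
concentrations clamped to [0, upper limit]; a blank read has no relative
tolerance, so dose-recovery checks require the blank's estimate to stay
below 10 % of the smallest nonzero dose instead.

## Known limitations

* Single strip window per ROI; multi-hole cassettes are handled by listing
  ROIs in the geometry config, not by detecting strips.
* The affine correction is grayscale-only; per-channel white balance is
  out of scope because quantification is luminance-based.
* The calibration curve is lot-specific and travels with the QR payload;
  extrapolation beyond the knot range is flagged, not modeled.
* Concentration uncertainty grows sharply at the extremes of the curve,
  where the log-axis slope is steep (top of range) or the contrast step
  between knots is small (near the blank).
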