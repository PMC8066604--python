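"""Densitometry core for lateral-flow strip images.

The read-out of a colloidal-gold lateral-flow assay is the darkness of the
control (C) and test (T) lines on a white nitrocellulose membrane.  This
module implements the image-processing chain that turns an 8-bit RGB capture
of the cassette read window into band measurements:

1. luminance conversion with the ITU-R BT.601 weights,
   ``Gray = 0.299 R + 0.587 G + 0.114 B``;
2. region-of-interest (ROI) extraction — the cassette carrier fixes the
   geometry, so the ROI is a configured rectangle (optionally given as
   fractions of the image size);
3. transverse averaging of the ROI to a 1-D longitudinal intensity profile,
   indexed along the flow direction (the ROI row axis);
4. band detection and quantification on that profile: each band is a dark
   dip near a known expected position, and its *relative grayscale* is the
   baseline-minus-band contrast used for quantification.

Grayscale values are kept as real numbers end to end; rounding happens only
at display.  All coordinates are 0-based with half-open windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DomainError, GeometryError

#: ITU-R BT.601 luma weights for the R, G, B channels.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 RGB image to a float grayscale matrix.

    Applies ``Gray = 0.299 R + 0.587 G + 0.114 B`` per pixel and keeps the
    result as real values in [0, 255] (no premature rounding).
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DomainError(
            f"expected an H x W x 3 RGB array, got shape {arr.shape!r}"
        )
    return arr.astype(np.float64) @ GRAY_WEIGHTS


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest, 0-based half-open bounds.

    Bounds are pixels by default; with ``units="fraction"`` they are
    fractions of the image dimensions, resolved against a concrete image
    shape before slicing.
    """

    row_start: float
    row_end: float
    col_start: float
    col_end: float
    units: str = "pixels"

    def resolve(self, shape: tuple[int, ...]) -> "ROISpec":
        """Return a pixel-unit ROISpec validated against ``shape``."""
        n_rows, n_cols = shape[0], shape[1]
        if self.units == "fraction":
            rs = int(round(self.row_start * n_rows))
            re_ = int(round(self.row_end * n_rows))
            cs = int(round(self.col_start * n_cols))
            ce = int(round(self.col_end * n_cols))
        elif self.units == "pixels":
            rs, re_, cs, ce = (
                int(self.row_start),
                int(self.row_end),
                int(self.col_start),
                int(self.col_end),
            )
        else:
            raise DomainError(f"unknown ROI units {self.units!r}")
        if not (0 <= rs < re_ <= n_rows and 0 <= cs < ce <= n_cols):
            raise GeometryError(
                f"ROI rows [{rs},{re_}) cols [{cs},{ce}) out of bounds or empty "
                f"for image shape {shape[:2]}"
            )
        return ROISpec(rs, re_, cs, ce, units="pixels")

    @property
    def n_rows(self) -> int:
        return int(self.row_end) - int(self.row_start)

    @property
    def n_cols(self) -> int:
        return int(self.col_end) - int(self.col_start)


def extract_roi(gray: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Extract the ROI sub-matrix from a grayscale image (no resampling)."""
    arr = np.asarray(gray, dtype=np.float64)
    if arr.ndim != 2:
        raise DomainError(f"expected a 2-D grayscale array, got shape {arr.shape!r}")
    r = roi.resolve(arr.shape)
    return arr[int(r.row_start):int(r.row_end), int(r.col_start):int(r.col_end)]


def longitudinal_profile(roi_gray: np.ndarray) -> np.ndarray:
    """Average the ROI across the transverse (column) axis.

    Element ``i`` is the arithmetic mean of ROI row ``i``, so the profile is
    indexed along the flow direction and has one value per ROI row.
    """
    arr = np.asarray(roi_gray, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise GeometryError("longitudinal profile requires a non-empty 2-D ROI")
    return arr.mean(axis=1)


@dataclass(frozen=True)
class BandMeasurement:
    """A located C or T band on a longitudinal profile.

    ``relative_grayscale`` is the densitometric contrast
    ``max(0, baseline_gray - band_mean_gray)``: how much darker the band is
    than the surrounding membrane.
    """

    band_kind: str  # "C" or "T"
    center: int
    window: tuple[int, int]  # half-open [start, stop)
    band_mean_gray: float
    baseline_gray: float
    relative_grayscale: float


@dataclass(frozen=True)
class StripGeometry:
    """Expected band layout on the longitudinal profile (profile indices).

    Defaults match the synthetic cassette's default strip: a 300-row ROI
    with the C line at row 80 and the T line at row 200.
    ``c_min_relative`` is the minimum C-line contrast (gray levels) for a
    test to be considered valid — no control line means the sample never
    flowed, and the read is rejected.
    """

    expected_c: int = 80
    expected_t: int = 200
    search_halfwidth: int = 20
    band_halfwidth: int = 3
    c_min_relative: float = 5.0


def _search_window(expected: int, halfwidth: int, n: int) -> tuple[int, int]:
    lo, hi = expected - halfwidth, expected + halfwidth + 1
    if not (0 <= lo < hi <= n):
        raise GeometryError(
            f"search window [{lo},{hi}) around {expected} outside profile of length {n}"
        )
    return lo, hi


def _argmin_toward(values: np.ndarray, lo: int, hi: int, expected: int) -> int:
    """Index of the window minimum; ties broken toward ``expected``."""
    seg = values[lo:hi]
    candidates = np.flatnonzero(seg <= seg.min() + 1e-12) + lo
    return int(candidates[np.argmin(np.abs(candidates - expected))])


def detect_bands(
    profile: np.ndarray,
    expected_c: int,
    expected_t: int,
    search_halfwidth: int,
    band_halfwidth: int,
    c_min_relative: float = 5.0,
) -> tuple[BandMeasurement, BandMeasurement, bool]:
    """Locate and quantify the C and T bands on a longitudinal profile.

    Each band center is the argmin, within a search window around its
    expected position, of the profile smoothed by a moving average of the
    measurement-window width (a matched filter for the flat-bottomed band —
    a raw per-sample argmin on a flat dip wanders under noise and drags the
    measurement window onto the band edge).  Ties go to the position nearest
    the expected center.  The band mean is taken over
    ``[center - band_halfwidth, center + band_halfwidth]`` of the *raw*
    profile; the baseline is the median of the profile outside both search
    windows (robust to the two dips).  The read is valid iff the C band's
    relative grayscale reaches ``c_min_relative``.
    """
    prof = np.asarray(profile, dtype=np.float64)
    n = prof.shape[0]
    c_lo, c_hi = _search_window(expected_c, search_halfwidth, n)
    t_lo, t_hi = _search_window(expected_t, search_halfwidth, n)
    if max(c_lo, t_lo) < min(c_hi, t_hi):
        raise GeometryError("C and T search windows overlap")

    size = 2 * band_halfwidth + 1
    filtered = uniform_filter1d(prof, size=size, mode="nearest")

    outside = np.ones(n, dtype=bool)
    outside[c_lo:c_hi] = False
    outside[t_lo:t_hi] = False
    if not outside.any():
        raise GeometryError("search windows cover the whole profile; no baseline left")
    baseline = float(np.median(prof[outside]))

    def measure(kind: str, lo: int, hi: int, expected: int) -> BandMeasurement:
        center = _argmin_toward(filtered, lo, hi, expected)
        w_lo, w_hi = center - band_halfwidth, center + band_halfwidth + 1
        if not (0 <= w_lo < w_hi <= n):
            raise GeometryError(
                f"{kind}-band window [{w_lo},{w_hi}) outside profile of length {n}"
            )
        band_mean = float(prof[w_lo:w_hi].mean())
        return BandMeasurement(
            band_kind=kind,
            center=center,
            window=(w_lo, w_hi),
            band_mean_gray=band_mean,
            baseline_gray=baseline,
            relative_grayscale=max(0.0, baseline - band_mean),
        )

    c_band = measure("C", c_lo, c_hi, expected_c)
    t_band = measure("T", t_lo, t_hi, expected_t)
    valid = c_band.relative_grayscale >= c_min_relative
    return c_band, t_band, valid


def measure_band_gray(profile: np.ndarray, band: BandMeasurement) -> float:
    """Absolute mean gray over the band window (not baseline-subtracted).

    This is the quantity reported for printed grayscale test strips, as
    opposed to ``relative_grayscale`` which the calibration curve consumes.
    """
    prof = np.asarray(profile, dtype=np.float64)
    lo, hi = band.window
    if not (0 <= lo < hi <= prof.shape[0]):
        raise GeometryError(f"band window [{lo},{hi}) outside profile")
    return float(prof[lo:hi].mean())
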