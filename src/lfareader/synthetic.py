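"""Synthetic cassette images: seeded, annotated stand-ins for the camera.

The physical reader photographs a cassette inside an LED-lit darkroom.  This
module replaces that optical front end with a deterministic renderer so the
whole pipeline is testable offline:

* **Strips** — a light membrane (default gray 230) carrying two dark
  transverse bands (C and T).  Bands are rectangular dips with a 1-px linear
  edge ramp.  In ``fixed_red_channel`` mode the band keeps R fixed and
  varies G = B so the rendered luminance hits a requested grayscale — the
  design used for printed simulated strips, whose color, like colloidal
  gold, is red-dominant.  ``gray_patch`` mode renders neutral R = G = B.
* **Calibration cassettes** — flat patches of known target gray, optionally
  distorted by a device/illumination gain, used to fit a device correction.
* **Dose series** — strips whose nominal T-band contrast follows a
  calibration curve at requested concentrations, with replicate noise.

Every generator is bit-reproducible under a fixed seed.  Noise is additive
Gaussian on the grayscale field, clipped to [0, 255].  When noise is zero,
quantization uses deterministic per-row Bresenham dithering so the
*transverse mean* of a band row matches a fractional nominal gray to within
0.5/width of a gray level (integer targets render exactly); with noise, the
noise itself dithers and plain rounding is used.

Ground truth (band centers, nominal grays, gain, seed) is returned with
every image and round-trips losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError
from .imaging import GRAY_WEIGHTS, ROISpec, StripGeometry
from .quant import CalibrationCurve

_RED_FIXED_GRAY = 0.299 * 255.0  # luminance contribution of a saturated R channel
_GB_WEIGHT = float(GRAY_WEIGHTS[1] + GRAY_WEIGHTS[2])  # 0.701


# ---------------------------------------------------------------------------
# Specs and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StripSpec:
    """Geometry and photometry of one synthetic strip image.

    Band centers are absolute image rows and must sit inside the ROI,
    separated by more than ``2 * band_width``.  Band grays must not exceed
    the background (bands are dark dips on a light membrane).
    ``illumination_gain`` is either a scalar or a ``(top, bottom)`` pair
    interpolated linearly along the rows.
    """

    image_height: int = 360
    image_width: int = 200
    roi: ROISpec = ROISpec(30, 330, 40, 160)
    c_band_center: int = 110
    t_band_center: int = 230
    band_width: int = 8
    background_gray: float = 230.0
    c_band_gray: float = 150.0
    t_band_gray: float = 200.0
    band_rgb_mode: str = "fixed_red_channel"
    illumination_gain: float | tuple[float, float] = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        roi = self.roi.resolve((self.image_height, self.image_width))
        object.__setattr__(self, "roi", roi)
        for name in ("background_gray", "c_band_gray", "t_band_gray"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise DomainError(f"{name}={v} outside [0, 255]")
        if self.c_band_gray > self.background_gray or self.t_band_gray > self.background_gray:
            raise DomainError("band grays must not exceed the background gray")
        if self.band_rgb_mode not in ("fixed_red_channel", "gray_patch"):
            raise DomainError(f"unknown band_rgb_mode {self.band_rgb_mode!r}")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        for g in self._gain_pair():
            if g <= 0:
                raise DomainError("illumination gain must be positive")
        for name, center in (("c_band_center", self.c_band_center),
                             ("t_band_center", self.t_band_center)):
            if not (roi.row_start <= center < roi.row_end):
                raise GeometryError(f"{name}={center} outside ROI rows "
                                    f"[{roi.row_start},{roi.row_end})")
        if abs(self.c_band_center - self.t_band_center) <= 2 * self.band_width:
            raise GeometryError("C and T band centers overlap "
                                "(separation must exceed 2 * band_width)")

    def _gain_pair(self) -> tuple[float, float]:
        g = self.illumination_gain
        if isinstance(g, (int, float)):
            return float(g), float(g)
        top, bottom = g
        return float(top), float(bottom)

    def gain_per_row(self) -> np.ndarray:
        top, bottom = self._gain_pair()
        return np.linspace(top, bottom, self.image_height)

    def geometry(self, search_halfwidth: int = 20, band_halfwidth: int = 3,
                 c_min_relative: float = 5.0) -> StripGeometry:
        """Pipeline geometry matching this spec (expected positions in profile rows)."""
        return StripGeometry(
            expected_c=self.c_band_center - int(self.roi.row_start),
            expected_t=self.t_band_center - int(self.roi.row_start),
            search_halfwidth=search_halfwidth,
            band_halfwidth=band_halfwidth,
            c_min_relative=c_min_relative,
        )


@dataclass
class GroundTruth:
    """Nominal annotations serialized alongside every generated image."""

    kind: str  # "strip" | "calibration_cassette"
    seed: int
    noise_sd: float
    illumination_gain: float | list[float]
    background_gray: float | None = None
    bands: dict | None = None          # {"C": {...}, "T": {...}} for strips
    patches: list[dict] | None = None  # calibration cassettes
    concentration: float | None = None
    extrapolated: bool | None = None

    def __post_init__(self) -> None:
        if isinstance(self.illumination_gain, tuple):
            self.illumination_gain = list(self.illumination_gain)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------

def _band_weights(n_rows: int, center: int, width: int) -> np.ndarray:
    """Longitudinal band profile: rectangular core of ``width`` rows, 1-px half ramps."""
    w = np.zeros(n_rows)
    lo = center - width // 2
    hi = lo + width
    w[max(lo, 0):min(hi, n_rows)] = 1.0
    if lo - 1 >= 0:
        w[lo - 1] = 0.5
    if hi < n_rows:
        w[hi] = 0.5
    return w


def _dither_row(row: np.ndarray) -> np.ndarray:
    """Quantize a row so each constant-valued run keeps its mean (Bresenham spread)."""
    out = np.empty_like(row)
    for v in np.unique(row):
        idx = np.flatnonzero(row == v)
        base = np.floor(v)
        k = int(round((v - base) * idx.size))
        hits = (np.arange(idx.size) * k) % idx.size < k  # exactly k, evenly spaced
        out[idx] = base + hits
    return out


def _quantize(field: np.ndarray, noisy: bool) -> np.ndarray:
    field = np.clip(field, 0.0, 255.0)
    if noisy:
        return np.rint(field)
    return np.vstack([_dither_row(row) for row in field])


def _render_rgb(field: np.ndarray, band_mask: np.ndarray | None, mode: str,
                noisy: bool) -> np.ndarray:
    """Turn a float grayscale field into an 8-bit RGB image.

    ``gray_patch`` renders neutral pixels.  ``fixed_red_channel`` renders
    band pixels with R = 255 and G = B chosen so the luminance matches the
    field (clipped at the R-only floor of 76.245).
    """
    q = _quantize(field, noisy)
    rgb = np.repeat(q[:, :, None], 3, axis=2)
    if mode == "fixed_red_channel" and band_mask is not None and band_mask.any():
        gb = np.clip((field - _RED_FIXED_GRAY) / _GB_WEIGHT, 0.0, 255.0)
        qgb = _quantize(gb, noisy)
        rgb[band_mask, 0] = 255
        rgb[band_mask, 1] = qgb[band_mask]
        rgb[band_mask, 2] = qgb[band_mask]
    return rgb.astype(np.uint8)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_strip(spec: StripSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one cassette strip image with its ground truth.

    With ``noise_sd = 0`` and unit gain, the luminance of T-band core pixels
    reproduces ``t_band_gray`` (exactly for integer grays in ``gray_patch``
    mode, to within quantization otherwise) and the transverse band mean
    matches it to well under 0.01 gray.  Same seed, same spec => identical
    pixels.
    """
    h, w = spec.image_height, spec.image_width
    roi = spec.roi
    field = np.full((h, w), spec.background_gray, dtype=np.float64)
    band_mask = np.zeros((h, w), dtype=bool)

    cs, ce = int(roi.col_start), int(roi.col_end)
    for center, gray in ((spec.c_band_center, spec.c_band_gray),
                         (spec.t_band_center, spec.t_band_gray)):
        wts = _band_weights(h, center, spec.band_width)
        rows = np.flatnonzero(wts > 0)
        field[rows, cs:ce] = spec.background_gray + \
            wts[rows, None] * (gray - spec.background_gray)
        band_mask[rows, cs:ce] = True

    field *= spec.gain_per_row()[:, None]
    np.clip(field, 0.0, 255.0, out=field)

    noisy = spec.noise_sd > 0
    if noisy:
        rng = np.random.default_rng(spec.seed)
        field = np.clip(field + rng.normal(0.0, spec.noise_sd, field.shape), 0.0, 255.0)

    rgb = _render_rgb(field, band_mask, spec.band_rgb_mode, noisy)

    gain = spec.illumination_gain
    truth = GroundTruth(
        kind="strip",
        seed=spec.seed,
        noise_sd=spec.noise_sd,
        illumination_gain=list(gain) if isinstance(gain, tuple) else float(gain),
        background_gray=spec.background_gray,
        bands={
            "C": {
                "center": spec.c_band_center,
                "profile_index": spec.c_band_center - int(roi.row_start),
                "gray": spec.c_band_gray,
                "relative_grayscale": spec.background_gray - spec.c_band_gray,
            },
            "T": {
                "center": spec.t_band_center,
                "profile_index": spec.t_band_center - int(roi.row_start),
                "gray": spec.t_band_gray,
                "relative_grayscale": spec.background_gray - spec.t_band_gray,
            },
        },
    )
    return rgb, truth


def calibration_patch_rois(n_patches: int, patch_height: int = 60,
                           image_width: int = 200) -> list[ROISpec]:
    """Patch measurement windows for an ``n_patches``-patch calibration cassette."""
    margin = 10
    return [
        ROISpec(i * patch_height + margin, (i + 1) * patch_height - margin, 40,
                image_width - 40)
        for i in range(n_patches)
    ]


def generate_calibration_cassette(
    patch_targets,
    applied_gain: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    patch_height: int = 60,
    image_width: int = 200,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a calibration cassette: flat patches of known target grays.

    Each patch renders at ``clamp(target * applied_gain, 0, 255)``; the
    ground truth records the rendered value and whether it clamped.
    """
    targets = [float(t) for t in patch_targets]
    if not targets:
        raise DomainError("patch_targets must be non-empty")
    if any(not (0.0 < t <= 255.0) for t in targets):
        raise DomainError("patch targets must lie in (0, 255]")
    if applied_gain <= 0:
        raise DomainError("applied_gain must be positive")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")

    h = patch_height * len(targets)
    field = np.full((h, image_width), 255.0 * min(applied_gain, 1.0))
    rois = calibration_patch_rois(len(targets), patch_height, image_width)
    patches = []
    for target, roi in zip(targets, rois):
        rendered = target * applied_gain
        clamped = not (0.0 <= rendered <= 255.0)
        rendered = min(max(rendered, 0.0), 255.0)
        field[int(roi.row_start):int(roi.row_end),
              int(roi.col_start):int(roi.col_end)] = rendered
        patches.append({
            "target_gray": target,
            "rendered_gray": rendered,
            "clamped": clamped,
            "roi": [int(roi.row_start), int(roi.row_end),
                    int(roi.col_start), int(roi.col_end)],
        })

    noisy = noise_sd > 0
    if noisy:
        rng = np.random.default_rng(seed)
        field = np.clip(field + rng.normal(0.0, noise_sd, field.shape), 0.0, 255.0)
    rgb = _render_rgb(field, None, "gray_patch", noisy)

    truth = GroundTruth(
        kind="calibration_cassette",
        seed=seed,
        noise_sd=noise_sd,
        illumination_gain=float(applied_gain),
        patches=patches,
    )
    return rgb, truth


def generate_dose_series(
    curve: CalibrationCurve,
    concentrations,
    replicates: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    spec: StripSpec | None = None,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Strips whose nominal T-band contrast follows ``curve`` at each concentration.

    The T band renders at ``background_gray - curve.evaluate(c)``, so the
    nominal relative grayscale equals the curve value; the blank's nonzero
    contrast is a faint T band — the curve, not binding chemistry, drives
    darkness.  Replicates differ only by their noise realization (seeds are
    spawned deterministically from ``seed``).  Concentrations beyond the
    knot range are flagged ``extrapolated`` in the ground truth.
    """
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    base = spec if spec is not None else StripSpec()
    concs = [float(c) for c in concentrations]
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(concs) * replicates) & 0x7FFFFFFF

    out: list[tuple[np.ndarray, GroundTruth]] = []
    lo, hi = curve.concentrations[0], curve.concentrations[-1]
    for i, conc in enumerate(concs):
        rel = curve.evaluate(conc)
        t_gray = base.background_gray - rel
        if t_gray < 0:
            raise DomainError(
                f"curve contrast {rel} exceeds background {base.background_gray}")
        for r in range(replicates):
            child = int(child_seeds[i * replicates + r])
            strip_spec = dataclasses.replace(
                base, t_band_gray=t_gray, noise_sd=noise_sd, seed=child)
            rgb, truth = generate_strip(strip_spec)
            truth.concentration = conc
            truth.extrapolated = bool(conc < lo or conc > hi)
            out.append((rgb, truth))
    return out
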