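"""Device-to-device grayscale normalization via a calibration cassette.

LED intensity and darkroom build differences shift and scale the grayscale a
given device records for the same strip.  Reading a cassette of patches with
known target grays at session start and fitting an affine map
``target ~ gain * measured + offset`` absorbs those differences; applying
the fitted correction to subsequent reads makes devices and sessions agree.
Affine is the minimal model for an exposure/illumination disturbance, and a
gain-only error is exactly what multiplicative lighting changes produce on
the baseline-subtracted band contrast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np

from .errors import CalibrationError, DegenerateFitError, DomainError
from .imaging import ROISpec, extract_roi, rgb_to_gray


@dataclass(frozen=True)
class CalibrationPatch:
    """One reference patch: where it is, what it should read, what it read."""

    target_gray: float
    measured_gray: float
    roi: ROISpec | None = None


@dataclass(frozen=True)
class CalibrationPatchSet:
    patches: tuple[CalibrationPatch, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", tuple(self.patches))
        if len(self.patches) < 2:
            raise DomainError("need at least 2 calibration patches")
        targets = {p.target_gray for p in self.patches}
        if len(targets) < 2:
            raise DomainError("calibration patches must have distinct target grays")
        for p in self.patches:
            if not (0.0 <= p.measured_gray <= 255.0):
                raise DomainError(f"measured gray {p.measured_gray} outside [0, 255]")


@dataclass(frozen=True)
class DeviceCorrection:
    """Affine grayscale correction for one device/session."""

    gain: float
    offset: float
    fit_residual_rms: float
    timestamp: str
    correction_id: str

    def to_json(self) -> str:
        return json.dumps({
            "gain": self.gain,
            "offset": self.offset,
            "fit_residual_rms": self.fit_residual_rms,
            "timestamp": self.timestamp,
            "correction_id": self.correction_id,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DeviceCorrection":
        return cls(**json.loads(text))


IDENTITY_CORRECTION = DeviceCorrection(
    gain=1.0, offset=0.0, fit_residual_rms=0.0, timestamp="", correction_id="identity")


def measure_patches(image_rgb: np.ndarray, rois, target_grays) -> CalibrationPatchSet:
    """Read the mean gray of each patch window on a calibration-cassette image."""
    gray = rgb_to_gray(image_rgb)
    patches = []
    for roi, target in zip(rois, target_grays):
        patches.append(CalibrationPatch(
            target_gray=float(target),
            measured_gray=float(extract_roi(gray, roi).mean()),
            roi=roi,
        ))
    return CalibrationPatchSet(tuple(patches))


def fit_correction(patch_set: CalibrationPatchSet) -> DeviceCorrection:
    """Least-squares affine fit ``target ~ gain * measured + offset``."""
    measured = np.array([p.measured_gray for p in patch_set.patches])
    targets = np.array([p.target_gray for p in patch_set.patches])
    if np.ptp(measured) < 1e-9:
        raise DegenerateFitError(
            "all patches measured the same gray; affine fit is underdetermined")
    gain, offset = np.polyfit(measured, targets, 1)
    if gain <= 0:
        raise CalibrationError(f"fitted gain {gain:.4f} is not positive")
    residuals = gain * measured + offset - targets
    rms = float(np.sqrt(np.mean(residuals ** 2)))
    ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
    cid = f"cal-{abs(hash((round(float(gain), 6), round(float(offset), 6)))) % 10**8:08d}"
    return DeviceCorrection(
        gain=float(gain), offset=float(offset), fit_residual_rms=rms,
        timestamp=ts, correction_id=cid,
    )


def apply_correction(correction: DeviceCorrection, gray):
    """Elementwise ``gain * x + offset`` clamped to [0, 255].

    Accepts a scalar, a profile, or a grayscale image; returns the same
    shape (a float scalar for scalar input).
    """
    arr = np.asarray(gray, dtype=np.float64)
    out = np.clip(correction.gain * arr + correction.offset, 0.0, 255.0)
    return float(out) if out.ndim == 0 else out
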