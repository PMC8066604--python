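"""Dose quantification: calibration-curve inversion, thresholding, replicate stats.

The assay's dose response is carried as a monotone set of
(concentration, relative grayscale) knots.  Concentration is interpolated
piecewise-linearly on a ``log10(concentration + 1)`` axis — lateral-flow
dose responses are strongly sublinear in concentration, and knot
interpolation reproduces the calibration points exactly without asserting a
parametric fit the data do not pin down.

The qualitative call uses a strict threshold: a sample is positive iff its
concentration *exceeds* the assay's lower threshold (50 ng/mL for fecal
occult blood).  Borderline calls flip on the strictness, so it is applied
exactly as stated.

Replicate statistics follow the assay-validation convention: sample SD
(n - 1 denominator) and CV = 100 * SD / mean.  Display formatting rounds
means and SDs half-up to 2 decimals and truncates CVs to 2 decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

import numpy as np

from . import imaging
from .errors import CurveError, DomainError

#: Clamp flags for curve inversion.
CLAMP_NONE = "none"
CLAMP_BELOW_BLANK = "below_blank"
CLAMP_ABOVE_UPPER = "above_upper"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (display convention for means and SDs)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def floor_decimals(x: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals (display convention for CVs)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_DOWN))


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone dose-response curve as (concentration ng/mL, relative grayscale) knots.

    Concentrations must be strictly increasing starting at the blank (0);
    relative grayscale must be strictly increasing with concentration.
    Interpolation is piecewise linear in ``log10(concentration + 1)``.
    """

    knots: tuple[tuple[float, float], ...]
    form: str = "piecewise_linear_log_conc"
    upper_limit: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        knots = tuple((float(c), float(g)) for c, g in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 2:
            raise CurveError("calibration curve needs at least 2 knots")
        concs = [c for c, _ in knots]
        grays = [g for _, g in knots]
        if concs[0] < 0:
            raise CurveError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise CurveError("knot concentrations must be strictly increasing")
        if any(b <= a for a, b in zip(grays, grays[1:])):
            raise CurveError(
                "relative grayscale must increase strictly with concentration"
            )
        if self.form != "piecewise_linear_log_conc":
            raise CurveError(f"unknown curve form {self.form!r}")
        if self.upper_limit is None:
            object.__setattr__(self, "upper_limit", concs[-1])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.knots])

    @property
    def relative_grayscales(self) -> np.ndarray:
        return np.array([g for _, g in self.knots])

    def _log_axis(self) -> np.ndarray:
        return np.log10(self.concentrations + 1.0)

    def evaluate(self, concentration: float) -> float:
        """Relative grayscale expected at ``concentration`` (clamped to knot range)."""
        if concentration < 0:
            raise DomainError("concentration must be non-negative")
        lc = math.log10(float(concentration) + 1.0)
        return float(np.interp(lc, self._log_axis(), self.relative_grayscales))

    def invert(self, relative_grayscale: float) -> tuple[float, str]:
        """Concentration whose expected response equals ``relative_grayscale``.

        Values below the blank knot clamp to 0 (flag ``below_blank``);
        values above the top knot clamp to the upper detection limit
        (flag ``above_upper``).  Knot inputs return knot concentrations.
        """
        grays = self.relative_grayscales
        if relative_grayscale < grays[0]:
            return 0.0, CLAMP_BELOW_BLANK
        if relative_grayscale > grays[-1]:
            return float(self.upper_limit), CLAMP_ABOVE_UPPER
        lc = float(np.interp(relative_grayscale, grays, self._log_axis()))
        conc = 10.0 ** lc - 1.0
        conc = min(max(conc, 0.0), float(self.upper_limit))
        return conc, CLAMP_NONE

    def to_dict(self) -> dict:
        return {
            "knots": [[c, g] for c, g in self.knots],
            "form": self.form,
            "upper_limit": self.upper_limit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            knots=tuple((float(c), float(g)) for c, g in d["knots"]),
            form=d.get("form", "piecewise_linear_log_conc"),
            upper_limit=d.get("upper_limit"),
        )


def classify(concentration: float, lower_threshold: float) -> str:
    """Positive iff the concentration strictly exceeds the threshold."""
    return "positive" if concentration > lower_threshold else "negative"


@dataclass(frozen=True)
class ReplicateStats:
    """Replicate summary: n, mean, sample SD (n-1) and CV% = 100*SD/mean."""

    n: int
    mean: float
    sd: float | None
    cv: float | None

    def formatted(self) -> dict[str, str]:
        """Table-style display: mean/SD half-up at 2 dp, CV truncated at 2 dp."""
        out = {"mean": f"{round_half_up(self.mean):.2f}"}
        out["sd"] = "" if self.sd is None else f"{round_half_up(self.sd):.2f}"
        out["cv"] = "" if self.cv is None else f"{floor_decimals(self.cv):.2f}%"
        return out


def replicate_stats(values) -> ReplicateStats:
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise DomainError("replicate_stats requires at least one value")
    mean = float(arr.mean())
    if arr.size < 2:
        return ReplicateStats(n=1, mean=mean, sd=None, cv=None)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        return ReplicateStats(n=int(arr.size), mean=mean, sd=0.0, cv=0.0)
    if mean == 0.0:
        raise DomainError("CV is undefined for zero mean")
    return ReplicateStats(n=int(arr.size), mean=mean, sd=sd, cv=100.0 * sd / mean)


@dataclass(frozen=True)
class AssayResult:
    """Outcome of one strip read.

    ``qualitative_call`` is "invalid" when the control line failed (the
    sample never flowed), in which case no concentration is reported.
    """

    qualitative_call: str  # "positive" | "negative" | "invalid"
    relative_grayscale: float | None = None
    concentration: float | None = None
    clamped: str = CLAMP_NONE
    c_relative_grayscale: float | None = None
    device_correction_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "qualitative_call": self.qualitative_call,
            "relative_grayscale": self.relative_grayscale,
            "concentration_ng_ml": self.concentration,
            "clamped": self.clamped,
            "c_relative_grayscale": self.c_relative_grayscale,
            "device_correction_id": self.device_correction_id,
        }


def quantify(
    profile: np.ndarray,
    geometry: imaging.StripGeometry,
    curve: CalibrationCurve,
    lower_threshold: float,
    correction=None,
) -> AssayResult:
    """Full read of one longitudinal profile: bands -> correction -> curve -> call.

    The device correction (if any) is applied to the profile before band
    detection so that its gain acts on the relative grayscale while its
    offset cancels in the baseline subtraction.  An invalid control line
    short-circuits to an "invalid" call with no concentration.
    """
    if correction is not None:
        from .calibration import apply_correction

        profile = apply_correction(correction, profile)
        correction_id = correction.correction_id
    else:
        correction_id = None

    c_band, t_band, valid = imaging.detect_bands(
        profile,
        expected_c=geometry.expected_c,
        expected_t=geometry.expected_t,
        search_halfwidth=geometry.search_halfwidth,
        band_halfwidth=geometry.band_halfwidth,
        c_min_relative=geometry.c_min_relative,
    )
    if not valid:
        return AssayResult(
            qualitative_call="invalid",
            c_relative_grayscale=c_band.relative_grayscale,
            device_correction_id=correction_id,
        )
    conc, clamped = curve.invert(t_band.relative_grayscale)
    return AssayResult(
        qualitative_call=classify(conc, lower_threshold),
        relative_grayscale=t_band.relative_grayscale,
        concentration=conc,
        clamped=clamped,
        c_relative_grayscale=c_band.relative_grayscale,
        device_correction_id=correction_id,
    )
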