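"""Exception hierarchy shared across the reader pipeline."""


class LFAError(Exception):
    """Base class for all lfareader errors."""


class GeometryError(LFAError, ValueError):
    """ROI, window or band placement is out of bounds, empty or overlapping."""


class DomainError(LFAError, ValueError):
    """A value is outside its physical domain (gray levels, gains, counts)."""


class CurveError(LFAError, ValueError):
    """A calibration curve violates monotonicity or knot ordering."""


class CalibrationError(LFAError, ValueError):
    """Device-correction fitting or application failed."""


class DegenerateFitError(CalibrationError):
    """All calibration patches measured identical gray; the affine fit is underdetermined."""


class QRCodecError(LFAError, RuntimeError):
    """QR barcode image encoding/decoding is unavailable or failed."""
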