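"""Assay metadata carried on the QR cassette.

Each reagent lot ships a QR cassette encoding everything the reader needs to
quantify that lot: the calibration curve, the number of sample holes on the
cassette, the test item names, and the assay's upper detection limit and
lower (positivity) threshold.  The wire format is canonical JSON — key-sorted
with minimal separators — so encoding the same payload twice is
byte-identical and the curve travels as explicit knots (the device
interpolates; it never refits).

Rendering the JSON into an actual QR barcode and reading one back from a
photo are delegated to the optional ``qrcode`` / ``pyzbar`` packages; the
codec itself is pure JSON and fully functional without them.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import QRCodecError
from .quant import CalibrationCurve

SCHEMA_VERSION = "1.0"

__all__ = [
    "QRPayload", "CurveSpec", "encode_payload", "decode_payload",
    "encode_qr_image", "decode_qr_image", "ValidationError",
]


class CurveSpec(BaseModel):
    """Serialized calibration curve: knots plus interpolation form."""

    model_config = ConfigDict(extra="forbid")

    knots: list[tuple[float, float]] = Field(min_length=2)
    form: str = "piecewise_linear_log_conc"
    upper_limit: float

    @model_validator(mode="after")
    def _monotone(self) -> "CurveSpec":
        CalibrationCurve(tuple(self.knots), form=self.form,
                         upper_limit=self.upper_limit)  # raises CurveError
        return self

    def to_curve(self) -> CalibrationCurve:
        return CalibrationCurve(tuple(self.knots), form=self.form,
                                upper_limit=self.upper_limit)

    @classmethod
    def from_curve(cls, curve: CalibrationCurve) -> "CurveSpec":
        return cls(knots=list(curve.knots), form=curve.form,
                   upper_limit=curve.upper_limit)


class QRPayload(BaseModel):
    """The five-field assay descriptor carried by the QR cassette."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    test_items: list[str] = Field(min_length=1)
    n_sample_holes: int = Field(gt=0)
    calibration_curve: CurveSpec
    upper_detection_limit: float = Field(gt=0)
    lower_threshold: float = Field(ge=0)

    @model_validator(mode="after")
    def _consistent(self) -> "QRPayload":
        if self.lower_threshold >= self.upper_detection_limit:
            raise ValueError(
                "lower_threshold must be below upper_detection_limit")
        concs = [c for c, _ in self.calibration_curve.knots]
        if concs[0] != 0.0 or concs[-1] != self.upper_detection_limit:
            raise ValueError(
                "calibration curve knots must span [0, upper_detection_limit]")
        return self


def encode_payload(payload: QRPayload) -> str:
    """Canonical JSON text for ``payload`` (key-sorted, minimal separators)."""
    return json.dumps(payload.model_dump(), sort_keys=True,
                      separators=(",", ":"), allow_nan=False)


def decode_payload(source: str | Path) -> QRPayload:
    """Validate a payload from JSON text or a ``.json`` file path.

    Raises ``pydantic.ValidationError`` naming the failing fields for a
    schema violation, ``json.JSONDecodeError`` for unparseable text.
    """
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = source
        as_path = Path(text)
        try:
            if as_path.suffix == ".json" and as_path.is_file():
                text = as_path.read_text()
        except OSError:  # e.g. name too long to be a path
            pass
    return QRPayload.model_validate(json.loads(text))


def encode_qr_image(payload: QRPayload, path: str | Path) -> Path:
    """Render the canonical JSON into a QR barcode PNG (optional ``qrcode``)."""
    try:
        import qrcode  # type: ignore[import-not-found]
    except ImportError as exc:
        raise QRCodecError(
            "QR barcode rendering requires the optional 'qrcode' package "
            "(pip install lfareader[qr]); the canonical JSON from "
            "encode_payload() carries the same content") from exc
    img = qrcode.make(encode_payload(payload))
    path = Path(path)
    img.save(path)
    return path


def decode_qr_image(image) -> QRPayload:
    """Decode a QR barcode image back into a payload (optional ``pyzbar``)."""
    try:
        from pyzbar.pyzbar import decode as zbar_decode  # type: ignore[import-not-found]
    except ImportError as exc:
        raise QRCodecError(
            "QR barcode reading requires the optional 'pyzbar' package "
            "(pip install lfareader[qr]); pass JSON text to decode_payload() "
            "instead") from exc
    symbols = zbar_decode(image)
    if not symbols:
        raise QRCodecError("no QR code found in image")
    return decode_payload(symbols[0].data.decode("utf-8"))
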