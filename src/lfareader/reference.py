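"""Published fecal-occult-blood (FOB) reference data for this assay lot.

Seven concentrations (0–1000 ng/mL) were each read in triplicate on the
reference device; the per-concentration average relative grayscale defines
the lot's calibration curve.  The FOB positivity threshold is 50 ng/mL and
the upper detection limit 1000 ng/mL.
"""

from __future__ import annotations

from .payload import CurveSpec, QRPayload
from .quant import CalibrationCurve, ReplicateStats, replicate_stats, round_half_up

FOB_LOWER_THRESHOLD_NG_ML = 50.0
FOB_UPPER_LIMIT_NG_ML = 1000.0

#: Relative-grayscale replicate triplets per FOB concentration (ng/mL),
#: measured on the reference device.
FOB_REPLICATES: dict[float, tuple[float, float, float]] = {
    0.0: (12.73, 12.91, 12.79),
    25.0: (13.24, 13.19, 13.31),
    50.0: (15.21, 14.98, 14.18),
    100.0: (16.16, 15.91, 15.42),
    200.0: (20.13, 19.24, 19.85),
    400.0: (26.38, 26.71, 26.43),
    1000.0: (56.31, 52.45, 48.53),
}


def fob_replicate_stats() -> dict[float, ReplicateStats]:
    """Average / sample SD / CV per concentration, ascending concentration."""
    return {c: replicate_stats(v) for c, v in sorted(FOB_REPLICATES.items())}


def fob_calibration_curve() -> CalibrationCurve:
    """The lot calibration curve: knots at the 2-dp rounded replicate averages."""
    knots = tuple(
        (conc, round_half_up(replicate_stats(vals).mean))
        for conc, vals in sorted(FOB_REPLICATES.items())
    )
    return CalibrationCurve(knots=knots, upper_limit=FOB_UPPER_LIMIT_NG_ML)


def fob_payload(n_sample_holes: int = 1) -> QRPayload:
    """The QR-cassette payload for this FOB lot."""
    return QRPayload(
        test_items=["FOB"],
        n_sample_holes=n_sample_holes,
        calibration_curve=CurveSpec.from_curve(fob_calibration_curve()),
        upper_detection_limit=FOB_UPPER_LIMIT_NG_ML,
        lower_threshold=FOB_LOWER_THRESHOLD_NG_ML,
    )
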