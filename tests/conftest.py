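import numpy as np
import pytest
from hypothesis import settings

import lfareader as L

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fob_curve():
    return L.fob_calibration_curve()


@pytest.fixture
def default_spec():
    return L.StripSpec()


def read_bands(img, spec, **geom_overrides):
    """Run the full densitometry chain on a generated image."""
    geom = spec.geometry(**geom_overrides)
    gray = L.rgb_to_gray(img)
    profile = L.longitudinal_profile(L.extract_roi(gray, spec.roi))
    bands = L.detect_bands(
        profile,
        expected_c=geom.expected_c,
        expected_t=geom.expected_t,
        search_halfwidth=geom.search_halfwidth,
        band_halfwidth=geom.band_halfwidth,
        c_min_relative=geom.c_min_relative,
    )
    return bands, profile


def strip_profile(img, spec):
    gray = L.rgb_to_gray(img)
    return L.longitudinal_profile(L.extract_roi(gray, spec.roi))
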