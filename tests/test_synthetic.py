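"""Synthetic cassette generator: determinism, photometric fidelity, ground truth."""

import dataclasses

import numpy as np
import pytest

import lfareader as L
from lfareader.errors import DomainError, GeometryError

from conftest import read_bands


class TestGenerateStrip:
    def test_seeded_determinism_bit_exact(self):
        spec = L.StripSpec(seed=7, noise_sd=2.0)
        img1, _ = L.generate_strip(spec)
        img2, _ = L.generate_strip(spec)
        assert img1.dtype == np.uint8
        assert np.array_equal(img1, img2)

    def test_gray_patch_band_pixels_hit_nominal_exactly(self):
        spec = L.StripSpec(t_band_gray=125.0, band_rgb_mode="gray_patch", noise_sd=0.0)
        img, truth = L.generate_strip(spec)
        gray = L.rgb_to_gray(img)
        t = truth.bands["T"]
        core = gray[t["center"] - 2: t["center"] + 3,
                    int(spec.roi.col_start): int(spec.roi.col_end)]
        assert np.abs(core - 125.0).max() <= 0.5

    def test_fixed_red_band_keeps_r_and_matches_luminance(self):
        spec = L.StripSpec(t_band_gray=170.0, band_rgb_mode="fixed_red_channel",
                           noise_sd=0.0)
        img, truth = L.generate_strip(spec)
        t = truth.bands["T"]
        core = img[t["center"] - 2: t["center"] + 3,
                   int(spec.roi.col_start): int(spec.roi.col_end)]
        assert (core[:, :, 0] == 255).all()
        assert np.array_equal(core[:, :, 1], core[:, :, 2])
        gray = L.rgb_to_gray(core)
        # G=B quantization step contributes 0.587+0.114 = 0.701 gray per pixel
        assert np.abs(gray - 170.0).max() <= 0.701
        assert gray.mean() == pytest.approx(170.0, abs=0.05)

    def test_fractional_gray_rendered_in_transverse_mean(self):
        """Dithering makes the band's transverse mean track fractional grays."""
        spec = L.StripSpec(t_band_gray=203.49, noise_sd=0.0)
        img, _ = L.generate_strip(spec)
        (c, t, _), _ = read_bands(img, spec)
        assert t.band_mean_gray == pytest.approx(203.49, abs=0.05)

    def test_detected_gray_monotone_in_nominal(self):
        base = L.StripSpec(background_gray=255.0, noise_sd=0.0)
        detected = []
        for g in np.arange(125.0, 256.0, 10.0):
            img, _ = L.generate_strip(dataclasses.replace(base, t_band_gray=g))
            (c, t, _), _ = read_bands(img, base)
            detected.append(t.band_mean_gray)
        assert (np.diff(detected) > 0).all()

    def test_self_consistency_noise_free(self, default_spec):
        """Pipeline on a noise-free strip recovers the nominal contrast."""
        for t_gray in (140.0, 177.57, 217.19):
            spec = dataclasses.replace(default_spec, t_band_gray=t_gray)
            img, truth = L.generate_strip(spec)
            (c, t, valid), _ = read_bands(img, spec)
            assert valid
            assert t.band_mean_gray == pytest.approx(t_gray, abs=0.5)
            assert t.relative_grayscale == pytest.approx(
                truth.bands["T"]["relative_grayscale"], abs=1.0)

    def test_band_recovery_under_noise(self, default_spec):
        """100 noisy strips: centers within 2 px, contrast within 1.5 gray."""
        seeds = np.random.SeedSequence(2024).generate_state(100) & 0x7FFFFFFF
        nominal = default_spec.background_gray - default_spec.t_band_gray
        for s in seeds:
            spec = dataclasses.replace(default_spec, noise_sd=2.0, seed=int(s))
            img, truth = L.generate_strip(spec)
            (c, t, valid), _ = read_bands(img, spec)
            assert valid
            assert abs(t.center - truth.bands["T"]["profile_index"]) <= 2
            assert abs(t.relative_grayscale - nominal) <= 1.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t_band_gray": 300.0},                      # gray out of range
            {"c_band_gray": 250.0},                      # lighter than the membrane
            {"t_band_center": 10},                       # outside ROI rows
            {"c_band_center": 220, "t_band_center": 230},  # overlap
            {"illumination_gain": 0.0},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises((DomainError, GeometryError)):
            L.generate_strip(L.StripSpec(**kwargs))

    def test_illumination_gain_scales_profile(self, default_spec):
        spec = dataclasses.replace(default_spec, illumination_gain=0.9)
        img, _ = L.generate_strip(spec)
        (c, t, _), _ = read_bands(img, spec)
        nominal = default_spec.background_gray - default_spec.t_band_gray
        assert t.relative_grayscale == pytest.approx(0.9 * nominal, abs=0.5)


class TestGroundTruth:
    def test_json_round_trip_is_lossless(self, default_spec):
        _, truth = L.generate_strip(default_spec)
        assert L.GroundTruth.from_json(truth.to_json()) == truth

    def test_cassette_truth_round_trip(self):
        _, truth = L.generate_calibration_cassette([64.0, 128.0], seed=3)
        assert L.GroundTruth.from_json(truth.to_json()) == truth


class TestCalibrationCassette:
    def _measured(self, img, n):
        gray = L.rgb_to_gray(img)
        return [float(L.extract_roi(gray, roi).mean())
                for roi in L.calibration_patch_rois(n)]

    def test_identity_gain_renders_targets(self):
        img, _ = L.generate_calibration_cassette([64.0, 128.0, 192.0], applied_gain=1.0)
        assert np.allclose(self._measured(img, 3), [64.0, 128.0, 192.0], atol=0.5)

    def test_gain_scales_patches(self):
        img, _ = L.generate_calibration_cassette([100.0], applied_gain=0.9)
        assert self._measured(img, 1)[0] == pytest.approx(90.0, abs=0.5)

    def test_saturation_clamps_and_is_recorded(self):
        img, truth = L.generate_calibration_cassette([200.0], applied_gain=1.5)
        assert self._measured(img, 1)[0] == pytest.approx(255.0, abs=0.5)
        assert truth.patches[0]["clamped"] is True
        assert truth.patches[0]["rendered_gray"] == 255.0

    @pytest.mark.parametrize(
        "targets, gain",
        [([], 1.0), ([0.0], 1.0), ([300.0], 1.0), ([100.0], 0.0), ([100.0], -1.0)],
    )
    def test_invalid_inputs_rejected(self, targets, gain):
        with pytest.raises(DomainError):
            L.generate_calibration_cassette(targets, applied_gain=gain)


class TestDoseSeries:
    def test_nominal_contrast_follows_curve(self, fob_curve, default_spec):
        series = L.generate_dose_series(fob_curve, [400.0, 0.0], 1, seed=1)
        by_conc = {t.concentration: t for _, t in series}
        assert by_conc[400.0].bands["T"]["relative_grayscale"] == pytest.approx(26.51)
        assert by_conc[0.0].bands["T"]["relative_grayscale"] == pytest.approx(12.81)

    def test_zero_noise_replicates_identical(self, fob_curve, default_spec):
        series = L.generate_dose_series(fob_curve, [100.0], 3, noise_sd=0.0, seed=9)
        reads = []
        for img, _ in series:
            (c, t, _), _ = read_bands(img, default_spec)
            reads.append(t.relative_grayscale)
        stats = L.replicate_stats(reads)
        assert stats.cv == 0.0

    def test_replicates_must_be_positive(self, fob_curve):
        with pytest.raises(DomainError):
            L.generate_dose_series(fob_curve, [100.0], 0)

    def test_out_of_range_concentration_flagged(self, fob_curve):
        series = L.generate_dose_series(fob_curve, [2000.0], 1)
        assert series[0][1].extrapolated is True
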