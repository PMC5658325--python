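"""Extraction chain: crop, grayscale, denoise, collapse, detect, T/C."""

import numpy as np
import pytest
from scipy import ndimage

from lfaquant import signal_extraction as se
from lfaquant import strip_model as sm
from lfaquant.errors import (
    ConfigError,
    FormatError,
    GeometryError,
    InvalidStripError,
    MissingLineError,
)


def make_image(pixels, ppm=20.0):
    return se.StripImage(pixels=np.asarray(pixels, float), pixels_per_mm=ppm)


class TestCrop:
    def test_full_roi_is_identity(self, noiseless_strip):
        img = noiseless_strip(1.0)
        out = se.crop_roi(img, (0, img.n_rows, 0, img.n_cols))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_out_of_bounds_roi_rejected(self, noiseless_strip):
        img = noiseless_strip(1.0)
        with pytest.raises(GeometryError):
            se.crop_roi(img, (0, img.n_rows + 1, 0, img.n_cols))

    def test_degenerate_roi_rejected(self, noiseless_strip):
        img = noiseless_strip(1.0)
        with pytest.raises(GeometryError):
            se.crop_roi(img, (0, img.n_rows, 5, 5))

    def test_roi_excluding_control_line_raises_missing_control(self, noiseless_strip):
        # crop keeps the test line near its downstream edge: no room for a
        # test line upstream of the lone detected peak, so the control is
        # the line that is missing
        img = noiseless_strip(2.0)
        cropped = se.crop_roi(img, (0, img.n_rows, 140, 250))  # 7-12.5 mm at 20 px/mm
        cfg = se.ExtractionConfig(expected_separation_px=80.0)
        with pytest.raises(MissingLineError) as exc_info:
            se.quantify_image(cropped, cfg)
        assert exc_info.value.which == "control"


class TestGrayscale:
    def test_gray_rgb_passes_value_through(self):
        rgb = np.full((4, 30, 3), 0.42)
        np.testing.assert_allclose(se.to_grayscale(rgb), 0.42)

    def test_pure_green_maps_to_its_luma_weight(self):
        rgb = np.zeros((2, 25, 3))
        rgb[..., 1] = 1.0
        np.testing.assert_allclose(se.to_grayscale(rgb), 0.587)

    def test_single_channel_unchanged(self):
        arr = np.random.default_rng(0).uniform(size=(5, 40))
        np.testing.assert_array_equal(se.to_grayscale(arr), arr)

    def test_unknown_channel_count_rejected(self):
        with pytest.raises(FormatError):
            se.to_grayscale(np.zeros((3, 20, 2)))


class TestDenoise:
    def test_sigma_zero_is_identity(self):
        img = make_image(np.random.default_rng(1).uniform(size=(6, 50)))
        np.testing.assert_array_equal(se.denoise(img, 0.0).pixels, img.pixels)

    def test_constant_image_preserved(self):
        img = make_image(np.full((6, 50), 0.7))
        np.testing.assert_allclose(se.denoise(img, 3.0).pixels, 0.7)

    def test_impulse_response_is_normalized_gaussian(self):
        arr = np.zeros((41, 41))
        arr[20, 20] = 1.0
        out = se.denoise(make_image(arr), 2.0).pixels
        assert out.sum() == pytest.approx(1.0, abs=1e-9)  # mass conserved
        # response profile proportional to a Gaussian of the same sigma
        x = np.arange(41) - 20
        expected = np.exp(-(x**2) / (2 * 2.0**2))
        row = out[20] / out[20, 20]
        assert np.corrcoef(row, expected / expected[20])[0, 1] > 0.9999


class TestCollapse:
    def test_identical_rows_collapse_to_any_row(self):
        row = np.linspace(0.2, 0.9, 60)
        img = make_image(np.tile(row, (7, 1)))
        np.testing.assert_allclose(se.collapse_to_profile(img, 1).values, row)

    def test_column_median_rejects_one_corrupt_row(self):
        row = np.linspace(0.2, 0.9, 60)
        clean = np.tile(row, (7, 1))
        dirty = clean.copy()
        dirty[3, ::5] = 1.0  # salt noise across one row
        p_clean = se.collapse_to_profile(make_image(clean), 1).values
        p_dirty = se.collapse_to_profile(make_image(dirty), 1).values
        np.testing.assert_allclose(p_dirty, p_clean)

    def test_window_one_single_row_passthrough(self):
        row = np.random.default_rng(2).uniform(size=(1, 30))
        np.testing.assert_allclose(se.collapse_to_profile(make_image(row), 1).values, row[0])

    @pytest.mark.parametrize("window", [2, 4, 1001])
    def test_invalid_median_window_rejected(self, window):
        img = make_image(np.zeros((3, 40)))
        with pytest.raises(ConfigError):
            se.collapse_to_profile(img, window)


class TestDetect:
    def test_peaks_found_at_rendered_line_centers(self, noiseless_strip):
        img = noiseless_strip(2.5)
        prof = se.collapse_to_profile(se.denoise(img, 2.0), 5)
        test, control, _ = se.detect_lines(prof, expected_separation_px=80.0)
        assert test.position_px == pytest.approx(img.meta["test_line_px"], abs=1.0)
        assert control.position_px == pytest.approx(img.meta["control_line_px"], abs=1.0)
        assert test.position_px < control.position_px

    def test_flat_profile_raises_missing_line(self):
        prof = se.IntensityProfile(np.full(300, 0.8), 20.0)
        with pytest.raises(MissingLineError):
            se.detect_lines(prof, 80.0)

    def test_depths_are_baseline_relative(self, noiseless_strip):
        img = noiseless_strip(2.0)
        prof = se.collapse_to_profile(se.denoise(img, 2.0), 5)
        _, control, _ = se.detect_lines(prof, 80.0)
        assert control.baseline == pytest.approx(0.85, abs=1e-6)
        assert control.depth == pytest.approx(control.baseline - control.raw_min)


class TestComputeTC:
    def test_ratio_of_depths(self):
        t = se.LinePeak(10, 0.3, 0.8, 2.0, 2.0)
        c = se.LinePeak(90, 0.5, 0.8, 1.0, 1.0)
        assert se.compute_tc(t, c, min_control_depth=0.01).tc_ratio == pytest.approx(2.0)

    def test_equal_depths_give_unity(self):
        t = se.LinePeak(10, 0.5, 0.8, 0.3, 0.3)
        c = se.LinePeak(90, 0.5, 0.8, 0.3, 0.3)
        assert se.compute_tc(t, c).tc_ratio == pytest.approx(1.0)

    def test_weak_control_is_invalid_strip(self):
        t = se.LinePeak(10, 0.5, 0.8, 0.3, 0.3)
        c = se.LinePeak(90, 0.795, 0.8, 0.005, 0.005)
        with pytest.raises(InvalidStripError):
            se.compute_tc(t, c, min_control_depth=0.01)


class TestQuantifyRoundTrip:
    def test_noiseless_round_trip_within_1e3(self, noiseless_strip):
        for tc_true in np.linspace(0.2, 6.0, 20):
            res = se.quantify_image(noiseless_strip(float(tc_true)))
            assert abs(res.tc_ratio - tc_true) <= 1e-3

    def test_zero_concentration_intercept_ratio_recovered(self, noiseless_strip):
        # T/C at zero analyte on the buffer calibration line
        res = se.quantify_image(noiseless_strip(3.983, control_depth=0.12))
        assert res.tc_ratio == pytest.approx(3.983, abs=0.004)

    def test_deterministic_on_same_image(self, noiseless_strip):
        img = noiseless_strip(1.7)
        a = se.quantify_image(img)
        b = se.quantify_image(img)
        assert a.tc_ratio == b.tc_ratio and a.test == b.test and a.control == b.control

    def test_extracted_tc_strictly_increasing_in_truth(self, noiseless_strip):
        extracted = [
            se.quantify_image(noiseless_strip(float(t))).tc_ratio
            for t in np.linspace(0.3, 5.0, 12)
        ]
        assert np.all(np.diff(extracted) > 0)

    def test_offset_invariance(self, noiseless_strip):
        img = noiseless_strip(2.5, background_intensity=0.6)
        shifted = se.StripImage(img.pixels + 0.2, img.pixels_per_mm)
        assert se.quantify_image(shifted).tc_ratio == pytest.approx(
            se.quantify_image(img).tc_ratio, abs=1e-9
        )

    def test_scale_invariance(self, noiseless_strip):
        img = noiseless_strip(2.5, background_intensity=0.6)
        scaled = se.StripImage(img.pixels * 1.5, img.pixels_per_mm)
        assert se.quantify_image(scaled).tc_ratio == pytest.approx(
            se.quantify_image(img).tc_ratio, abs=1e-9
        )

    def test_noise_robustness_within_5_percent(self, geometry):
        for tc_true in [0.5, 1.5, 3.0, 5.0]:
            clean = sm.render_strip(geometry, sm.OpticalModel(tc_ratio_true=tc_true))
            noisy = sm.render_strip(
                geometry, sm.OpticalModel(tc_ratio_true=tc_true, noise_sigma=0.01, seed=13)
            )
            tc_clean = se.quantify_image(clean).tc_ratio
            tc_noisy = se.quantify_image(noisy).tc_ratio
            assert abs(tc_noisy - tc_clean) / tc_clean < 0.05

    def test_illumination_gradient_tolerated(self, geometry):
        img = sm.render_strip(
            geometry, sm.OpticalModel(tc_ratio_true=2.0, illumination_slope=0.003)
        )
        assert se.quantify_image(img).tc_ratio == pytest.approx(2.0, abs=0.05)

    def test_stage_tagged_on_failure(self, noiseless_strip):
        img = noiseless_strip(2.0)
        cfg = se.ExtractionConfig(min_prominence=10.0)  # nothing can qualify
        with pytest.raises(MissingLineError) as exc_info:
            se.quantify_image(img, cfg)
        assert any("stage: detect" in n for n in getattr(exc_info.value, "__notes__", []))
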