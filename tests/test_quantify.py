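"""Pixel-to-mass impurity-rate quantification and delta calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wheatvision as wv
from wheatvision import synthetic
from wheatvision.quantify import (
    DEFAULT_DELTA,
    CalibrationSample,
    PixelCounts,
    calibrate_delta,
    manual_rate,
    pixel_rate,
)


class TestManualRate:
    def test_no_impurity_is_zero_percent(self):
        assert manual_rate(0.0, 500.0) == 0.0

    def test_five_grams_in_500_is_one_percent(self):
        assert manual_rate(5.0, 500.0) == pytest.approx(1.0)

    def test_all_impurity_is_hundred_percent(self):
        assert manual_rate(3.0, 3.0) == pytest.approx(100.0)

    def test_invalid_masses_rejected(self):
        with pytest.raises(ValueError):
            manual_rate(1.0, 0.0)
        with pytest.raises(ValueError):
            manual_rate(2.0, 1.0)
        with pytest.raises(ValueError):
            manual_rate(-0.5, 1.0)


class TestPixelRate:
    def test_no_impurity_pixels_is_zero(self):
        assert pixel_rate(PixelCounts(t_w=5000, t_z=0), DEFAULT_DELTA) == 0.0

    def test_equal_counts_unit_delta_is_fifty_percent(self):
        assert pixel_rate(PixelCounts(t_w=777, t_z=777), 1.0) == pytest.approx(50.0)

    def test_published_delta_direct_arithmetic(self):
        # 1000 / (1000 + 11.8906 * 10000) * 100
        rate = pixel_rate(PixelCounts(t_w=10000, t_z=1000), 11.8906)
        assert rate == pytest.approx(1000 / 119906 * 100, rel=1e-12)
        assert rate == pytest.approx(0.834, abs=5e-4)

    def test_no_visible_material_is_undefined(self):
        assert math.isnan(pixel_rate(PixelCounts(t_w=0, t_z=0), DEFAULT_DELTA))

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            pixel_rate(PixelCounts(t_w=1, t_z=1), 0.0)

    @given(
        t_w=st.integers(1, 10**6),
        t_z=st.integers(1, 10**6),
        delta=st.floats(0.1, 100.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_and_monotonic(self, t_w, t_z, delta):
        rate = pixel_rate(PixelCounts(t_w=t_w, t_z=t_z), delta)
        assert 0.0 <= rate <= 100.0
        assert pixel_rate(PixelCounts(t_w=t_w, t_z=t_z + 1), delta) > rate
        assert pixel_rate(PixelCounts(t_w=t_w + 1, t_z=t_z), delta) < rate
        assert pixel_rate(PixelCounts(t_w=t_w, t_z=t_z), delta * 1.1) < rate


class TestCalibration:
    def test_single_sample_direct_arithmetic(self):
        # grain: 2 g per 1000 px, impurity: 1 g per 1000 px -> delta = 2
        sample = CalibrationSample(
            counts=PixelCounts(t_w=1000, t_z=1000), w=3.0, w_z=1.0
        )
        result = calibrate_delta([sample])
        assert result.delta == pytest.approx(2.0)
        assert result.n_samples == 1

    def test_equal_densities_give_unit_delta(self):
        samples = [
            CalibrationSample(PixelCounts(2000, 500), w=2.5, w_z=0.5),
            CalibrationSample(PixelCounts(1500, 1500), w=3.0, w_z=1.5),
        ]
        assert calibrate_delta(samples).delta == pytest.approx(1.0)

    def test_noiseless_synthetic_recovers_shipped_delta_exactly(self):
        model = wv.MassModel(noise_cv=0.0)
        spec = wv.SceneSpec(
            image_width=128, image_height=128, n_grains=25, n_impurities=3,
            grain_axis_range=(5, 9), impurity_length_range=(20, 40),
            impurity_width_range=(2, 4),
        )
        samples = synthetic.sample_calibration(5, spec, model, seed=2)
        result = calibrate_delta(samples)
        assert result.delta == pytest.approx(11.8906, rel=1e-12)
        assert result.dispersion == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_ratios_variant(self):
        samples = [
            CalibrationSample(PixelCounts(1000, 1000), w=3.0, w_z=1.0),
            CalibrationSample(PixelCounts(1000, 1000), w=5.0, w_z=1.0),
        ]
        rom = calibrate_delta(samples, method="ratio-of-means").delta
        mor = calibrate_delta(samples, method="mean-of-ratios").delta
        assert rom == pytest.approx(3.0)
        assert mor == pytest.approx(3.0)

    def test_unusable_samples_rejected(self):
        no_impurity = CalibrationSample(PixelCounts(1000, 0), w=2.0, w_z=0.0)
        with pytest.raises(ValueError, match="calibration"):
            calibrate_delta([no_impurity])
        with pytest.raises(ValueError, match="method"):
            calibrate_delta(
                [CalibrationSample(PixelCounts(10, 10), w=2.0, w_z=1.0)],
                method="median",
            )

    def test_json_round_trip(self, tmp_path):
        result = calibrate_delta(
            [CalibrationSample(PixelCounts(1000, 1000), w=3.0, w_z=1.0)]
        )
        path = tmp_path / "calib.json"
        result.to_json(path, note="test")
        again = wv.CalibrationResult.from_json(path)
        assert again == result


class TestDetect:
    def test_oracle_mask_end_to_end_identity(self, rendered):
        # use the ground-truth mask as the "prediction": with delta equal to
        # the true density ratio and no mass noise, the pixel rate must equal
        # the manual mass rate of the same sample
        model = wv.MassModel(noise_cv=0.0)
        w, w_z = wv.sample_masses(rendered.true_counts, model, seed=0)
        p_manual = manual_rate(w_z, w)
        p_pixel = pixel_rate(
            PixelCounts.from_mask(rendered.mask), model.true_delta
        )
        assert p_pixel == pytest.approx(p_manual, rel=1e-10)

    def test_detect_records_counts_and_rate(self, overfit_model, tiny_pairs, tmp_path):
        net, _ = overfit_model
        log = tmp_path / "detections.csv"
        record = wv.detect(
            tiny_pairs[0][0], net, delta=DEFAULT_DELTA,
            image_id="img0", log_path=log,
        )
        assert record.image_id == "img0"
        assert record.counts.t_w > 0
        assert 0.0 <= record.p_z <= 100.0
        assert log.exists()

    def test_repeated_detection_identical_except_timestamp(
        self, overfit_model, tiny_pairs
    ):
        net, _ = overfit_model
        a = wv.detect(tiny_pairs[1][0], net, delta=DEFAULT_DELTA, image_id="x")
        b = wv.detect(tiny_pairs[1][0], net, delta=DEFAULT_DELTA, image_id="x")
        assert a.counts == b.counts
        assert a.p_z == b.p_z
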