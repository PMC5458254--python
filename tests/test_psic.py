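"""PSIC mapping: baseline/peak extraction, Eq-style map algebra, classification."""

import numpy as np
import pytest

from oemri import (
    LABEL_HIGH,
    LABEL_LOW,
    ROI,
    StageTiming,
    baseline_si,
    classify_regions,
    compute_psic_map,
    default_phantom_spec,
    extract_time_curve,
    generate_phantom,
    low_psic_fraction,
    peak_si,
    place_circular_roi,
)
from oemri.phantom import LABEL_CODES

from conftest import make_series


class TestBaselineAndPeak:
    def test_baseline_is_pre_stage_arithmetic_mean(self, timing):
        frames = np.zeros((12, 1, 1))
        frames[:4, 0, 0] = [90, 100, 110, 100]  # pre stage (t = 0..225 s)
        frames[4:, 0, 0] = 100.0
        series = make_series(frames)
        assert baseline_si(series, timing)[0, 0] == pytest.approx(100.0)

    def test_constant_series_baseline_and_peak(self, constant_series, timing):
        assert np.all(baseline_si(constant_series, timing) == 100.0)
        assert np.all(peak_si(constant_series, timing) == 100.0)

    def test_spike_raw_vs_smoothed(self, timing):
        # single spike in the oxygen stage: raw max returns it, a 3-frame
        # moving average attenuates it to the hand-computed value
        frames = np.full((12, 1, 1), 100.0)
        frames[6, 0, 0] = 130.0  # t=450 s, interior to the oxygen stage
        series = make_series(frames)
        assert peak_si(series, timing, smooth_window=1)[0, 0] == 130.0
        assert peak_si(series, timing, smooth_window=3)[0, 0] == pytest.approx(110.0)

    def test_too_few_stage_frames_rejected(self):
        series = make_series(np.full((6, 2, 2), 50.0), frame_interval=200.0)
        # frames at 0,200,...,1000: only frame 0 falls in a [0,200) pre stage
        timing = StageTiming.from_durations((200.0, 400.0, 500.0))
        with pytest.raises(ValueError, match="pre-oxygen"):
            baseline_si(series, timing)
        tight = StageTiming(0.0, 400.0, 600.0, 1100.0)  # oxygen holds one frame
        with pytest.raises(ValueError, match="oxygen"):
            peak_si(series, tight)

    def test_even_smooth_window_rejected(self, constant_series, timing):
        with pytest.raises(ValueError, match="odd"):
            peak_si(constant_series, timing, smooth_window=4)


class TestComputePsicMap:
    def test_direct_substitution(self, timing):
        frames = np.full((12, 1, 1), 100.0)
        frames[4:8, 0, 0] = [104, 108, 110, 109]  # oxygen stage
        series = make_series(frames)
        pmap = compute_psic_map(series, timing, smooth_window=1)
        assert pmap.values[0, 0] == pytest.approx(10.0, abs=1e-12)

    def test_constant_series_gives_zero_map_and_full_low_fraction(
        self, constant_series, timing
    ):
        pmap = compute_psic_map(constant_series, timing, smooth_window=1)
        assert np.all(pmap.values == 0.0)
        mask = np.ones((4, 4), dtype=bool)
        assert low_psic_fraction(pmap, mask) == 1.0

    def test_matches_literal_per_pixel_loop(self, timing):
        # oracle: a literal loop implementation of the percent-change map
        rng = np.random.default_rng(42)
        frames = rng.uniform(50.0, 150.0, size=(10, 4, 4))
        series = make_series(frames, frame_interval=90.0)
        pmap = compute_psic_map(series, timing, smooth_window=1)
        for r in range(4):
            for c in range(4):
                pre = [frames[k, r, c] for k in range(10) if series.times[k] < 300]
                oxy = [frames[k, r, c] for k in range(10)
                       if 300 <= series.times[k] < 600]
                expected = 100.0 * (max(oxy) - sum(pre) / len(pre)) / (sum(pre) / len(pre))
                assert pmap.values[r, c] == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, timing):
        rng = np.random.default_rng(1)
        frames = rng.uniform(50.0, 150.0, size=(12, 5, 5))
        s1 = make_series(frames)
        s2 = make_series(frames * 7.3)
        p1 = compute_psic_map(s1, timing, smooth_window=3)
        p2 = compute_psic_map(s2, timing, smooth_window=3)
        assert np.allclose(p1.values, p2.values, atol=1e-9)

    def test_offset_changes_map_by_exact_algebra(self, timing):
        frames = np.full((12, 1, 1), 100.0)
        frames[4:8, 0, 0] = 120.0
        shift = 50.0
        p1 = compute_psic_map(make_series(frames), timing, smooth_window=1)
        p2 = compute_psic_map(make_series(frames + shift), timing, smooth_window=1)
        base, peak = 100.0, 120.0
        expected = 100.0 * (peak - base) / (base + shift)
        assert p1.values[0, 0] == pytest.approx(20.0)
        assert p2.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_near_zero_baseline_flagged_invalid(self, timing):
        frames = np.full((12, 2, 2), 100.0)
        frames[:, 0, 0] = 0.0  # dead pixel
        pmap = compute_psic_map(make_series(frames), timing)
        assert not pmap.valid_mask[0, 0]
        assert np.isnan(pmap.values[0, 0])
        assert pmap.valid_mask[1, 1]

    def test_noise_free_phantom_reproduces_ground_truth(self, noise_free_phantom, timing):
        spec, series, truth = noise_free_phantom
        pmap = compute_psic_map(series, timing, smooth_window=1)
        assert np.nanmax(np.abs(pmap.values - truth.true_psic_map)) < 1e-9

    def test_noise_free_fraction_equals_pixelized_geometry(
        self, noise_free_phantom, timing
    ):
        spec, series, truth = noise_free_phantom
        pmap = compute_psic_map(series, timing, smooth_window=1)
        frac = low_psic_fraction(pmap, truth.tumor_mask)
        assert frac == pytest.approx(truth.true_low_fraction, abs=1e-12)


class TestClassification:
    def _map_from_values(self, values, timing):
        # baseline exactly 100 so a PSIC of v% is the exact float v
        values = np.asarray(values, dtype=float)
        frames = np.full((12,) + values.shape, 100.0)
        frames[4:8] = 100.0 + values
        return compute_psic_map(make_series(frames), timing, smooth_window=1)

    def test_threshold_and_tie_rule(self, timing):
        pmap = self._map_from_values([[5.0, 10.0, 15.0]], timing)
        labels = classify_regions(pmap, np.ones((1, 3), dtype=bool))
        assert labels.tolist() == [[LABEL_LOW, LABEL_LOW, LABEL_HIGH]]

    def test_all_high(self, timing):
        pmap = self._map_from_values(np.full((2, 2), 20.0), timing)
        labels = classify_regions(pmap, np.ones((2, 2), dtype=bool))
        assert np.all(labels == LABEL_HIGH)

    def test_counting_fraction(self, timing):
        values = np.zeros((10, 10))
        values[:5, :5] = 5.0   # 25 low pixels
        values[values == 0] = 20.0
        pmap = self._map_from_values(values, timing)
        assert low_psic_fraction(pmap, np.ones((10, 10), bool)) == pytest.approx(0.25)

    def test_empty_mask_rejected(self, timing):
        pmap = self._map_from_values(np.full((2, 2), 20.0), timing)
        with pytest.raises(ValueError, match="empty"):
            classify_regions(pmap, np.zeros((2, 2), bool))

    def test_no_valid_tumor_pixels_rejected(self, timing):
        frames = np.zeros((12, 2, 2))
        pmap = compute_psic_map(make_series(frames), timing, epsilon_baseline=1.0)
        with pytest.raises(ValueError, match="valid"):
            low_psic_fraction(pmap, np.ones((2, 2), bool))

    def test_noise_free_labels_match_ground_truth(self, noise_free_phantom, timing):
        spec, series, truth = noise_free_phantom
        pmap = compute_psic_map(series, timing, smooth_window=1)
        labels = classify_regions(pmap, truth.tumor_mask)
        expected_low = np.isin(
            truth.label_map, [LABEL_CODES["necrotic_core"], LABEL_CODES["penumbra"]]
        )
        assert np.array_equal(labels == LABEL_LOW, expected_low)
        assert np.array_equal(
            labels == LABEL_HIGH, truth.label_map == LABEL_CODES["active_tumor"]
        )


class TestTimeCurvesAndROIs:
    def test_single_pixel_curve_is_raw_course(self, timing):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 1, size=(12, 3, 3))
        series = make_series(frames)
        roi = ROI(roi_id="p", pixels=[(1, 2)])
        curve = extract_time_curve(series, roi)
        assert np.array_equal(curve.values, frames[:, 1, 2])

    def test_two_pixel_curve_is_mean(self, timing):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 1, size=(12, 3, 3))
        series = make_series(frames)
        roi = ROI(roi_id="p", pixels=[(0, 0), (2, 1)])
        curve = extract_time_curve(series, roi)
        assert np.allclose(curve.values, (frames[:, 0, 0] + frames[:, 2, 1]) / 2)

    def test_roi_outside_grid_rejected(self, constant_series):
        with pytest.raises(ValueError, match="outside"):
            extract_time_curve(constant_series, ROI(roi_id="x", pixels=[(5, 0)]))

    def test_curve_matches_compartment_kinetics(self, noise_free_phantom):
        spec, series, truth = noise_free_phantom
        active = next(c for c in spec.compartments if c.label == "active_tumor")
        rows, cols = np.nonzero(truth.label_map == LABEL_CODES["active_tumor"])
        roi = ROI(roi_id="a", pixels=np.column_stack((rows[:5], cols[:5])))
        curve = extract_time_curve(series, roi)
        readout = series.times + spec.frame_interval_s
        oxy = (readout > 300) & (readout <= 600)
        expected = active.baseline_si * (
            1 + active.amplitude * (1 - np.exp(-(readout[oxy] - 300) / active.tau_in))
        )
        assert np.allclose(curve.values[oxy], expected, atol=1e-9)

    def test_roi_pixel_count_from_acquisition_geometry(self):
        # 0.98 mm^3 over a 2-mm slice at 0.4167 x 0.8333 mm pixels:
        # 0.49 mm^2 / 0.3472 mm^2 = 1.41 -> one pixel
        roi = place_circular_roi((10.0, 10.0), 0.98, (80 / 96, 80 / 192), 2.0, (96, 192))
        assert len(roi.pixels) == 1
        assert roi.area_mm2 == pytest.approx((80 / 96) * (80 / 192))

    def test_large_roi_area_within_one_pixel_of_target(self):
        roi = place_circular_roi((48.0, 96.0), 200.0, (80 / 96, 80 / 192), 2.0, (96, 192))
        assert abs(roi.area_mm2 - 100.0) <= (80 / 96) * (80 / 192)

    def test_roi_deterministic(self):
        a = place_circular_roi((5.2, 7.7), 12.0, (1.0, 1.0), 2.0, (30, 30))
        b = place_circular_roi((5.2, 7.7), 12.0, (1.0, 1.0), 2.0, (30, 30))
        assert np.array_equal(a.pixels, b.pixels)

    def test_subpixel_target_warns_and_returns_single_pixel(self):
        with pytest.warns(UserWarning, match="single-pixel"):
            roi = place_circular_roi((5.0, 5.0), 0.1, (1.0, 1.0), 2.0, (10, 10))
        assert len(roi.pixels) == 1


class TestNoise:
    def test_max_of_noise_bias_positive_and_decreasing_in_window(self, timing):
        # zero-enhancement noisy series: the raw per-voxel peak is biased
        # upward; smoothing shrinks the bias monotonically
        rng = np.random.default_rng(7)
        frames = 1000.0 + rng.normal(0, 50.0, size=(60, 40, 40))
        series = make_series(frames, frame_interval=15.0)
        biases = []
        for w in (1, 3, 5, 7):
            pmap = compute_psic_map(series, timing, smooth_window=w)
            biases.append(np.nanmean(pmap.values))
        assert all(b > 0 for b in biases)
        assert all(b1 > b2 for b1, b2 in zip(biases, biases[1:]))

    def test_compartment_mean_psic_within_1p5_points_at_snr20(self, timing):
        # pool seven seeds so every compartment mean covers >= 500 pixels
        # (the necrotic core holds only ~84 pixels per phantom)
        sums = {}
        for seed in range(7):
            spec = default_phantom_spec(seed=seed, noise_sigma=50.0)
            series, truth = generate_phantom(spec)
            pmap = compute_psic_map(series, timing)
            for comp in spec.compartments:
                mask = truth.label_map == LABEL_CODES[comp.label]
                vals, true = sums.setdefault(comp.label, ([], comp.true_psic(300.0)))
                vals.append(pmap.values[mask])
        for label, (vals, true) in sums.items():
            pooled = np.concatenate(vals)
            assert pooled.size >= 500
            assert abs(np.nanmean(pooled) - true) <= 1.5, label

    def test_low_fraction_recovery_at_snr20(self, timing):
        for seed in range(10):
            spec = default_phantom_spec(seed=seed, noise_sigma=50.0)
            series, truth = generate_phantom(spec)
            pmap = compute_psic_map(series, timing)
            frac = low_psic_fraction(pmap, truth.tumor_mask)
            assert abs(frac - truth.true_low_fraction) <= 0.05
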