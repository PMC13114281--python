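"""Confidence gating, gap filling, despiking, filtering, scaling, sync."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitwarp import (
    CleaningConfig, GaitConfig, detect_ground_contact, fill_gaps, lowpass,
    mask_low_confidence, pixels_to_height_units, replace_outliers, synchronize,
)
from gaitwarp.pose_io import BODY25_NAMES, KeypointSeries
from gaitwarp.synthetic import generate_waveforms, project_skeleton


def make_series(confidences, fs=60.0):
    """Keypoint series with all points sharing the given per-frame confidence."""
    n = len(confidences)
    p = len(BODY25_NAMES)
    conf = np.tile(np.asarray(confidences, float)[:, None], (1, p))
    return KeypointSeries(
        x=np.ones((n, p)), y=np.ones((n, p)), confidence=conf,
        missing=np.zeros((n, p), dtype=bool), fs=fs,
    )


class TestConfidenceGate:
    def test_strictly_below_threshold_is_masked(self):
        series = make_series([0.9, 0.44, 0.45])
        out, n_masked = mask_low_confidence(series, 0.45)
        assert out.missing[1].all() and not out.missing[0].any()
        assert not out.missing[2].any()  # 0.45 itself survives the gate
        assert n_masked == len(BODY25_NAMES)

    def test_zero_threshold_masks_nothing(self):
        out, n_masked = mask_low_confidence(make_series([0.5, 0.01]), 0.0)
        assert n_masked == 0 and not out.missing.any()

    def test_saturating_gate_masks_everything(self):
        out, _ = mask_low_confidence(make_series([0.1, 0.1, 0.1]), 0.45)
        assert out.missing.all()
        assert np.isnan(out.x).all()

    def test_does_not_touch_surviving_samples(self):
        series = make_series([0.9, 0.2, 0.8])
        out, _ = mask_low_confidence(series, 0.45)
        keep = ~out.missing
        assert np.array_equal(out.x[keep], series.x[keep])


class TestFillGaps:
    def test_linear_interpolation_closed_form(self):
        filled, rep = fill_gaps(np.array([0.0, np.nan, np.nan, 3.0]), max_gap=12)
        assert np.allclose(filled, [0, 1, 2, 3])
        assert rep.n_interpolated == 2 and not rep.excluded

    def test_gap_longer_than_bound_excludes(self):
        x = np.concatenate([[0.0], np.full(13, np.nan), [1.0]])
        _, rep = fill_gaps(x, max_gap=12)
        assert rep.excluded
        assert "13" in rep.exclusion_reason

    def test_gap_at_bound_fills(self):
        x = np.concatenate([[0.0], np.full(12, np.nan), [13.0]])
        filled, rep = fill_gaps(x, max_gap=12)
        assert not rep.excluded
        assert np.allclose(filled, np.arange(14.0))

    def test_clean_signal_is_identity(self):
        x = np.sin(np.arange(20.0))
        filled, rep = fill_gaps(x, max_gap=12)
        assert np.array_equal(filled, x)
        assert rep.n_interpolated == 0

    def test_edges_trimmed_not_extrapolated(self):
        x = np.array([np.nan, np.nan, 1.0, 2.0, np.nan])
        filled, rep = fill_gaps(x, max_gap=12)
        assert np.array_equal(filled, [1.0, 2.0])
        assert (rep.first_valid, rep.last_valid) == (2, 3)

    def test_fully_missing_signal_excluded(self):
        _, rep = fill_gaps(np.full(5, np.nan), max_gap=12)
        assert rep.excluded and "fully missing" in rep.exclusion_reason

    @given(st.data())
    def test_never_alters_finite_samples_and_stays_within_flanks(self, data):
        n = data.draw(st.integers(6, 40))
        vals = data.draw(st.lists(st.floats(-100, 100), min_size=n, max_size=n))
        holes = data.draw(st.sets(st.integers(1, n - 2), max_size=n // 2))
        x = np.array(vals)
        x[list(holes)] = np.nan
        filled, rep = fill_gaps(x, max_gap=n, trim=False)
        if rep.excluded:
            return
        finite = np.isfinite(x)
        assert np.array_equal(filled[finite], x[finite])
        lo, hi = np.nanmin(x), np.nanmax(x)
        assert np.all(filled[np.isfinite(filled)] >= lo - 1e-9)
        assert np.all(filled[np.isfinite(filled)] <= hi + 1e-9)


class TestReplaceOutliers:
    def test_spike_on_ramp_is_replaced_exactly(self):
        ramp = np.linspace(0.0, 10.0, 101)
        x = ramp.copy()
        x[50] += 50.0
        out = replace_outliers(x, window=11, nsigma=3.0)
        assert np.max(np.abs(out - ramp)) < 1e-6

    def test_constant_signal_unchanged(self):
        x = np.full(50, 7.0)
        assert np.array_equal(replace_outliers(x), x)

    def test_signal_within_gate_untouched(self, rng):
        x = np.sin(np.arange(100) / 10.0)
        assert np.array_equal(replace_outliers(x), x)

    def test_window_longer_than_signal_is_noop(self):
        x = np.arange(5.0)
        assert np.array_equal(replace_outliers(x, window=11), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            replace_outliers(np.arange(20.0), window=10)


class TestLowpass:
    def test_dc_unity_gain(self):
        x = np.full(200, 7.3)
        assert np.max(np.abs(lowpass(x, fs=60.0, cutoff=6.0) - 7.3)) < 1e-9

    def test_passband_tone_preserved(self):
        t = np.arange(1200) / 60.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass(x, fs=60.0, cutoff=6.0, order=4)
        amp = np.max(np.abs(y[300:-300]))
        assert 0.99 <= amp <= 1.01

    def test_stopband_tone_attenuated(self):
        t = np.arange(1200) / 60.0
        x = np.sin(2 * np.pi * 25.0 * t)
        y = lowpass(x, fs=60.0, cutoff=6.0, order=4)
        assert np.max(np.abs(y[300:-300])) < 0.01

    def test_refuses_missing_samples(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValueError, match="gap"):
            lowpass(x, fs=60.0)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(np.ones(100), fs=60.0, cutoff=31.0)

    @given(seed=st.integers(0, 2**16))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=64), r.normal(size=64)
        a, b = r.normal(), r.normal()
        lhs = lowpass(a * x + b * y, fs=60.0)
        rhs = a * lowpass(x, fs=60.0) + b * lowpass(y, fs=60.0)
        assert np.max(np.abs(lhs - rhs)) < 1e-9


class TestHeightScaling:
    @staticmethod
    def _standing_series(nose_y=900.0, heel_y=50.0):
        p = len(BODY25_NAMES)
        x = np.full((2, p), np.nan)
        y = np.full((2, p), np.nan)
        missing = np.ones((2, p), dtype=bool)
        for name, yy in (("Nose", nose_y), ("LHeel", heel_y), ("LHip", 475.0)):
            j = BODY25_NAMES.index(name)
            x[:, j], y[:, j], missing[:, j] = 100.0, yy, False
        return KeypointSeries(x=x, y=y, confidence=np.ones((2, p)),
                              missing=missing, fs=60.0)

    def test_ratio_arithmetic(self):
        series = self._standing_series()  # 850 px extent
        out = pixels_to_height_units(series, subject_height=1.70)
        assert out.scale == pytest.approx(0.002)
        # a 425 px segment becomes 0.85 m
        _, y, _ = out.point("Nose")
        _, y2, _ = out.point("LHip")
        assert (y[0] - y2[0]) == pytest.approx(0.002 * 425.0)

    def test_scaling_is_invertible(self):
        series = self._standing_series()
        out = pixels_to_height_units(series, subject_height=1.70)
        assert np.allclose(out.x / out.scale, series.x, equal_nan=True)

    def test_angles_are_scale_invariant(self, default_truth, default_skeleton):
        from gaitwarp import angle_series

        scaled = pixels_to_height_units(default_skeleton, subject_height=1.70)
        before = angle_series(default_skeleton, "knee", "left").values
        after = angle_series(scaled, "knee", "left").values
        assert np.nanmax(np.abs(before - after)) < 1e-9

    def test_no_calibration_frame_is_an_error(self):
        series = self._standing_series()
        series.missing[:, BODY25_NAMES.index("Nose")] = True
        with pytest.raises(ValueError, match="manual scale"):
            pixels_to_height_units(series, subject_height=1.70)


class TestGroundContact:
    def test_recovers_generator_heel_strikes(self):
        cfg = GaitConfig(cadence=1.0 / 1.1, n_cycles=5)  # strikes every 1.1 s
        truth = generate_waveforms(cfg)
        kp = project_skeleton(truth)
        _, y, _ = kp.point("LAnkle")
        events = detect_ground_contact(y, cfg.fs)
        assert len(events) == len(truth.events_s)
        err = np.abs(events - truth.events_s * cfg.fs)
        assert np.all(err <= 2.0)

    def test_constant_trajectory_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            detect_ground_contact(np.full(100, 3.0), fs=60.0)

    def test_single_dip_detected_at_vertex(self):
        t = np.linspace(-1, 1, 201)
        y = t**2  # vertex at index 100
        events = detect_ground_contact(y, fs=60.0, min_separation_s=0.1)
        assert events.tolist() == [100]

    def test_median_error_at_most_one_frame_across_seeds(self):
        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            cadence = float(r.uniform(0.8, 1.0))
            cfg = GaitConfig(cadence=cadence, n_cycles=4, seed=seed)
            truth = generate_waveforms(cfg)
            _, y, _ = project_skeleton(truth).point("LAnkle")
            events = detect_ground_contact(y, cfg.fs)
            truth_frames = truth.events_s * cfg.fs
            for e in events:
                errs.append(np.min(np.abs(truth_frames - e)))
        assert np.median(errs) <= 1.0


class TestSynchronize:
    def test_offset_is_difference_of_first_event_times(self):
        assert synchronize([60], 60.0, [75], 60.0) == pytest.approx(-0.25)

    def test_identical_event_lists_give_zero(self):
        assert synchronize([10, 20], 60.0, [10, 20], 60.0) == 0.0

    def test_equal_times_across_rates(self):
        assert synchronize([240], 240.0, [60], 60.0) == 0.0

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            synchronize([], 60.0, [1], 60.0)


class TestCleaningConfig:
    def test_gap_bound_matches_point_two_seconds_at_sixty_fps(self):
        cfg = CleaningConfig()
        assert cfg.max_gap_frames == round(cfg.max_gap_seconds * 60.0) == 12
        assert cfg.max_gap_for(60.0) == 12

    def test_gap_bound_scales_with_rate(self):
        assert CleaningConfig().max_gap_for(240.0) == 48
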