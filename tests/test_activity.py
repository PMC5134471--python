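import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uwbspeech import (
    amplitude_diff,
    apply_margins,
    build_clean_map,
    confirm_articulator_motion,
    detect_general_motion,
    estimate_background,
    motion_trace,
    motion_variance,
    reduce_clutter,
    rest_distance,
    simulate_session,
    smooth_variance,
)
from uwbspeech.activity import MotionTrace, SpeechSegment
from uwbspeech.clutter import ClutterReducedMatrix
from uwbspeech.scene import static_scene, word_scene


def reduced_from(values):
    return ClutterReducedMatrix(np.asarray(values, dtype=float),
                                scan_interval_s=0.01, bin_size_m=0.004)


def trace_from_smoothed(smoothed, dt=0.01):
    smoothed = np.asarray(smoothed, dtype=float)
    return MotionTrace(raw_variance=smoothed, smoothed_variance=smoothed,
                       alpha=0.1, n_bins=256, scan_interval_s=dt)


def square_trace(t_on, t_off, total=3.0, dt=0.01, level=5e-5):
    """Smoothed-variance trace at/above threshold on [t_on, t_off)."""
    times = (np.arange(int(total / dt) - 1) + 1) * dt
    values = np.where((times >= t_on) & (times < t_off), level, 1e-7)
    return trace_from_smoothed(values, dt)


class TestAmplitudeDiff:
    def test_two_bin_example(self):
        reduced = reduced_from([[0.0, 0.0], [1.0, 3.0]])
        assert np.allclose(amplitude_diff(reduced, 1), [0.25, 0.75])

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(3)
        reduced = reduced_from(rng.normal(size=(5, 64)))
        for m in range(1, 5):
            assert amplitude_diff(reduced, m).sum() == pytest.approx(1.0)

    def test_identical_rows_give_uniform_profile(self):
        reduced = reduced_from(np.ones((2, 8)))
        assert np.allclose(amplitude_diff(reduced, 1), 1.0 / 8)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_mean_of_profile_is_one_over_n(self, seed):
        """The forced-normalization identity: the profile's mean is exactly
        1/N for every frame pair."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 300))
        reduced = reduced_from(rng.normal(size=(2, n)))
        x = amplitude_diff(reduced, 1)
        assert x.mean() == pytest.approx(1.0 / n, rel=1e-12)


class TestMotionVariance:
    def test_uniform_profile_has_zero_variance(self):
        assert motion_variance(np.full(16, 1 / 16)) == 0.0

    def test_two_bin_arithmetic(self):
        assert motion_variance(np.array([0.25, 0.75])) == pytest.approx(0.0625)

    def test_point_mass_maximizes_variance(self):
        """Brute force over simplex corners: all mass in one bin maximizes
        the variance at (N-1)/N^2."""
        n = 8
        corner_vals = []
        for i in range(n):
            x = np.zeros(n)
            x[i] = 1.0
            corner_vals.append(motion_variance(x))
        assert np.allclose(corner_vals, (n - 1) / n**2)
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.dirichlet(np.ones(n))
            assert motion_variance(x) <= (n - 1) / n**2 + 1e-12


class TestSmoothVariance:
    def test_constant_input_is_fixed_point(self):
        out = smooth_variance(np.full(10, 3.3), alpha=0.1)
        assert np.allclose(out, 3.3)

    def test_single_step_update(self):
        out = smooth_variance(np.array([0.0, 1.0]), alpha=0.1)
        assert out[1] == pytest.approx(0.1)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 1.0))
    def test_output_bounded_by_input_range(self, seed, alpha):
        raw = np.random.default_rng(seed).uniform(0, 5, 50)
        out = smooth_variance(raw, alpha)
        assert np.all(out >= raw.min() - 1e-12)
        assert np.all(out <= raw.max() + 1e-12)

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
    def test_alpha_outside_interval_rejected(self, alpha):
        with pytest.raises(ValueError):
            smooth_variance(np.ones(3), alpha)


class TestDetectGeneralMotion:
    def test_margin_rule_first_worked_example(self):
        """Crossings at 0.47 s and 1.28 s store the 0.27-1.38 s window."""
        segs = detect_general_motion(square_trace(0.47, 1.28))
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.raw_start_s, seg.raw_end_s) == pytest.approx((0.47, 1.28))
        assert (seg.start_s, seg.end_s) == pytest.approx((0.27, 1.38))

    def test_margin_rule_second_worked_example(self):
        """Crossings at 0.42 s and 1.02 s store the 0.22-1.12 s window."""
        seg = detect_general_motion(square_trace(0.42, 1.02))[0]
        assert (seg.start_s, seg.end_s) == pytest.approx((0.22, 1.12))

    def test_trace_below_threshold_yields_no_segments(self):
        assert detect_general_motion(trace_from_smoothed(np.full(200, 1e-7))) == []

    def test_brief_dip_does_not_split_segment(self):
        times = (np.arange(299) + 1) * 0.01
        values = np.where((times >= 0.5) & (times < 1.5), 5e-5, 1e-7)
        values[(times >= 0.9) & (times < 1.1)] = 1e-7  # 0.2 s dip < 0.4 s gap
        segs = detect_general_motion(trace_from_smoothed(values))
        assert len(segs) == 1
        assert segs[0].raw_end_s == pytest.approx(1.5)

    def test_start_margin_clipped_at_zero(self):
        seg = detect_general_motion(square_trace(0.1, 0.8))[0]
        assert seg.start_s == 0.0

    def test_raising_threshold_never_lengthens_segments(self):
        rng = np.random.default_rng(8)
        values = np.abs(rng.normal(2e-5, 2e-5, 400))
        trace = trace_from_smoothed(values)
        spans_low = [(s.raw_start_s, s.raw_end_s)
                     for s in detect_general_motion(trace, threshold=1e-5)]
        for factor in (2, 5, 10):
            spans_high = detect_general_motion(trace, threshold=factor * 1e-5)
            total_low = sum(b - a for a, b in spans_low)
            total_high = sum(s.raw_end_s - s.raw_start_s for s in spans_high)
            assert total_high <= total_low + 1e-9

    def test_apply_margins_matches_detector(self):
        assert apply_margins(0.47, 1.28) == pytest.approx((0.27, 1.38))
        assert apply_margins(0.42, 1.02) == pytest.approx((0.22, 1.12))


class TestNoMotionSpecificity:
    def test_noiseless_static_scene_yields_zero_segments(self, template):
        scene = dataclasses.replace(static_scene(seed=0), noise_sd=0.0,
                                    wander_amplitude=0.0)
        session, _ = simulate_session(scene, template)
        bg, _ = simulate_session(scene.background(), template)
        reduced = reduce_clutter(session, estimate_background(bg))
        assert detect_general_motion(motion_trace(reduced)) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_noisy_static_scene_stays_below_threshold(self, template, seed):
        scene = static_scene(seed=seed, duration_s=3.0)
        session, _ = simulate_session(scene, template)
        bg, _ = simulate_session(scene.background(), template)
        reduced = reduce_clutter(session, estimate_background(bg))
        assert detect_general_motion(motion_trace(reduced)) == []


class TestSegmentationRecovery:
    @pytest.mark.parametrize("profile", ["two_like", "five_like"])
    def test_stored_window_covers_speech_interval_with_margins(
        self, template, profile, short_template
    ):
        scene = word_scene(profile, seed=13, speech_interval_s=(0.5, 1.2))
        session, _ = simulate_session(scene, template)
        bg, _ = simulate_session(scene.background(), template)
        reduced = reduce_clutter(session, estimate_background(bg))
        segs = detect_general_motion(motion_trace(reduced))
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start_s == pytest.approx(seg.raw_start_s - 0.2, abs=1e-9)
        assert seg.end_s == pytest.approx(seg.raw_end_s + 0.1, abs=1e-9)
        assert seg.start_s <= 0.5 and seg.end_s >= 1.2


class TestRestDistanceAndGate:
    def make_map(self, bins, dt=0.01):
        from uwbspeech.clean import CleanDetection, CleanMap

        return CleanMap(
            detections=tuple((CleanDetection(bin=int(b), amplitude=1.0),) for b in bins),
            detector_tag="short_template",
            scan_interval_s=dt,
            bin_size_m=0.004,
        )

    def segment(self, raw_start, raw_end):
        start, end = apply_margins(raw_start, raw_end)
        return SpeechSegment(raw_start_s=raw_start, raw_end_s=raw_end,
                             start_s=start, end_s=end)

    def test_constant_rest_bin_is_returned(self):
        cmap = self.make_map([33] * 100)
        assert rest_distance(cmap, self.segment(0.5, 0.9)) == 33

    def test_median_of_pre_window(self):
        cmap = self.make_map([32] + [33] * 99)
        assert rest_distance(cmap, self.segment(0.5, 0.9)) == 33

    def test_empty_pre_window_instructs_longer_capture(self):
        cmap = self.make_map([33] * 100)
        with pytest.raises(ValueError, match="pre-speech"):
            rest_distance(cmap, self.segment(0.0, 0.5))

    def test_rest_bin_matches_configured_range(self, template, short_template):
        scene = word_scene("two_like", seed=4, rest_range_m=0.132)
        session, _ = simulate_session(scene, template)
        bg, _ = simulate_session(scene.background(), template)
        reduced = reduce_clutter(session, estimate_background(bg))
        cmap = build_clean_map(reduced, short_template, "short_template")
        segs = detect_general_motion(motion_trace(reduced))
        rest = rest_distance(cmap, segs[0])
        assert abs(rest - round(0.132 / 0.004)) <= 1

    def test_zero_excursion_confirmed(self):
        cmap = self.make_map([33] * 100)
        assert confirm_articulator_motion(cmap, self.segment(0.3, 0.8), 33)

    def test_excursion_beyond_forward_gate_rejected(self):
        bins = [33] * 100
        bins[50] = 33 - 12  # -4.8 cm, beyond the -4 cm gate
        cmap = self.make_map(bins)
        assert not confirm_articulator_motion(cmap, self.segment(0.3, 0.8), 33)

    def test_simulated_scenes_on_both_sides_of_gate(self, template, short_template):
        """2 cm articulation passes the gate; a 6 cm head-drift-like
        excursion is discarded."""
        for excursion, expected in ((0.02, True), (0.06, False)):
            scene = word_scene("two_like", seed=6, excursion_m=excursion,
                               rest_range_m=0.132)
            session, _ = simulate_session(scene, template)
            bg, _ = simulate_session(scene.background(), template)
            reduced = reduce_clutter(session, estimate_background(bg))
            cmap = build_clean_map(reduced, short_template, "short_template")
            segs = detect_general_motion(motion_trace(reduced))
            assert len(segs) == 1
            rest = rest_distance(cmap, segs[0])
            assert confirm_articulator_motion(cmap, segs[0], rest) is expected
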