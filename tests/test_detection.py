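import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coddetect import (
    COIEvent,
    DetectionConfig,
    SensorRecording,
    detect_cods,
    detect_cois,
    horizontal_modulus,
    reproject,
    smooth_heading,
    smooth_linear,
    unify_cods,
)

finite_arrays = st.lists(
    st.floats(-10, 10, allow_nan=False), min_size=1, max_size=200
).map(np.asarray)


class TestSmoothing:
    def test_constant_sequence_unchanged(self):
        out = smooth_linear(np.full(50, 1.7), 40, 100)
        np.testing.assert_allclose(out, 1.7)

    def test_window_of_one_is_identity(self):
        x = np.array([0.1, 0.9, -0.4, 2.0])
        np.testing.assert_array_equal(smooth_linear(x, 1, 100), x)  # w = 1

    def test_three_sample_window_mean(self):
        # direct windowed-mean oracle: peak sample becomes mean([0,3,0]) = 1
        out = smooth_linear(np.array([0.0, 0.0, 3.0, 0.0, 0.0]), 3, 100)
        assert out[2] == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smooth_linear(np.array([]), 30, 100)

    @settings(deadline=None, derandomize=True)
    @given(values=finite_arrays, pct=st.sampled_from([20.0, 30.0, 40.0, 100.0]))
    def test_max_attenuation(self, values, pct):
        out = smooth_linear(values, pct, 100)
        assert len(out) == len(values)
        assert np.max(np.abs(out)) <= np.max(np.abs(values)) + 1e-12

    def test_constant_heading_unchanged(self):
        out = smooth_heading(np.full(40, 350.0), 30, 100)
        np.testing.assert_allclose(out, 350.0)

    def test_circular_mean_across_north_seam(self):
        # windows straddling north must average near 0, never near 180
        out = smooth_heading(np.array([359.0, 0.0, 1.0]), 3, 100)
        assert min(out[1], 360 - out[1]) == pytest.approx(0.0, abs=1e-9)
        assert np.max(np.minimum(out, 360 - out)) < 1.5

    def test_heading_window_of_one_is_identity(self, rng):
        h = rng.uniform(0, 360, 30)
        np.testing.assert_allclose(smooth_heading(h, 1, 100), h, atol=1e-9)


class TestReprojection:
    def test_zero_heading_is_identity(self, rng):
        ex, ey = rng.normal(size=(2, 20))
        a_ml, a_ap = reproject(ex, ey, np.zeros(20))
        np.testing.assert_allclose(a_ap, ey, atol=1e-12)
        np.testing.assert_allclose(a_ml, ex, atol=1e-12)

    def test_east_facing_runner(self):
        # heading 90 deg, eastward acceleration (1, 0) is purely forward
        a_ml, a_ap = reproject([1.0], [0.0], [90.0])
        assert a_ap[0] == pytest.approx(1.0)
        assert a_ml[0] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        ex=st.floats(-5, 5, allow_nan=False),
        ey=st.floats(-5, 5, allow_nan=False),
        h=st.floats(0, 360, exclude_max=True),
    )
    def test_rotation_preserves_norm(self, ex, ey, h):
        a_ml, a_ap = reproject([ex], [ey], [h])
        assert np.hypot(a_ml, a_ap)[0] == pytest.approx(np.hypot(ex, ey), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reproject([1.0, 2.0], [1.0], [0.0, 0.0])


class TestModulus:
    def test_pythagorean_triple(self):
        assert horizontal_modulus([3.0], [4.0])[0] == pytest.approx(5.0)

    def test_zero_inputs(self):
        np.testing.assert_array_equal(horizontal_modulus(np.zeros(5), np.zeros(5)), 0.0)

    def test_sign_invariance(self, rng):
        a, b = rng.normal(size=(2, 30))
        np.testing.assert_allclose(
            horizontal_modulus(a, b), horizontal_modulus(-a, b)
        )
        np.testing.assert_allclose(
            horizontal_modulus(a, b), horizontal_modulus(a, -b)
        )


class TestCoiDetection:
    def test_subthreshold_signal_yields_nothing(self):
        x = 0.5 + 0.3 * np.sin(np.linspace(0, 20, 200))
        assert detect_cois(x, pmi_g=1.0, fs_hz=100) == []

    def test_triangular_pulse_single_event_at_apex(self):
        x = np.concatenate([np.linspace(0, 1.2, 50), np.linspace(1.2, 0, 50)[1:]])
        events = detect_cois(x, pmi_g=1.0, fs_hz=100)
        assert len(events) == 1
        assert events[0].time_s == pytest.approx(49 / 100)
        assert events[0].peak_g == pytest.approx(1.2)

    def test_plateau_peak_reported_at_center(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        events = detect_cois(x, pmi_g=0.5, fs_hz=10)
        assert len(events) == 1
        assert events[0].time_s == pytest.approx(2 / 10)

    def test_close_peaks_keep_larger(self):
        x = np.zeros(100)
        x[40], x[45] = 1.0, 1.4  # 0.05 s apart at 100 Hz
        events = detect_cois(x, pmi_g=0.8, fs_hz=100, min_peak_separation_s=0.1)
        assert [e.peak_g for e in events] == [1.4]

    def test_equal_close_peaks_keep_earlier(self):
        x = np.zeros(100)
        x[40], x[45] = 1.2, 1.2
        events = detect_cois(x, pmi_g=0.8, fs_hz=100, min_peak_separation_s=0.1)
        assert len(events) == 1
        assert events[0].time_s == pytest.approx(0.40)

    def test_threshold_superset_property(self, rng):
        # lowering the threshold can only add events (checked on 30 random signals)
        for _ in range(30):
            x = np.abs(rng.normal(0, 0.6, 300))
            counts = [
                len(detect_cois(x, pmi_g=g, fs_hz=100)) for g in (1.0, 0.9, 0.8)
            ]
            assert counts[0] <= counts[1] <= counts[2]


class TestUnification:
    def test_empty_input(self):
        assert unify_cods([]) == []

    def test_close_cois_merge(self):
        cois = [COIEvent(1.0, 1.1), COIEvent(1.2, 1.5)]
        cods = unify_cods(cois, merge_gap_s=0.5)
        assert len(cods) == 1
        assert cods[0].n_cois == 2
        assert cods[0].peak_g == pytest.approx(1.5)
        assert (cods[0].start_s, cods[0].end_s) == (1.0, 1.2)

    def test_distant_cois_stay_separate(self):
        cois = [COIEvent(t, 1.0) for t in (1.0, 2.0, 3.0)]
        assert len(unify_cods(cois, merge_gap_s=0.5)) == 3

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            unify_cods([COIEvent(2.0, 1.0), COIEvent(1.0, 1.0)])

    def test_idempotent_on_cod_midpoints(self, rng):
        times = np.sort(rng.uniform(0, 30, 25))
        cois = [COIEvent(float(t), 1.0) for t in times]
        cods = unify_cods(cois, merge_gap_s=0.5)
        again = unify_cods([COIEvent(c.mid_s, c.peak_g) for c in cods], merge_gap_s=0.5)
        assert len(again) == len(cods)


class TestEndToEnd:
    def test_zero_acceleration_recording(self):
        rec = SensorRecording(
            fs_hz=100, earth_x=np.zeros(500), earth_y=np.zeros(500),
            euler_x=np.zeros(500),
        )
        assert detect_cods(rec, DetectionConfig(30, 0.9)) == []

    def test_rotation_invariance(self, sample_trial):
        """Rotating the whole scene (heading offset + matching Earth-vector
        rotation) must not change the detected events."""
        rec, _ = sample_trial
        config = DetectionConfig(30, 0.9)
        baseline = detect_cods(rec, config)
        for offset_deg in (37.0, 120.0, 305.0):
            phi = np.radians(offset_deg)
            # heading is clockwise from north: rotate Earth vectors clockwise too
            ex = rec.earth_x * np.cos(phi) - rec.earth_y * np.sin(phi)
            ey = rec.earth_x * np.sin(phi) + rec.earth_y * np.cos(phi)
            rotated = SensorRecording(
                fs_hz=rec.fs_hz, earth_x=ex, earth_y=ey,
                euler_x=rec.euler_x + offset_deg,
            )
            events = detect_cods(rotated, config)
            assert len(events) == len(baseline)
            for a, b in zip(events, baseline):
                assert a.start_s == pytest.approx(b.start_s, abs=1e-6)
                assert a.peak_g == pytest.approx(b.peak_g, rel=1e-9)

    def test_cod_count_bounded_by_coi_count(self, sample_trial):
        rec, _ = sample_trial
        from coddetect.detection import smooth_heading, smooth_linear

        config = DetectionConfig(20, 0.8)
        ex = smooth_linear(rec.earth_x, config.smoothing_pct, rec.fs_hz)
        ey = smooth_linear(rec.earth_y, config.smoothing_pct, rec.fs_hz)
        h = smooth_heading(rec.euler_x, config.smoothing_pct, rec.fs_hz)
        mod = horizontal_modulus(*reproject(ex, ey, h))
        cois = detect_cois(mod, config.pmi_g, rec.fs_hz, config.min_peak_separation_s)
        cods = detect_cods(rec, config)
        assert len(cods) <= len(cois)
        assert sum(c.n_cois for c in cods) == len(cois)
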