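"""Loop geometry and spatial-angle computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrstangle.core_geometry import (
    DegenerateVectorError,
    Fiducials,
    Loop,
    VcgBeat,
    dominant_vector_max,
    dominant_vector_mean,
    extract_loop,
    loop_origin,
    qrst_angle_conventional,
    spatial_angle,
    unit,
)

finite_coord = st.floats(-10, 10, allow_nan=False)
nonzero_vector = st.tuples(finite_coord, finite_coord, finite_coord).filter(
    lambda v: np.linalg.norm(v) > 1e-3
)


class TestUnit:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ((3, 0, 0), (1, 0, 0)),
            ((1, 1, 1), (0.5774, 0.5774, 0.5774)),
            ((0, -2, 0), (0, -1, 0)),
        ],
    )
    def test_examples(self, v, expected):
        np.testing.assert_allclose(unit(np.array(v)), expected, atol=1e-4)

    def test_zero_vector_is_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            unit(np.zeros(3))

    @given(nonzero_vector)
    @settings(max_examples=50, deadline=None)
    def test_unit_magnitude_and_direction(self, v):
        u = unit(np.array(v))
        assert abs(np.linalg.norm(u) - 1.0) < 1e-9
        assert np.dot(u, v) > 0


class TestSpatialAngle:
    @pytest.mark.parametrize(
        "u1, u2, expected",
        [
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 0, 0), (-2, 0, 0), 180.0),
            ((1, 1, 0), (1, 0, 0), 45.0),
            ((1, 0, 0), (3, 0, 0), 0.0),
        ],
    )
    def test_canonical_pairs(self, u1, u2, expected):
        assert spatial_angle(np.array(u1), np.array(u2)) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(DegenerateVectorError):
            spatial_angle(np.zeros(3), np.ones(3))

    @given(nonzero_vector, nonzero_vector, st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_scale_invariance(self, u, v, c):
        u, v = np.array(u), np.array(v)
        a = spatial_angle(u, v)
        assert 0.0 <= a <= 180.0
        assert spatial_angle(v, u) == pytest.approx(a, abs=1e-9)
        assert spatial_angle(c * u, v) == pytest.approx(a, abs=1e-7)

    @given(nonzero_vector, st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_parallel_and_antiparallel(self, u, c):
        u = np.array(u)
        assert spatial_angle(u, c * u) == pytest.approx(0.0, abs=1e-5)
        assert spatial_angle(u, -c * u) == pytest.approx(180.0, abs=1e-5)


class TestLoopOrigin:
    def test_constant_beat(self):
        beat = VcgBeat(np.tile([0.1, -0.2, 0.3], (100, 1)), 500.0)
        np.testing.assert_allclose(loop_origin(beat, 50), [0.1, -0.2, 0.3])

    def test_median_robust_to_outlier(self):
        # median of {1, 2, 100} is 2, unlike the mean
        samples = np.zeros((40, 3))
        fs = 100.0  # window [18, 20]: 3 samples
        samples[17:21, 0] = [1.0, 2.0, 100.0, 2.0]
        beat = VcgBeat(samples, fs)
        origin = loop_origin(beat, 20)
        assert origin[0] == pytest.approx(2.0)

    def test_window_span_at_500hz(self):
        # window must cover round(0.025 * 500) + 1 = 13 samples inclusive
        samples = np.zeros((100, 3))
        samples[37:50, 1] = 1.0  # exactly the 13 samples [37, 49]
        beat = VcgBeat(samples, 500.0)
        assert loop_origin(beat, 49)[1] == pytest.approx(1.0)
        samples2 = np.zeros((100, 3))
        samples2[36, 1] = 100.0  # one sample before the window: no effect
        samples2[37:50, 1] = 1.0
        assert loop_origin(VcgBeat(samples2, 500.0), 49)[1] == pytest.approx(1.0)

    def test_clipping_warns(self):
        beat = VcgBeat(np.zeros((50, 3)), 500.0)
        with pytest.warns(UserWarning, match="clipping"):
            loop_origin(beat, 5)


class TestExtractLoop:
    def test_zero_origin_identity(self):
        samples = np.arange(30.0).reshape(10, 3)
        beat = VcgBeat(samples, 500.0)
        loop = extract_loop(beat, 2, 5, np.zeros(3))
        np.testing.assert_array_equal(loop.samples, samples[2:6])

    def test_single_sample_and_full_cancellation(self):
        beat = VcgBeat(np.ones((10, 3)), 500.0)
        loop = extract_loop(beat, 4, 4, np.ones(3))
        assert len(loop) == 1
        np.testing.assert_array_equal(loop.samples, np.zeros((1, 3)))

    def test_inverted_bounds_raise(self):
        beat = VcgBeat(np.ones((10, 3)), 500.0)
        with pytest.raises(ValueError):
            extract_loop(beat, 5, 4, np.zeros(3))


class TestDominantVectors:
    def test_mean_threshold_excludes_small_samples(self):
        loop = Loop(np.array([[1, 0, 0], [0.8, 0, 0], [0.6, 0, 0]], dtype=float), "QRS")
        np.testing.assert_allclose(dominant_vector_mean(loop), [0.9, 0, 0])

    def test_mean_threshold_is_inclusive(self):
        loop = Loop(np.array([[1.0, 0, 0], [0.7, 0, 0]]), "QRS")
        np.testing.assert_allclose(dominant_vector_mean(loop), [0.85, 0, 0])

    def test_single_and_identical_samples(self):
        assert dominant_vector_mean(Loop(np.array([[0, 2.0, 0]]), "T"))[1] == 2.0
        loop = Loop(np.tile([0.3, -0.1, 0.2], (5, 1)), "T")
        np.testing.assert_allclose(dominant_vector_mean(loop), [0.3, -0.1, 0.2])

    def test_all_zero_loop_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            dominant_vector_mean(Loop(np.zeros((4, 3)), "T"))

    def test_max_argmax_and_tie_break(self):
        loop = Loop(np.array([[1, 0, 0], [0, 3, 0], [2, 0, 0]], dtype=float), "QRS")
        np.testing.assert_array_equal(dominant_vector_max(loop), [0, 3, 0])
        tie = Loop(np.array([[0, 2, 0], [2, 0, 0]], dtype=float), "QRS")
        np.testing.assert_array_equal(dominant_vector_max(tie), [0, 2, 0])

    def test_mean_matches_brute_force_on_random_loops(self, rng):
        """Filter-then-mean must agree exactly with a brute-force loop."""
        for _ in range(1000):
            n = rng.integers(1, 30)
            samples = rng.normal(size=(n, 3))
            loop = Loop(samples, "QRS")
            mags = [float(np.linalg.norm(s)) for s in samples]
            mmax = max(mags)
            selected = [s for s, m in zip(samples, mags) if m >= 0.7 * mmax]
            expected = np.mean(selected, axis=0)
            np.testing.assert_array_equal(dominant_vector_mean(loop), expected)


def _two_phase_beat(u_qrs, u_t, fs=500.0):
    """Beat with QRS samples along u_qrs and T samples along u_t."""
    n = 400
    samples = np.zeros((n, 3))
    for i, a in enumerate(np.linspace(0.5, 1.0, 20)):
        samples[150 + i] = a * np.asarray(u_qrs)
    for i, a in enumerate(np.linspace(0.3, 0.6, 40)):
        samples[250 + i] = a * np.asarray(u_t)
    fid = Fiducials(qrs_onset=148, qrs_offset=172, t_onset=248, t_offset=292, r_peak=169)
    return VcgBeat(samples, fs), fid


class TestConventionalAngle:
    def test_orthogonal_construction(self):
        beat, fid = _two_phase_beat([1, 0, 0], [0, 1, 0])
        _, _, alpha = qrst_angle_conventional(beat, fid)
        assert alpha == pytest.approx(90.0, abs=1e-9)

    def test_scale_invariance_of_t_loop(self):
        beat, fid = _two_phase_beat([1, 0, 0], [0.2, 0.9, 0.1])
        _, _, a1 = qrst_angle_conventional(beat, fid)
        half, _ = _two_phase_beat([1, 0, 0], np.array([0.2, 0.9, 0.1]) * 0.5)
        _, _, a2 = qrst_angle_conventional(half, fid)
        assert a2 == pytest.approx(a1, abs=1e-9)

    def test_matches_brute_force_recomputation(self, rng):
        """Independent recomputation: origin median, 70 % filter, mean, angle."""
        for _ in range(20):
            samples = rng.normal(scale=0.05, size=(400, 3))
            samples += _two_phase_beat(rng.normal(size=3), rng.normal(size=3))[0].samples
            beat = VcgBeat(samples, 500.0)
            fid = Fiducials(qrs_onset=148, qrs_offset=172, t_onset=248, t_offset=292, r_peak=169)
            u_qrs, u_t, alpha = qrst_angle_conventional(beat, fid)

            window = samples[148 - 13 + 1 : 149]  # 13 samples inclusive at 500 Hz
            origin = np.median(window, axis=0)

            def dominant(seg):
                mags = np.linalg.norm(seg, axis=1)
                return seg[mags >= 0.7 * mags.max()].mean(axis=0)

            exp_q = dominant(samples[148:173] - origin)
            exp_t = dominant(samples[248:293] - origin)
            np.testing.assert_allclose(u_qrs, exp_q, atol=1e-12)
            np.testing.assert_allclose(u_t, exp_t, atol=1e-12)
            cross = np.linalg.norm(np.cross(exp_q, exp_t))
            expected_alpha = np.degrees(np.arctan2(cross, np.dot(exp_q, exp_t)))
            assert alpha == pytest.approx(expected_alpha, abs=1e-9)

    def test_baseline_shift_conserves_angle(self):
        beat, fid = _two_phase_beat([1, 0.2, 0], [0, 1, 0.3])
        _, _, a1 = qrst_angle_conventional(beat, fid)
        shifted = VcgBeat(beat.samples + np.array([0.5, -0.3, 0.2]), 500.0)
        _, _, a2 = qrst_angle_conventional(shifted, fid)
        assert a2 == pytest.approx(a1, abs=1e-9)

    def test_flat_t_wave_flagged(self):
        samples = np.zeros((400, 3))
        samples[150:170, 0] = 1.0
        beat = VcgBeat(samples, 500.0)
        fid = Fiducials(qrs_onset=148, qrs_offset=172, t_onset=248, t_offset=292, r_peak=160)
        with pytest.raises(DegenerateVectorError):
            qrst_angle_conventional(beat, fid)

    def test_max_method(self):
        beat, fid = _two_phase_beat([1, 0, 0], [0, 1, 0])
        u_qrs, u_t, alpha = qrst_angle_conventional(beat, fid, method="max")
        np.testing.assert_allclose(u_qrs, [1.0, 0, 0], atol=1e-12)
        assert alpha == pytest.approx(90.0)


class TestFiducials:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            Fiducials(qrs_onset=10, qrs_offset=5, t_onset=20, t_offset=30, r_peak=7)

    def test_bounds_check(self):
        fid = Fiducials(qrs_onset=0, qrs_offset=5, t_onset=10, t_offset=500, r_peak=3)
        with pytest.raises(ValueError):
            fid.validate_against(400)
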