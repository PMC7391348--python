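import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from yawkit import (
    circular_mean,
    circular_smooth,
    derive_orientation,
    heading,
    pitch_roll,
    smooth,
    tilt_correct,
)
from yawkit.simulator import _body_frame_vectors


def brute_force_smooth(x, half):
    """Independent direct-summation oracle with symmetric edge truncation."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = sum(x[i - h : i + h + 1]) / (2 * h + 1)
    return out


def brute_force_circular_smooth(h_deg, half):
    n = len(h_deg)
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        win = np.radians(h_deg[i - k : i + k + 1])
        out[i] = math.degrees(math.atan2(np.sin(win).mean(), np.cos(win).mean())) % 360.0
    return out


class TestSmooth:
    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth(np.full(100, 3.7), 2.0, 40.0), 3.7)

    def test_alternating_cancels_in_interior(self):
        x = np.tile([1.0, -1.0], 200)
        out = smooth(x, 2.0, 40.0)
        assert np.abs(out[100:-100]).max() < 0.02

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=300)
        out = smooth(x, 2.0, 40.0)  # half-width 40
        expected = brute_force_smooth(x, 40)
        idx = rng.integers(41, 259, size=20)
        np.testing.assert_allclose(out[idx], expected[idx], atol=1e-12)
        np.testing.assert_allclose(out, expected, atol=1e-12)  # incl. edges

    def test_nan_samples_excluded_not_poisoning(self):
        x = np.ones(50)
        x[10] = np.nan
        out = smooth(x, 2.0, 5.0)
        np.testing.assert_allclose(out, 1.0)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            smooth(np.array([]), 2.0, 40.0)


class TestPitchRoll:
    def test_level_posture(self):
        p, r, v = pitch_roll(np.array([[0.0, 0.0, 1.0]]))
        assert p[0] == pytest.approx(0.0) and r[0] == pytest.approx(0.0) and v[0]

    def test_nose_up(self):
        p, _, _ = pitch_roll(np.array([[1.0, 0.0, 0.0]]))
        assert p[0] == pytest.approx(90.0)

    def test_against_trigonometric_oracle(self, rng):
        v = rng.normal(size=(1000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        p, r, valid = pitch_roll(v)
        for i in range(1000):
            sx, sy, sz = v[i]
            assert p[i] == pytest.approx(
                math.degrees(math.atan2(sx, math.sqrt(sy**2 + sz**2))), abs=1e-9
            )
            assert r[i] == pytest.approx(
                math.degrees(math.atan2(sy, math.sqrt(sx**2 + sz**2))), abs=1e-9
            )
        assert valid.all()
        assert np.abs(p).max() <= 90.0 and np.abs(r).max() <= 90.0

    def test_zero_vector_marked_invalid(self):
        p, r, v = pitch_roll(np.array([[0.0, 0.0, 0.0], [0, 0, 1]]))
        assert not v[0] and np.isnan(p[0]) and np.isnan(r[0])
        assert v[1]


class TestTiltCorrectAndHeading:
    def test_zero_tilt_is_identity(self, rng):
        m = rng.normal(size=(20, 3))
        hx, hy, _ = tilt_correct(m, np.zeros(20), np.zeros(20))
        np.testing.assert_allclose(hx, m[:, 0], atol=1e-12)
        np.testing.assert_allclose(hy, m[:, 1], atol=1e-12)

    @pytest.mark.parametrize("truth_heading", [0.0, 37.5, 123.0, 269.9])
    def test_pitched_sample_recovers_truth_heading(self, truth_heading):
        field = 0.35 * np.array([math.cos(math.radians(40)), 0, -math.sin(math.radians(40))])
        m = _body_frame_vectors([truth_heading], [30.0], [0.0], field)
        hx, hy, valid = tilt_correct(m, np.array([30.0]), np.array([0.0]))
        assert valid[0]
        assert heading(hx, hy)[0] == pytest.approx(truth_heading, abs=1e-6)

    def test_vertical_field_flagged_invalid(self):
        m = np.array([[0.0, 0.0, -0.4]])
        _, _, valid = tilt_correct(m, np.array([0.0]), np.array([0.0]))
        assert not valid[0]

    @pytest.mark.parametrize(
        "mx,my,expected",
        [(1.0, 0.0, 0.0), (0.0, -1.0, 90.0), (-1.0, 0.0, 180.0), (0.0, 1.0, 270.0)],
    )
    def test_compass_convention(self, mx, my, expected):
        assert heading(mx, my) == pytest.approx(expected)

    def test_zero_horizontal_component_is_nan(self):
        assert math.isnan(heading(0.0, 0.0))

    @given(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3))
    @settings(deadline=None, max_examples=200)
    def test_heading_always_in_range(self, mx, my):
        h = heading(mx, my)
        if not math.isnan(h):
            assert 0.0 <= h < 360.0


class TestCircularMean:
    def test_symmetric_about_north(self):
        assert circular_mean([350.0, 10.0]) == pytest.approx(0.0, abs=1e-9)

    def test_single_angle_identity(self):
        assert circular_mean([90.0]) == pytest.approx(90.0)

    def test_antipodal_cancellation_undefined(self):
        assert math.isnan(circular_mean([0.0, 180.0]))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            circular_mean([])

    @given(
        st.lists(st.floats(0, 360, exclude_max=True), min_size=1, max_size=20),
        st.integers(-3, 3),
    )
    @settings(deadline=None, max_examples=200)
    def test_invariant_to_full_turn_offsets(self, angles, k):
        base = circular_mean(angles)
        shifted = circular_mean([a + 360.0 * k for a in angles])
        if not math.isnan(base):
            d = (shifted - base + 180.0) % 360.0 - 180.0
            assert abs(d) < 1e-6


class TestCircularSmooth:
    def test_constant_heading(self):
        out = circular_smooth(np.full(50, 123.0), 2.0, 5.0)
        np.testing.assert_allclose(out, 123.0, atol=1e-9)

    def test_wrap_safe_near_north(self):
        h = np.tile([359.0, 1.0], 50)
        out = circular_smooth(h, 2.0, 10.0)
        interior = out[20:-20]
        d = (interior + 180.0) % 360.0 - 180.0
        assert np.abs(d).max() < 1.01  # near 0, never near 180

    def test_matches_trigonometric_moment_oracle(self, rng):
        h = np.cumsum(rng.normal(0, 20, 200)) % 360.0
        out = circular_smooth(h, 2.0, 5.0)  # half-width 5
        expected = brute_force_circular_smooth(h, 5)
        d = (out - expected + 180.0) % 360.0 - 180.0
        np.testing.assert_allclose(d, 0.0, atol=1e-9)


class TestDeriveOrientation:
    def test_noiseless_level_chain_recovers_truth(self, noiseless_deployment):
        truth, raw, fit = noiseless_deployment
        ori = derive_orientation(raw, fit=fit)
        assert ori.valid.all()
        err = (ori.heading - truth.heading + 180.0) % 360.0 - 180.0
        assert np.sqrt(np.mean(err**2)) < 1e-3
        np.testing.assert_allclose(ori.pitch, truth.pitch, atol=1e-6)

    def test_heading_range_and_validity_contract(self, noiseless_deployment):
        _, raw, fit = noiseless_deployment
        ori = derive_orientation(raw, fit=fit)
        h = ori.heading[ori.valid]
        assert ((h >= 0) & (h < 360)).all()
        assert np.isnan(ori.heading[~ori.valid]).all()
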