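"""Motion patterns: kinematics, periodicity, and the dwell (arcsine) density."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cbctmotion import MotionPattern, constant_speed, sinusoidal, static

amplitudes = st.floats(0.5, 40.0)
frequencies = st.floats(0.05, 2.0)
phases = st.floats(0.0, 2.0 * math.pi)
times = st.floats(0.0, 120.0)


class TestDisplacement:
    @pytest.mark.parametrize(
        "pattern, t, expected",
        [
            (sinusoidal(20, 0.25, 0.0), 0.0, 0.0),          # sin(0) = 0
            (sinusoidal(20, 0.25, 0.0), 1.0, 20.0),         # quarter period -> peak
            (constant_speed(2.0), 3.0, 6.0),
            (static(Zo=5.0), 17.0, 5.0),
        ],
    )
    def test_known_values(self, pattern, t, expected):
        assert pattern.displacement(t) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_formula(self):
        # independent evaluation of Zo + A sin(2 pi f t + phi)
        p = sinusoidal(20, 0.25, math.pi / 3, Zo=5.0)
        expected = 5.0 + 20.0 * math.sin(2 * math.pi * 0.25 * 1.7 + math.pi / 3)
        assert p.displacement(1.7) == pytest.approx(expected, rel=1e-15)

    @given(A=amplitudes, f=frequencies, phi=phases, t=times)
    def test_periodicity(self, A, f, phi, t):
        p = sinusoidal(A, f, phi)
        assert p.displacement(t) == pytest.approx(
            p.displacement(t + 1.0 / f), abs=1e-9 * max(1.0, A)
        )


class TestVelocity:
    @pytest.mark.parametrize(
        "pattern, t, expected",
        [
            (sinusoidal(20, 0.25, 0.0), 1.0, 0.0),          # cos(pi/2) = 0
            (sinusoidal(20, 0.25, 0.0), 0.0, 2 * math.pi * 0.25 * 20),  # peak wA
            (static(), 9.0, 0.0),
            (constant_speed(1.5), 0.0, 1.5),
        ],
    )
    def test_known_values(self, pattern, t, expected):
        assert pattern.velocity(t) == pytest.approx(expected, abs=1e-9)

    @given(A=amplitudes, f=st.floats(0.05, 1.0), phi=phases, t=st.floats(0.01, 60.0))
    def test_is_derivative_of_displacement(self, A, f, phi, t):
        p = sinusoidal(A, f, phi)
        h = 1e-4
        fd = (p.displacement(t + h) - p.displacement(t - h)) / (2 * h)
        assert p.velocity(t) == pytest.approx(fd, abs=1e-2 * max(1.0, A * f))

    def test_central_difference_at_fixed_points(self):
        p = sinusoidal(20, 0.25, 0.9)
        h = 1e-4
        for t in (0.5, 1.0, 2.7, 10.0):
            fd = (p.displacement(t + h) - p.displacement(t - h)) / (2 * h)
            assert p.velocity(t) == pytest.approx(fd, abs=1e-3)


class TestDwellDensity:
    def test_zero_amplitude_is_delta(self):
        offsets, weights = static().dwell_density(2.0)
        assert offsets.tolist() == [0.0]
        assert weights.tolist() == [1.0]

    def test_normalization_and_symmetry(self):
        offsets, weights = sinusoidal(20, 0.25).dwell_density(2.0)
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(weights, weights[::-1])
        assert np.allclose(offsets, -offsets[::-1])

    @pytest.mark.parametrize("A", [5.0, 7.5, 20.0])
    def test_support_is_excursion_range(self, A):
        offsets, weights = sinusoidal(A, 0.25).dwell_density(2.0)
        nz = offsets[weights > 0]
        assert nz.min() >= -A - 1.0  # bin centers stay within one half-bin of +-A
        assert nz.max() <= A + 1.0
        # the outermost occupied bins must cover the excursion endpoints
        assert nz.max() + 1.0 >= A
        assert nz.min() - 1.0 <= -A

    def test_matches_time_sampling_histogram(self):
        # occupancy fractions from dense uniform time sampling of Z(t)
        A, dz = 20.0, 2.0
        p = sinusoidal(A, 0.25, 1.1)
        t = (np.arange(100_000) + 0.5) / 100_000 * p.period
        samples = p.displacement(t)
        offsets, weights = p.dwell_density(dz)
        edges = np.concatenate([offsets - dz / 2, [offsets[-1] + dz / 2]])
        hist, _ = np.histogram(samples, bins=edges)
        assert np.allclose(hist / hist.sum(), weights, atol=2e-4)

    def test_rejects_constant_speed(self):
        with pytest.raises(ValueError):
            constant_speed(1.0).dwell_density(2.0)


class TestValidation:
    def test_static_with_motion_parameters_rejected(self):
        with pytest.raises(ValueError):
            MotionPattern(kind="static", A=3.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            MotionPattern(kind="sinusoidal", A=-1.0, f=0.25)

    def test_rom_is_twice_amplitude(self):
        assert sinusoidal(12.5, 0.25).rom == 25.0
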