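"""Phase constructions: wrapping, activation/arrival phase, LAT, levels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasedefect import (Movie, activation_phase, arrival_phase,
                         defect_thickness, fronts, hilbert_phase, lat_series,
                         phase_gradient, phase_levels, unwrap, update_lat)

PI = np.pi


class TestUnwrap:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0),
        (5.0, 5.0 - 2 * PI),          # ~ -1.2832
        (PI, -PI),                    # boundary tie maps to -pi
        (-PI, -PI),
        (2 * PI, 0.0),
        (-5.0, 2 * PI - 5.0),
    ])
    def test_values(self, x, expected):
        assert unwrap(x) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-50, 50))
    def test_congruent_and_minimal(self, x):
        u = float(unwrap(x))
        assert -PI <= u < PI
        assert abs((u - x) / (2 * PI) - round((u - x) / (2 * PI))) < 1e-9

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(-20, 20))
    def test_antisymmetry_away_from_boundary(self, x):
        # antisymmetric except on the pi (mod 2pi) boundary itself
        if abs(abs(float(unwrap(x))) - PI) > 1e-6:
            assert float(unwrap(-x)) == pytest.approx(-float(unwrap(x)),
                                                      abs=1e-9)


class TestActivationPhase:
    @pytest.mark.parametrize("dv,dr,expected", [
        (1.0, 0.0, 0.0),
        (0.0, 1.0, PI / 2),
        (-1.0, 0.0, -PI),   # pi wraps to the negative representative
    ])
    def test_axis_directions(self, dv, dr, expected):
        phi = activation_phase(np.array([0.5 + dv]), np.array([0.2 + dr]),
                               0.5, 0.2, b=0.0)
        assert phi[0] == pytest.approx(expected, abs=1e-12)

    def test_offset_rewraps(self):
        phi = activation_phase(np.array([1.5]), np.array([0.2]), 0.5, 0.2,
                               b=1.5 * PI)
        assert phi[0] == pytest.approx(-PI / 2, abs=1e-12)

    def test_reference_point_is_undefined(self):
        phi = activation_phase(np.array([[0.5, 1.0]]), np.array([[0.2, 0.2]]),
                               0.5, 0.2)
        assert np.isnan(phi[0, 0]) and np.isfinite(phi[0, 1])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            activation_phase(np.zeros(3), np.zeros(4), 0.5, 0.2)


class TestLat:
    def test_single_crossing(self):
        lat = np.zeros((1,))
        for t, (a, b) in zip([2.0, 3.0], [(0.2, 0.4), (0.4, 0.6)]):
            lat = update_lat(lat, np.array([a]), np.array([b]), t, 0.5)
        assert lat[0] == 3.0

    def test_never_activated_keeps_sentinel(self):
        lat = update_lat(np.zeros(1), np.array([0.2]), np.array([0.4]), 5.0, 0.5)
        assert lat[0] == 0.0

    def test_newest_crossing_overwrites(self):
        trace = [0.2, 0.6, 0.2, 0.7]
        lat = np.zeros(1)
        for k in range(1, 4):
            lat = update_lat(lat, np.array([trace[k - 1]]),
                             np.array([trace[k]]), float(k + 1), 0.5)
        assert lat[0] == 4.0  # second upstroke wins

    def test_lat_series_matches_frame_by_frame_updates(self, rng):
        V = rng.uniform(0, 1, size=(30, 6, 5))
        movie = Movie(V=V, dt_frame=2.0, dx=1.0)
        series = lat_series(movie, 0.5)
        lat = np.zeros((6, 5))
        for k in range(1, 30):
            lat = update_lat(lat, V[k - 1], V[k], movie.times[k], 0.5)
            assert np.array_equal(series[k], lat)
        assert np.all(series[0] == 0.0)


class TestArrivalPhase:
    def test_fresh_activation_is_zero(self):
        assert arrival_phase(10.0, np.array([10.0]), tau=20.0)[0] == 0.0

    def test_value_at_tau(self):
        # 2*pi*tanh(3) = 6.2521 rad -> wraps to about -0.0311
        phi = arrival_phase(30.0, np.array([10.0]), tau=20.0)
        assert phi[0] == pytest.approx(2 * PI * np.tanh(3.0) - 2 * PI,
                                       abs=1e-12)
        assert phi[0] == pytest.approx(-0.0311, abs=1e-4)

    def test_saturation_equals_rest(self):
        phi = arrival_phase(1e6, np.array([1.0]), tau=20.0)
        assert abs(phi[0]) < 1e-9

    def test_never_activated_is_undefined(self):
        assert np.isnan(arrival_phase(5.0, np.array([0.0]), tau=20.0)[0])

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            arrival_phase(1.0, np.array([1.0]), tau=0.0)


class TestPhaseGradient:
    def test_constant_field(self):
        g = phase_gradient(np.full((5, 5), 1.3), dx=1.0)
        assert np.all(g[:-1, :-1] == 0.0)
        assert np.all(np.isnan(g[-1, :])) and np.all(np.isnan(g[:, -1]))

    def test_ramp_across_wrap(self):
        """A 0.1 rad/px ramp has constant gradient even across the 2pi wrap."""
        phi = unwrap(0.1 * np.arange(100))[None, :].repeat(2, axis=0)
        g = phase_gradient(phi, dx=1.0)
        assert np.allclose(g[0, :-1], 0.1, atol=1e-12)

    def test_step_below_pi_is_unchanged(self):
        """A 3-rad step is below the pi wrap boundary, so U leaves it at
        3.0 (a 3.5-rad step, by contrast, reads as its 2pi complement)."""
        g = phase_gradient(np.array([[0.0, 3.0], [0.0, 3.0]]), dx=1.0)
        assert g[0, 0] == pytest.approx(3.0, abs=1e-12)
        g = phase_gradient(unwrap(np.array([[0.0, 3.5], [0.0, 3.5]])), dx=1.0)
        assert g[0, 0] == pytest.approx(2 * PI - 3.5, abs=1e-12)

    def test_undefined_neighbor_propagates(self):
        phi = np.array([[0.0, np.nan], [0.0, 0.1]])
        g = phase_gradient(phi, dx=1.0)
        assert np.isnan(g[0, 0])


class TestPhaseLevels:
    def test_synthetic_cycle(self):
        """On the circular cycle V = V*+cos(th), R = R*+sin(th) traversed
        with increasing th, the upstroke (dV/dt > 0) sits at th = -pi/2 and
        the downstroke at +pi/2, fixing phi1 = -pi/2 and phi2 = +pi/2."""
        th = np.linspace(0, 6 * PI, 241)
        V = (0.5 + np.cos(th))[:, None, None] * np.ones((1, 2, 2))
        R = (0.2 + np.sin(th))[:, None, None] * np.ones((1, 2, 2))
        movie = Movie(V=V, dt_frame=1.0, dx=1.0)
        phases = activation_phase(V, R, 0.5, 0.2)
        lv = phase_levels(movie, phases, 0.5)
        assert lv.phi1 == pytest.approx(-PI / 2, abs=0.1)
        assert lv.phi2 == pytest.approx(PI / 2, abs=0.1)

    def test_no_activity_is_an_error(self):
        movie = Movie(V=np.zeros((5, 3, 3)), dt_frame=1.0, dx=1.0)
        with pytest.raises(ValueError, match="phi1"):
            phase_levels(movie, np.zeros((5, 3, 3)), 0.5)


class TestFronts:
    def test_quiescent_frames_are_empty(self):
        fs = fronts(np.zeros((4, 4)), np.zeros((4, 4)), 0.5)
        assert not fs.WF.any() and not fs.WB.any()

    def test_plane_wave_bands(self, ap_rotor):
        """During S1 propagation the WF and WB are disjoint vertical bands."""
        k = int(round(30.0 / ap_rotor.dt_frame))
        fs = fronts(ap_rotor.V[k - 1], ap_rotor.V[k], 0.5)
        assert fs.WF.any() and fs.WB.any()
        assert not (fs.WF & fs.WB).any()
        # bands: each front occupies a narrow range of columns
        for m in (fs.WF, fs.WB):
            cols = np.argwhere(m)[:, 1]
            assert cols.max() - cols.min() <= 3
        # WF is ahead (larger x) of WB, separated by the pulse width
        assert np.argwhere(fs.WF)[:, 1].min() > np.argwhere(fs.WB)[:, 1].max()


class TestDefectThickness:
    def test_published_worked_values(self):
        """sqrt(D*tau) with D = 1.171 cm^2/s, tau = 269 ms gives 5.6 mm
        across fibers and 14 mm along them (anisotropy ratio 2.5)."""
        assert round(defect_thickness(1.171, 269.0), 1) == 5.6
        assert round(defect_thickness(1.171, 269.0, 2.5)) == 14

    def test_degenerate_and_invalid(self):
        assert defect_thickness(0.0, 100.0) == 0.0
        with pytest.raises(ValueError):
            defect_thickness(-1.0, 100.0)
        with pytest.raises(ValueError):
            defect_thickness(1.0, 100.0, anisotropy_ratio=0.5)


class TestHilbertPhase:
    def test_sinusoid_winding(self, sinusoid):
        """The analytic-signal phase advances 2pi per period: winding count
        over the trace equals f*T within one cycle."""
        phi = hilbert_phase(sinusoid)
        tr = phi[:, 3, 3]
        wraps = (np.abs(np.diff(tr)) > PI).sum()
        expected = sinusoid.meta["frequency"] * sinusoid.n_frames
        assert abs(wraps - expected) <= 1

    def test_constant_pixel_is_undefined(self):
        V = np.ones((64, 3, 3)) * 0.5
        V[:, 0, 0] = 0.5 + 0.3 * np.sin(np.arange(64) / 3.0)
        phi = hilbert_phase(Movie(V=V, dt_frame=1.0, dx=1.0))
        assert np.isfinite(phi[:, 0, 0]).all()
        assert np.isnan(phi[:, 1, 1]).all()
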