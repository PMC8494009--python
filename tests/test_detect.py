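"""Detectors: ring PS method vs winding oracle, CBL/PDL/PDS edge rules."""

import numpy as np
import pytest

from phasedefect import (associate_ps_pdl, detect_cbl, detect_pdl,
                         detect_pdl_cos, detect_pds, detect_ps,
                         random_phase_field, straddle_field, winding_number)

PI = np.pi


def _plaquette(values):
    """2x2 field whose ring traversal (0,0)->(0,1)->(1,1)->(1,0) visits
    ``values`` in order."""
    a, b, c, d = values
    return np.array([[a, b], [d, c]])


class TestRingMethod:
    def test_single_vortex_plaquette(self):
        """Phases 0, pi/2, pi, 3pi/2 around the ring: one raw difference
        exceeds pi, so a PS with positive winding is flagged."""
        phi = _plaquette([0.0, PI / 2, -PI, -PI / 2])  # stored representatives
        ps = detect_ps(phi, "ring2x2")
        assert len(ps) == 1
        assert ps[0].position == (0.5, 0.5)
        assert ps[0].chirality == +1
        assert winding_number(phi)[0, 0] == 1.0

    def test_uniform_field_has_no_ps(self):
        assert detect_ps(np.full((6, 6), 0.7), "ring2x2") == []

    def test_defect_straddle_is_rejected(self):
        """A plaquette straddling a phase jump (two super-pi differences)
        carries no winding and must not be reported as a PS."""
        phi = _plaquette([0.0, 0.0, 3.2 - 2 * PI, 3.2 - 2 * PI])
        assert detect_ps(phi, "ring2x2") == []
        assert winding_number(phi)[0, 0] == 0.0

    def test_undefined_pixels_skip_corner(self):
        phi = _plaquette([0.0, PI / 2, -PI, -PI / 2])
        phi[0, 0] = np.nan
        assert detect_ps(phi, "ring2x2") == []

    def test_combined_method_is_stricter(self, rng):
        """Every 2x2+4x4 detection is also a 2x2 detection."""
        for _ in range(20):
            phi, _ = random_phase_field(rng)
            small = {p.position for p in detect_ps(phi, "ring2x2")}
            combined = {p.position for p in detect_ps(phi, "ring2x2_4x4")}
            assert combined <= small

    def test_combined_method_needs_4x4(self):
        with pytest.raises(ValueError, match="4x4"):
            detect_ps(np.zeros((3, 3)), "ring2x2_4x4")

    def test_vortex_found_by_both_methods(self, rng):
        phi, vortices = random_phase_field(rng, n_vortices=1, smooth_modes=0)
        (yv, xv, charge) = vortices[0]
        expected = (np.floor(yv) + 0.5, np.floor(xv) + 0.5)
        for method in ("ring2x2", "ring2x2_4x4"):
            ps = detect_ps(phi, method)
            assert [p.position for p in ps] == [expected]
            assert ps[0].chirality == charge


class TestWindingOracle:
    def test_oracle_values_are_integers_in_range(self, rng):
        for _ in range(30):
            phi, _ = random_phase_field(rng)
            w = winding_number(phi)
            assert np.isin(w[np.isfinite(w)], [-1.0, 0.0, 1.0]).all()

    def test_ring2x2_equals_oracle(self, rng):
        """On smooth-plus-vortex fields the ring method detects exactly the
        corners with winding +/-1, with matching chirality."""
        for _ in range(100):
            phi, _ = random_phase_field(rng)
            w = winding_number(phi)
            oracle = {(i + 0.5, j + 0.5): int(w[i, j])
                      for i, j in np.argwhere(np.nan_to_num(w) != 0)}
            found = {p.position: p.chirality for p in detect_ps(phi, "ring2x2")}
            assert found == oracle


class TestCbl:
    def test_single_jump_row(self):
        lat = np.array([[10.0, 12.0, 100.0, 102.0]])
        ds = detect_cbl(lat, dt_c=16.0)
        assert ds.n_edges == 1
        assert tuple(ds.midpoints[0]) == (0.0, 1.5)

    def test_never_activated_is_excluded(self):
        assert detect_cbl(np.array([[10.0, 0.0]]), 5.0).n_edges == 0

    def test_uniform_lat_is_empty(self):
        assert detect_cbl(np.full((4, 4), 33.0), 1.0).n_edges == 0

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            detect_cbl(np.ones((2, 2)), 0.0)


class TestPdl:
    def test_step_above_threshold(self):
        phi = np.array([[0.1, 0.1, 2.9, 2.9]])
        ds = detect_pdl(phi, 2.0)
        assert ds.n_edges == 1
        assert tuple(ds.midpoints[0]) == (0.0, 1.5)

    def test_two_pi_jumps_are_invisible(self):
        """A near-2pi raw jump unwraps to its small residual (-0.2) and
        stays below threshold."""
        phi = np.array([[0.1, float(np.mod(0.1 + 2 * PI - 0.2 + PI, 2 * PI) - PI)]])
        assert detect_pdl(phi, 0.3).n_edges == 0

    def test_constant_field_is_empty(self):
        assert detect_pdl(np.zeros((4, 4)), 2.22).n_edges == 0

    def test_unreachable_threshold_warns(self):
        with pytest.warns(RuntimeWarning, match="never fire"):
            detect_pdl(np.zeros((3, 3)), PI + 0.1)

    def test_monotone_in_threshold(self, rng):
        phi = rng.uniform(-PI, PI, size=(20, 20))
        loose = {tuple(e.ravel()) for e in detect_pdl(phi, 1.0).edges}
        tight = {tuple(e.ravel()) for e in detect_pdl(phi, 2.5).edges}
        assert tight <= loose

    def test_components_are_connected_lines(self):
        """A straight jump line forms a single 8-connected component."""
        phi = np.zeros((8, 8))
        phi[:, 4:] = 2.8
        ds = detect_pdl(phi, 2.0)
        assert ds.n_edges == 8
        assert ds.n_components == 1


class TestPdlCos:
    def test_equivalent_to_arccos_threshold(self, rng):
        """cos(dphi) < A fires exactly where |U(dphi)| > arccos(A)."""
        for A in (np.cos(2.22), 0.0, -0.5):
            for _ in range(10):
                phi = rng.uniform(-PI, PI, size=(15, 15))
                a = detect_pdl_cos(phi, A)
                b = detect_pdl(phi, float(np.arccos(A)))
                assert np.array_equal(a.edges, b.edges)

    def test_cosine_evaluation(self):
        ds = detect_pdl_cos(np.array([[0.0, 3.0]]), A=0.0)
        assert ds.n_edges == 1  # cos(3.0) ~ -0.99 < 0

    def test_printed_inequality_flags_smooth_tissue(self):
        phi = np.zeros((3, 3))
        assert detect_pdl_cos(phi, 0.5).n_edges == 0
        assert detect_pdl_cos(phi, 0.5, printed_inequality=True).n_edges == 12

    def test_invalid_A(self):
        with pytest.raises(ValueError):
            detect_pdl_cos(np.zeros((2, 2)), 1.5)


class TestPds:
    def test_extruded_pdl(self):
        """A z-constant volume carries the 2D PDL extruded along z: one
        in-plane flagged edge per layer and no transverse edges."""
        phi2d = np.zeros((6, 6))
        phi2d[:, 3:] = 2.8
        vol = np.repeat(phi2d[:, :, None], 5, axis=2)
        pds = detect_pds(vol, 2.0)
        ds2d = detect_pdl(phi2d, 2.0)
        assert pds.n_edges == 5 * ds2d.n_edges
        assert pds.n_components == 1
        assert np.all(np.mod(pds.midpoints[:, 2], 1.0) == 0)  # all in-plane

    def test_uniform_volume_is_empty(self):
        assert detect_pds(np.zeros((4, 4, 4)), 2.0).n_edges == 0

    def test_surface_consistency_on_slab(self, scroll3d):
        """The 3D detector restricted to the bottom surface agrees exactly
        with the 2D detector on that surface, and the block surface spans
        the wall interior."""
        from phasedefect import arrival_phase_series, detect_pdl as dpdl

        tau = 70.0
        parr = arrival_phase_series(scroll3d, tau, 0.5)
        k = int(round((scroll3d.meta["t_s2"] + 16.0) / scroll3d.dt_frame))
        pds = detect_pds(parr[k], 2.0, frame=k)
        assert pds.n_edges > 0
        mp = pds.midpoints
        bottom_inplane = {tuple(m[:2]) for m in mp[mp[:, 2] == 0.0]}
        surf = dpdl(parr[k][:, :, 0], 2.0, frame=k)
        assert bottom_inplane == {tuple(m) for m in surf.midpoints}
        assert mp[:, 2].max() >= 2.0  # extends into the wall


class TestAssociation:
    def test_ps_on_its_cell_edge(self):
        phi = np.zeros((4, 4))
        ds = detect_pdl(np.array([[0.0, 2.8], [0.0, 2.8]]), 2.0)
        ps = detect_ps(_vortex_field(), "ring2x2")
        on = associate_ps_pdl(ps, ds)
        assert on.shape == (1,) and on[0]

    def test_empty_defect_set(self):
        ps = detect_ps(_vortex_field(), "ring2x2")
        ds = detect_pdl(np.zeros((4, 4)), 2.0)
        assert not associate_ps_pdl(ps, ds).any()

    def test_distant_pdl_is_off(self):
        ps = detect_ps(_vortex_field(), "ring2x2")  # PS at (0.5, 0.5)
        phi = np.zeros((8, 8))
        phi[:, 6:] = 2.8  # PDL nodes at columns 5 and 6
        on = associate_ps_pdl(ps, detect_pdl(phi, 2.0))
        assert not on.any()


def _vortex_field():
    return np.array([[0.0, PI / 2], [-PI / 2, -PI]])


def test_straddle_fields_have_no_winding(rng):
    """Step fields with a super-pi jump are never reported as PSs."""
    for _ in range(50):
        phi = straddle_field(rng)
        assert detect_ps(phi, "ring2x2") == []
        w = winding_number(phi)
        assert np.all(w[np.isfinite(w)] == 0.0)
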