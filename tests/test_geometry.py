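"""Gonad geometry: path arclength, projection, tube/rachis enforcement,
DTC migration and stretching."""

import numpy as np
import pytest

from germsim.geometry import DTCPathSpec, GeometryError, GonadGeometry


def make_geom(pre_turn=None, arc=200.0, turn_radius=10.0, **spec_kw):
    spec = DTCPathSpec(turn_radius_um=turn_radius, **spec_kw)
    g = GonadGeometry(spec)
    g.dtc_arclength = arc
    g.pre_turn_len = pre_turn
    return g


class TestPath:
    def test_initial_dtc_position_on_axis(self):
        g = make_geom(arc=20.0)
        assert np.allclose(g.dtc_position(), [20.0, 0, 0])

    def test_turn_endpoint_geometry(self):
        """At arclength P + pi*Rt the path is at (P, 2*Rt, 0) heading back
        antiparallel to the distal axis."""
        g = make_geom(pre_turn=100.0, arc=200.0, turn_radius=10.0)
        end = g.path_point(100.0 + np.pi * 10.0)[0]
        assert np.allclose(end, [100.0, 20.0, 0], atol=1e-9)
        after = g.path_point(100.0 + np.pi * 10.0 + 5.0)[0]
        assert np.allclose(after, [95.0, 20.0, 0], atol=1e-9)

    def test_total_length_analytic(self):
        """L1=100, Rt=10, L2=50 gives 100 + 10*pi + 50 ~ 181.4 um."""
        total = 100.0 + np.pi * 10.0 + 50.0
        g = make_geom(pre_turn=100.0, arc=total, turn_radius=10.0)
        assert g.total_length_um == pytest.approx(181.4159, abs=1e-3)
        # the path point at the very end exists and is on the return limb
        p = g.path_point(total)[0]
        assert np.allclose(p, [50.0, 20.0, 0], atol=1e-9)


class TestProjection:
    def test_point_on_path_has_zero_rho(self):
        g = make_geom(pre_turn=100.0, arc=181.4159, turn_radius=10.0)
        for s in (10.0, 100.0 + 5.0, 140.0):
            x = g.path_point(s)[0]
            s_hat, rho = g.project_to_path(x)
            assert rho == pytest.approx(0.0, abs=1e-9)
            assert s_hat == pytest.approx(s, abs=1e-6)

    def test_perpendicular_offset_mid_segment(self):
        g = make_geom(pre_turn=None, arc=100.0)
        s, rho = g.project_to_path([50.0, 3.0, 0.0])
        assert s == pytest.approx(50.0)
        assert rho == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_dense_sampling_oracle(self, seed):
        """Projection agrees with a brute-force nearest-point search over
        10^4 path samples to within 0.1 um in distance."""
        g = make_geom(pre_turn=80.0, arc=80.0 + np.pi * 10 + 60.0,
                      turn_radius=10.0)
        rng = np.random.default_rng(seed)
        X = rng.uniform([-10, -15, -15], [100, 40, 15], size=(100, 3))
        s_grid = np.linspace(0, g.dtc_arclength, 10_000)
        pts = g.path_point(s_grid)
        s, rho, _ = g.project(X)
        for i in range(len(X)):
            d_grid = np.linalg.norm(pts - X[i], axis=1)
            assert rho[i] == pytest.approx(d_grid.min(), abs=0.1)

    def test_tie_at_turn_center_resolves_to_smaller_s(self):
        """The turn's center is equidistant from every turn point; the
        projection must pick the smallest arclength."""
        g = make_geom(pre_turn=100.0, arc=181.4159, turn_radius=10.0)
        center = np.array([100.0, 10.0, 0.0])
        s, rho = g.project_to_path(center)
        assert s == pytest.approx(100.0, abs=1e-6)


class TestTubeEnforcement:
    def test_interior_cell_unchanged(self):
        g = make_geom(arc=100.0)
        X = np.array([[50.0, 2.0, 0.0]])
        out, s, rho = g.enforce_tube(X, np.array([2.7]), t=16.0)
        assert np.allclose(out, X)

    def test_surface_contact_moved_inward_by_radius(self):
        g = make_geom(arc=100.0)
        r_tube = g.radius_at(16.0)
        X = np.array([[50.0, r_tube, 0.0]])
        out, s, rho = g.enforce_tube(X, np.array([2.7]), t=16.0)
        assert rho[0] == pytest.approx(r_tube - 2.7)
        assert np.allclose(out[0], [50.0, r_tube - 2.7, 0.0])

    def test_random_violators_satisfy_postcondition(self):
        g = make_geom(pre_turn=80.0, arc=150.0, turn_radius=17.0)
        rng = np.random.default_rng(1)
        X = rng.uniform([-20, -30, -30], [120, 60, 30], size=(200, 3))
        radii = np.full(200, 2.7)
        out, s, rho = g.enforce_tube(X, radii, t=16.0)
        assert np.all(rho + radii <= g.radius_at(16.0) + 1e-9)
        assert np.all(s <= g.dtc_arclength + 1e-9)

    def test_gonad_narrower_than_cell_is_an_error(self):
        g = make_geom(arc=100.0)
        with pytest.raises(GeometryError):
            g.enforce_tube(np.array([[50.0, 0, 0.0]]), np.array([50.0]),
                           t=16.0)


class TestRachisEnforcement:
    def test_axis_cell_pushed_to_wall_shell(self):
        """In the distal arm a cell on the tube axis moves out to
        rho = r - 2*radius."""
        g = make_geom(pre_turn=None, arc=100.0)
        r_tube = g.radius_at(25.0)
        X = np.array([[50.0, 0.0, 0.0]])
        out, s, rho = g.enforce_rachis(X, np.array([2.7]), t=25.0)
        assert rho[0] == pytest.approx(r_tube - 2 * 2.7)

    def test_proximal_cells_unconstrained(self):
        g = make_geom(pre_turn=80.0, arc=150.0, turn_radius=17.0)
        X = np.array([[40.0, 0.0, 0.0]])  # s=40 < turn start
        out, s, rho = g.enforce_rachis(X, np.array([2.7]), t=25.0)
        assert np.allclose(out, X)

    def test_joint_band_with_tube(self):
        """After tube + rachis enforcement, distal cells lie in the wall
        band r - 2R <= rho <= r - R."""
        g = make_geom(pre_turn=20.0, arc=150.0, turn_radius=17.0)
        rng = np.random.default_rng(2)
        X = rng.uniform([-10, -20, -20], [40, 60, 20], size=(150, 3))
        radii = np.full(150, 2.7)
        r_tube = g.radius_at(25.0)
        out, s, rho = g.enforce_tube(X, radii, t=25.0)
        feet = g.path_point(s)
        out, s, rho = g.enforce_rachis(out, radii, t=25.0,
                                       proj=(s, rho, feet))
        distal = s >= g.pre_turn_len
        assert np.all(rho[distal] >= r_tube - 2 * 2.7 - 1e-9)
        assert np.all(rho[distal] <= r_tube - 2.7 + 1e-9)


class TestDTCMigration:
    def test_unobstructed_advance(self):
        g = make_geom(arc=20.0)
        adv = g.update_dtc(5.0, 0.1, max_cell_arclength=20.0,
                           cell_diameter_um=5.4)
        assert adv == pytest.approx(0.5)
        assert g.dtc_arclength == pytest.approx(20.5)

    def test_full_gap_pauses_migration(self):
        g = make_geom(arc=20.0)
        adv = g.update_dtc(5.0, 0.1, max_cell_arclength=20.0 - 5.4,
                           cell_diameter_um=5.4)
        assert adv == 0.0

    def test_partial_gap_truncates_advance(self):
        g = make_geom(arc=20.0)
        adv = g.update_dtc(5.0, 0.1, max_cell_arclength=20.0 - 5.1,
                           cell_diameter_um=5.4)
        assert adv == pytest.approx(0.3)

    def test_migration_budget_caps_travel(self):
        g = make_geom(arc=20.0, migration_budget_um=1.0)
        g.update_dtc(50.0, 1.0, max_cell_arclength=20.0,
                     cell_diameter_um=5.4)
        assert g.dtc_arclength == pytest.approx(21.0)

    def test_arclength_non_decreasing(self):
        g = make_geom(arc=20.0)
        rng = np.random.default_rng(0)
        prev = g.dtc_arclength
        for _ in range(50):
            g.update_dtc(rng.uniform(0, 20), 0.05,
                         max_cell_arclength=prev - rng.uniform(0, 8),
                         cell_diameter_um=5.4)
            assert g.dtc_arclength >= prev
            prev = g.dtc_arclength


class TestStretch:
    def make_stretching(self):
        spec = DTCPathSpec(turn_radius_um=10.0, stretch_window=(30.0, 34.0),
                           stretch_rate_um_per_h=10.0)
        g = GonadGeometry(spec)
        g.pre_turn_len = 40.0
        g.dtc_arclength = 40.0 + np.pi * 10.0 + 60.0
        return g

    def test_outside_window_no_change(self):
        g = self.make_stretching()
        before = g.dtc_arclength
        assert g.apply_stretch(20.0, 0.1) is None
        assert g.dtc_arclength == before

    def test_total_length_grows_by_twice_displacement(self):
        g = self.make_stretching()
        before = g.dtc_arclength
        g.apply_stretch(31.0, 0.1)  # d_sigma = 1.0
        assert g.dtc_arclength == pytest.approx(before + 2.0)
        assert g.pre_turn_len == pytest.approx(41.0)

    def test_exact_doubling_over_window(self):
        """stretch_rate * window = initial proximal length doubles the
        proximal region."""
        g = self.make_stretching()
        # proximal length 40; rate 10 over 4 h -> displacement 40
        t = 30.0
        while t < 34.0:
            g.apply_stretch(t, 0.1)
            t += 0.1
        assert g.pre_turn_len == pytest.approx(80.0, rel=1e-9)

    def test_remap_is_monotone(self):
        """Strictly monotone; the deliberate gap just distal of the turn
        is where stretching opens new space."""
        g = self.make_stretching()
        s = np.linspace(0, g.dtc_arclength, 500)
        remap = g.apply_stretch(31.0, 0.1)
        out = remap(s)
        assert np.all(np.diff(out) > 0)
        assert out[0] == pytest.approx(0.0)

    def test_dtc_gap_preserved_under_stretch(self):
        """A cell riding at the DTC stays at the DTC through stretching
        (the tip is remapped with the same frame as the cells)."""
        g = self.make_stretching()
        cell_s = np.array([g.dtc_arclength - 1.0])
        remap = g.apply_stretch(31.0, 0.1)
        new_gap = g.dtc_arclength - remap(cell_s)[0]
        assert new_gap == pytest.approx(1.0, abs=0.05)
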