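"""2D moving-boundary flow solver: validation cases and swirl metrics."""

import numpy as np
import pytest

from vesica.displacement import SphericalFrame, compute_displacement_field
from vesica.flow import (
    FluidProperties,
    FlowDomain,
    Grid2D,
    PlaneSpec,
    UrethraChannel,
    _vorticity_centers,
    build_domain,
    dimensionless_vorticity,
    recirculation_from_fields,
    simulate_channel_flow,
    solve_voiding_flow,
)
from vesica.synthetic import VoidingScenario, make_voiding_pair
from vesica.temporal import AlphaCurve, alpha_sqrt_cosine, volume_and_flow

TEST_FLUID = FluidProperties(density=1000.0, viscosity=0.02)  # nu = 20 mm^2/s


def small_domain(pattern="uniform", shrink=0.5, tend=6.0, r_pre=20.0,
                 static=False, D=6.0, plane="x"):
    sc = VoidingScenario(pattern=pattern, r_pre=r_pre, shrink_fraction=shrink,
                         mesh_subdivisions=3)
    pre, post, _ = make_voiding_pair(sc)
    frame = SphericalFrame.from_meshes(pre, post)
    field = compute_displacement_field(pre, post, frame)
    t = np.linspace(0.0, tend, 33)
    alpha = alpha_sqrt_cosine(t, 0.0, tend)
    if static:
        alpha = np.zeros_like(t)
    kin = volume_and_flow(pre, field, frame, AlphaCurve(t, alpha))
    return build_domain(kin, PlaneSpec(normal=plane),
                        UrethraChannel(diameter=D, length=12.0))


class TestDomain:
    def test_sphere_slice_is_circle(self):
        dom = small_domain(static=True)
        # uniform scenario: post is concentric, origin at centre -> R = r_pre
        np.testing.assert_allclose(dom.R[0], 20.0, rtol=5e-3)

    def test_channel_geometry(self):
        dom = small_domain(static=True, D=6.0)
        assert dom.y_outlet == pytest.approx(-dom.R[0].max() - 12.0, abs=0.5)
        assert dom.channel.diameter == 6.0

    def test_area_matches_circle_plus_channel(self):
        dom = small_domain(static=True)
        circle = np.pi * 20.0**2
        assert dom.area[0] > circle  # channel adds area
        # the added part is at most the whole channel rectangle
        extra_max = dom.channel.diameter * (dom.y_channel_top - dom.y_outlet)
        assert dom.area[0] < circle + extra_max

    def test_oversized_channel_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            small_domain(D=25.0)

    def test_tangent_plane_rejected(self):
        sc = VoidingScenario(pattern="uniform", r_pre=20.0, shrink_fraction=0.5,
                             mesh_subdivisions=2)
        pre, post, _ = make_voiding_pair(sc)
        frame = SphericalFrame.from_meshes(pre, post)
        t = np.linspace(0, 1, 9)
        kin = volume_and_flow(
            pre, compute_displacement_field(pre, post, frame), frame,
            AlphaCurve(t, np.zeros_like(t)),
        )
        with pytest.raises(ValueError, match="misses"):
            build_domain(kin, PlaneSpec(normal="x", offset=25.0),
                         UrethraChannel(6.0, 12.0))


class TestPoiseuille:
    def test_profile_within_two_percent_at_16_cells(self):
        res = simulate_channel_flow(D=8.0, L=16.0, n_across=16,
                                    dp_over_rho=800.0, fluid=TEST_FLUID)
        assert res.relative_error < 0.02
        assert res.max_divergence < 1e-6

    def test_profile_error_decreases_with_resolution(self):
        errs = [
            simulate_channel_flow(D=8.0, L=16.0, n_across=n,
                                  dp_over_rho=800.0, fluid=TEST_FLUID).profile_error
            for n in (8, 16, 32)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_profile_is_parabolic(self):
        res = simulate_channel_flow(D=8.0, L=16.0, n_across=16,
                                    dp_over_rho=800.0, fluid=TEST_FLUID)
        exact = res.v_max_analytic * (1 - (2 * res.x_profile / 8.0) ** 2)
        np.testing.assert_allclose(res.v_profile, exact,
                                   atol=0.02 * res.v_max_analytic)


class TestSolverBasics:
    def test_static_walls_stay_quiescent(self):
        dom = small_domain(static=True, tend=1.0)
        sol = solve_voiding_flow(dom, grid_h=0.75, n_snapshots=3)
        for snap in sol.snapshots:
            assert np.abs(snap.u).max() < 1e-12
            assert np.abs(snap.v).max() < 1e-12

    def test_underresolved_channel_rejected(self):
        dom = small_domain(static=True)
        with pytest.raises(ValueError, match="under-resolves"):
            solve_voiding_flow(dom, grid_h=1.0)  # D=6 -> 6 cells

    def test_bad_cfl_rejected(self):
        dom = small_domain(static=True)
        with pytest.raises(ValueError, match="cfl"):
            solve_voiding_flow(dom, grid_h=0.75, cfl=0.9)


@pytest.fixture(scope="module")
def driven_solution():
    """One small driven voiding run shared by the conservation/metric tests."""
    dom = small_domain(pattern="uniform", shrink=0.5, tend=6.0, r_pre=20.0, D=6.0)
    return solve_voiding_flow(dom, grid_h=0.75, n_snapshots=10)


class TestDrivenVoiding:
    def test_outlet_flux_matches_area_shrink(self, driven_solution):
        sol = driven_solution
        assert sol.mass_error < 0.02

    def test_divergence_free_after_projection(self, driven_solution):
        assert driven_solution.max_divergence.max() < 1e-6

    def test_outflow_is_outward(self, driven_solution):
        sol = driven_solution
        assert sol.mean_outlet_flux > 0
        # bulk of the run pushes fluid out
        assert np.quantile(sol.outlet_flux, 0.1) > -1e-6

    def test_determinism(self):
        dom = small_domain(pattern="uniform", shrink=0.4, tend=3.0, r_pre=15.0,
                           D=6.0)
        a = solve_voiding_flow(dom, grid_h=0.75, n_snapshots=3)
        b = solve_voiding_flow(dom, grid_h=0.75, n_snapshots=3)
        np.testing.assert_array_equal(a.outlet_flux, b.outlet_flux)
        np.testing.assert_array_equal(a.mean_abs_vorticity, b.mean_abs_vorticity)
        np.testing.assert_array_equal(a.recirc_fraction, b.recirc_fraction)


class TestVorticity:
    def grid(self, n=32, h=0.5):
        return Grid2D(x0=-n * h / 2, y0=-n * h / 2, h=h, nx=n, ny=n)

    def faces(self, g):
        xf, yc = np.meshgrid(g.xf, g.yc, indexing="ij")
        xc, yf = np.meshgrid(g.xc, g.yf, indexing="ij")
        return (xf, yc), (xc, yf)

    def test_uniform_flow_zero_vorticity(self):
        g = self.grid()
        u = np.ones((g.nx + 1, g.ny))
        v = np.zeros((g.nx, g.ny + 1))
        np.testing.assert_allclose(_vorticity_centers(u, v, g.h), 0.0, atol=1e-14)

    def test_solid_body_rotation_curl_is_two_omega(self):
        g = self.grid()
        (xfu, ycu), (xcv, yfv) = self.faces(g)
        omega = 3.0
        u = -omega * ycu
        v = omega * xcv
        w = _vorticity_centers(u, v, g.h)
        np.testing.assert_allclose(w, 2 * omega, atol=1e-10)

    def test_matches_independent_stencil_on_smooth_field(self):
        """Central-difference curl agrees with a wider-stencil oracle to
        O(h^2) on a smooth analytic field."""
        g = self.grid(n=64, h=0.25)
        (xfu, ycu), (xcv, yfv) = self.faces(g)
        u = np.sin(0.4 * xfu) * np.cos(0.3 * ycu)
        v = np.cos(0.25 * xcv) * np.sin(0.35 * yfv)
        w = _vorticity_centers(u, v, g.h)
        X, Y = np.meshgrid(g.xc, g.yc, indexing="ij")
        w_exact = (-0.25 * np.sin(0.25 * X) * np.sin(0.35 * Y)
                   - 0.3 * np.sin(0.4 * X) * -np.sin(0.3 * Y) * -1)
        # exact: dv/dx - du/dy
        w_exact = (-0.25 * np.sin(0.25 * X) * np.sin(0.35 * Y)
                   + 0.3 * np.sin(0.4 * X) * np.sin(0.3 * Y))
        assert np.abs(w[2:-2, 2:-2] - w_exact[2:-2, 2:-2]).max() < 5e-3

    def test_mean_vorticity_of_rotation_masked_disk(self):
        from vesica.flow import _mean_abs_vorticity

        g = self.grid()
        (xfu, ycu), (xcv, yfv) = self.faces(g)
        u, v = -3.0 * ycu, 3.0 * xcv
        X, Y = np.meshgrid(g.xc, g.yc, indexing="ij")
        disk = X**2 + Y**2 < 36.0
        assert _mean_abs_vorticity(u, v, g.h, disk) == pytest.approx(6.0, abs=1e-10)


class TestDimensionlessVorticity:
    def test_hand_value(self):
        assert dimensionless_vorticity(10.0, 100.0, 5.0) == pytest.approx(2.5)

    def test_zero_vorticity(self):
        assert dimensionless_vorticity(0.0, 50.0, 5.0) == 0.0

    def test_time_rescaling_invariance(self):
        """Doubling both the vorticity and the flow rate (a time-rescaled
        Stokes-regime run) leaves the dimensionless value unchanged."""
        assert dimensionless_vorticity(20.0, 200.0, 5.0) == pytest.approx(
            dimensionless_vorticity(10.0, 100.0, 5.0)
        )

    def test_pseudo3d_mode(self):
        z2 = dimensionless_vorticity(10.0, 100.0, 5.0, mode="pseudo3d")
        assert z2 == pytest.approx(10.0 * 5.0 / (100.0 / (np.pi * 25.0 / 4.0)))

    def test_zero_flow_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            dimensionless_vorticity(1.0, 0.0, 5.0)


class TestRecirculation:
    def grid(self):
        n, h = 64, 0.5
        return Grid2D(x0=-16.0, y0=-16.0, h=h, nx=n, ny=n)

    def center_coords(self, g):
        return np.meshgrid(g.xc, g.yc, indexing="ij")

    def test_pure_sink_flow_has_no_recirculation(self):
        g = self.grid()
        X, Y = self.center_coords(g)
        outlet = np.array([0.0, -15.0])
        dx, dy = outlet[0] - X, outlet[1] - Y
        r = np.hypot(dx, dy)
        uc, vc = dx / r, dy / r  # everywhere toward the sink
        mask = X**2 + Y**2 < 14.0**2
        assert recirculation_from_fields(uc, vc, mask, g, outlet) == 0.0

    def test_superposed_vortex_matches_pointwise_oracle(self):
        """Sink + strong off-centre vortex: the grid fraction matches a
        dense Monte-Carlo evaluation of the same angle criterion."""
        g = self.grid()
        X, Y = self.center_coords(g)
        outlet = np.array([0.0, -15.0])

        def velocity(x, y):
            dx, dy = outlet[0] - x, outlet[1] - y
            r = np.hypot(dx, dy) + 1e-12
            u, v = dx / r, dy / r
            # ideal vortex centred at (5, 5), circulation dominating locally
            vx, vy = x - 5.0, y - 5.0
            r2 = vx**2 + vy**2 + 1.0
            u += -40.0 * vy / r2 / (2 * np.pi)
            v += 40.0 * vx / r2 / (2 * np.pi)
            return u, v

        uc, vc = velocity(X, Y)
        mask = X**2 + Y**2 < 14.0**2
        frac = recirculation_from_fields(uc, vc, mask, g, outlet)
        assert frac > 0.03

        rng = np.random.default_rng(11)
        pts = rng.uniform(-14, 14, size=(200_000, 2))
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) < 14.0]
        u, v = velocity(pts[:, 0], pts[:, 1])
        sx, sy = outlet[0] - pts[:, 0], outlet[1] - pts[:, 1]
        speed = np.hypot(u, v)
        opposed = (u * sx + v * sy < 0) & (speed > 0.01 * speed.max())
        assert frac == pytest.approx(opposed.mean(), abs=0.02)

    def test_speed_floor_excludes_near_stagnant_cells(self):
        g = self.grid()
        X, Y = self.center_coords(g)
        outlet = np.array([0.0, -15.0])
        mask = X**2 + Y**2 < 14.0**2
        # one fast sink-ward jet, everything else creeping upward (away)
        uc = np.zeros_like(X)
        vc = np.full_like(Y, 1e-4)
        vc[32, :] = -50.0
        frac = recirculation_from_fields(uc, vc, mask, g, outlet)
        assert frac == 0.0

    def test_quiescent_step_warns_and_returns_zero(self):
        g = self.grid()
        X, Y = self.center_coords(g)
        mask = X**2 + Y**2 < 14.0**2
        with pytest.warns(UserWarning, match="quiescent"):
            frac = recirculation_from_fields(np.zeros_like(X), np.zeros_like(Y),
                                             mask, g, np.array([0.0, -15.0]))
        assert frac == 0.0
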