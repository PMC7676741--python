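"""Ray casting, displacement fields, regional statistics and densities."""

import numpy as np
import pytest

from vesica.displacement import (
    DensityEstimate,
    SphericalFrame,
    _fibonacci_directions,
    asymmetry_ratio,
    compute_displacement_field,
    displacement_density,
    fivenum,
    partition_regions,
    radial_distance,
    ray_triangle_intersect,
    regional_stats,
)
from vesica.mesh import SurfaceMesh
from vesica.synthetic import VoidingScenario, make_sphere_mesh, make_voiding_pair


def brute_force_intersect(origin, direction, tri, eps=1e-9):
    """Independent oracle: solve the 3x3 linear system
    origin + t*d = v0 + u*e1 + w*e2 and test barycentric containment."""
    v0, v1, v2 = (np.asarray(p, float) for p in tri)
    A = np.column_stack([-np.asarray(direction, float), v1 - v0, v2 - v0])
    if abs(np.linalg.det(A)) < 1e-12:
        return None
    t, u, w = np.linalg.solve(A, np.asarray(origin, float) - v0)
    if u < -eps or w < -eps or u + w > 1 + eps or t < -eps:
        return None
    return max(t, 0.0)


class TestMollerTrumbore:
    def test_axis_aligned_hit(self):
        t = ray_triangle_intersect(
            (0, 0, 0), (0, 0, 1), [(-1, -1, 5), (2, -1, 5), (0, 2, 5)]
        )
        assert t == pytest.approx(5.0, abs=1e-12)

    def test_behind_ray_is_miss(self):
        t = ray_triangle_intersect(
            (0, 0, 0), (0, 0, -1), [(-1, -1, 5), (2, -1, 5), (0, 2, 5)]
        )
        assert t is None

    def test_degenerate_triangle_warns_and_misses(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t = ray_triangle_intersect(
                (0, 0, 0), (0, 0, 1), [(0, 0, 5), (0, 0, 5), (1, 0, 5)]
            )
        assert t is None

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ray_triangle_intersect((0, 0, 0), (0, 0, 2), [(0, 0, 5)] * 3)

    def test_agrees_with_brute_force_oracle(self, rng):
        """10^4 random ray/triangle pairs: identical hit classification and
        hit distances to 1e-9 relative."""
        n_disagree = 0
        for _ in range(10_000):
            origin = rng.normal(size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            tri = rng.normal(scale=2.0, size=(3, 3))
            t_mt = ray_triangle_intersect(origin, d, tri)
            t_bf = brute_force_intersect(origin, d, tri)
            if (t_mt is None) != (t_bf is None):
                n_disagree += 1
            elif t_mt is not None:
                assert t_mt == pytest.approx(t_bf, rel=1e-9, abs=1e-12)
        assert n_disagree == 0


class TestRadialDistance:
    def test_sphere_radius(self, sphere_sub4):
        frame = SphericalFrame(np.zeros(3))
        for theta, phi in [(0.0, 0.0), (np.pi / 2, 1.0), (2.0, -2.0)]:
            hit = radial_distance(sphere_sub4, frame, (theta, phi))
            assert hit.r == pytest.approx(10.0, rel=2e-3)
            assert hit.multiplicity == 1

    def test_cube_axis(self):
        verts = np.array(
            [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
             [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float
        )
        faces = np.array(
            [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
             [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
             [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
        )
        cube = SurfaceMesh(verts, faces)
        frame = SphericalFrame(np.zeros(3))
        hit = radial_distance(cube, frame, np.array([1.0, 0.0, 0.0]))
        assert hit.r == pytest.approx(1.0, abs=1e-12)

    def test_torus_multiplicity(self):
        """A ray from the hole centre of a torus crosses the tube twice; the
        nearest crossing is returned with the crossing count flagged."""
        import trimesh

        t = trimesh.creation.torus(major_radius=10.0, minor_radius=3.0)
        torus = SurfaceMesh(np.asarray(t.vertices), np.asarray(t.faces))
        frame = SphericalFrame(np.zeros(3))
        hit = radial_distance(torus, frame, np.array([1.0, 0.0, 0.0]))
        assert hit.r == pytest.approx(7.0, rel=0.02)
        assert hit.multiplicity == 2

    def test_escaping_ray_raises(self, sphere_sub4):
        frame = SphericalFrame(np.array([0.0, 0.0, 50.0]))  # outside
        with pytest.raises(ValueError, match="does not meet"):
            radial_distance(sphere_sub4, frame, (0.0, 0.0))  # ray points away


class TestDisplacementField:
    def test_concentric_spheres_d0(self, concentric_field):
        field, *_ = concentric_field
        np.testing.assert_allclose(field.d0, 10.0, rtol=0.02)
        assert field.n_failed == 0

    def test_identical_meshes_give_zero(self, sphere_sub4):
        frame = SphericalFrame(np.zeros(3))
        field = compute_displacement_field(sphere_sub4, sphere_sub4, frame)
        np.testing.assert_allclose(field.d0, 0.0, atol=1e-9)

    def test_tangential_components_identically_zero(self, concentric_field):
        field, *_ = concentric_field
        assert np.all(field.d_theta == 0.0)
        assert np.all(field.d_phi == 0.0)

    def test_dome_pattern_recovery_within_edge_length(self):
        sc = VoidingScenario(pattern="dome_weighted", r_pre=30.0,
                             shrink_fraction=0.25, dome_gain=1.8,
                             mesh_subdivisions=4)
        pre, post, truth = make_voiding_pair(sc)
        frame = SphericalFrame.from_meshes(pre, post)
        field = compute_displacement_field(pre, post, frame)
        dirs = (field.directions_local() @ frame.axes)
        expected = truth.d0_true(dirs)
        edges = pre.vertices[pre.faces[:, 0]] - pre.vertices[pre.faces[:, 1]]
        mean_edge = np.linalg.norm(edges, axis=1).mean()
        assert np.max(np.abs(field.d0 - expected)) < 2.0 * mean_edge

    def test_rigid_rotation_equivariance(self, concentric_pair):
        """Rotating both meshes and the frame leaves d0 and the regional
        statistics unchanged."""
        from scipy.spatial.transform import Rotation

        pre, post, _ = concentric_pair
        R = Rotation.from_euler("zyx", [0.3, -1.1, 0.7]).as_matrix()
        frame0 = SphericalFrame.from_meshes(pre, post)
        f0 = compute_displacement_field(pre, post, frame0)
        pre_r = SurfaceMesh(pre.vertices @ R.T, pre.faces)
        post_r = SurfaceMesh(post.vertices @ R.T, post.faces)
        frame_r = SphericalFrame(R @ frame0.origin, frame0.axes @ R.T)
        f1 = compute_displacement_field(pre_r, post_r, frame_r)
        np.testing.assert_allclose(f1.d0, f0.d0, atol=1e-9)
        s0, s1 = regional_stats(f0), regional_stats(f1)
        for reg in s0.summaries:
            assert s1.summaries[reg]["median"] == pytest.approx(
                s0.summaries[reg]["median"], abs=1e-9
            )

    def test_uniform_sphere_sampling_mode(self, concentric_pair):
        pre, post, _ = concentric_pair
        frame = SphericalFrame.from_meshes(pre, post)
        field = compute_displacement_field(pre, post, frame,
                                           sampling=("uniform_sphere", 500))
        assert field.n_samples == 500
        np.testing.assert_allclose(field.d0, 10.0, rtol=0.02)


class TestRegions:
    def test_axis_directions_labelled(self, concentric_field):
        field, frame, *_ = concentric_field
        local = field.directions_local()
        apex = np.argmax(local[:, 2])
        assert field.region_db[apex] == "dome"
        diag = np.argmax(local @ np.ones(3) / np.sqrt(3))
        assert field.region_lr[diag] == "left"
        assert field.region_ap[diag] == "anterior"
        assert field.region_db[diag] == "dome"

    def test_hemisphere_shares_balanced(self, concentric_field):
        field, *_ = concentric_field
        n = field.n_samples
        for reg in ("anterior", "dome", "left"):
            share = field.region_mask(reg).sum() / n
            assert share == pytest.approx(0.5, abs=0.02)

    def test_boundary_tie_goes_positive(self):
        frame = SphericalFrame(np.zeros(3))
        from vesica.displacement import DisplacementField

        field = DisplacementField(
            theta=np.array([np.pi / 2]), phi=np.array([np.pi / 2]),
            r_pre=np.array([1.0]), r_post=np.array([1.0]), d0=np.array([0.0]),
            d_theta=np.zeros(1), d_phi=np.zeros(1),
            multiplicity_pre=np.ones(1, int), multiplicity_post=np.ones(1, int),
            n_failed=0, frame=frame,
        )
        field = partition_regions(field, frame)
        # direction (0, 1, 0): x = 0 exactly -> left (positive side)
        assert field.region_lr[0] == "left"
        assert field.region_db[0] == "dome"


class TestStatsAndAsymmetry:
    def test_fivenum_hand_example(self):
        q = fivenum(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (q["min"], q["q1"], q["median"], q["q3"], q["max"]) == (1, 2, 3, 4, 5)

    @pytest.mark.parametrize("left,right,expected", [
        (10.0, 10.0, 0.0),
        (15.0, 10.0, 40.0),
        (10.0, 2.0, 400.0 / 3.0),
    ])
    def test_asymmetry_formula(self, left, right, expected):
        assert asymmetry_ratio(left, right) == pytest.approx(expected, rel=1e-12)

    def test_asymmetry_symmetric_in_sides(self):
        assert asymmetry_ratio(15.0, 10.0) == asymmetry_ratio(10.0, 15.0)

    def test_asymmetry_can_exceed_100_percent(self):
        assert asymmetry_ratio(10.0, 1.0) > 100.0

    def test_asymmetry_both_zero_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            asymmetry_ratio(0.0, 0.0)

    def test_uniform_scenario_stats(self, concentric_field):
        field, *_ = concentric_field
        stats = regional_stats(field)
        for reg in stats.summaries.values():
            assert reg["median"] == pytest.approx(10.0, rel=0.02)
            assert reg["q3"] - reg["q1"] < 0.2
        assert stats.asymmetry_ratio < 1.0

    def test_asymmetric_scenario_medians(self, asymmetric_pair):
        pre, post, truth = asymmetric_pair
        frame = SphericalFrame.from_meshes(pre, post)
        field = compute_displacement_field(pre, post, frame)
        stats = regional_stats(field)
        assert stats.summaries["left"]["median"] == pytest.approx(15.0, rel=0.02)
        assert stats.summaries["right"]["median"] == pytest.approx(10.0, rel=0.02)
        assert stats.asymmetry_ratio == pytest.approx(truth.asymmetry_true, rel=0.05)


class TestDensity:
    def test_normal_samples_mode(self, rng):
        samples = rng.normal(10.0, 1.0, size=10_000)
        den = displacement_density(samples)
        assert den.mode == pytest.approx(10.0, abs=0.2)
        assert den.integral == pytest.approx(1.0, abs=1e-3)

    def test_uniform_scenario_near_point_mass(self, concentric_field):
        field, *_ = concentric_field
        den = displacement_density(field)
        assert den.mode == pytest.approx(10.0, abs=0.1)
        # essentially all mass within the tiny faceting spread
        inside = (den.grid > 9.5) & (den.grid < 10.5)
        assert np.trapezoid(den.density[inside], den.grid[inside]) > 0.99

    def test_degenerate_point_mass(self):
        with pytest.warns(UserWarning, match="point mass"):
            den = displacement_density(np.full(50, 3.0))
        assert den.point_mass and den.location == 3.0
        assert den.integral == 1.0

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="20 samples"):
            displacement_density(np.arange(5.0))


class TestFrame:
    def test_origin_outside_rejected(self, concentric_pair):
        pre, post, _ = concentric_pair
        shifted = post.translated([100.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="not inside"):
            SphericalFrame.from_meshes(pre, shifted)

    def test_non_orthonormal_axes_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            SphericalFrame(np.zeros(3), np.eye(3) * 2.0)

    def test_left_handed_axes_rejected(self):
        axes = np.eye(3)
        axes[2] *= -1
        with pytest.raises(ValueError, match="right-handed"):
            SphericalFrame(np.zeros(3), axes)

    def test_fibonacci_directions_are_unit_and_balanced(self):
        d = _fibonacci_directions(2000)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        assert abs(d[:, 2].mean()) < 0.01
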