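"""Drill profile, distance fields, trajectory clearance, entry angles and
the exposed-area model."""

import numpy as np
import pytest
import trimesh

from canalplan.centreline import CanalTargets
from canalplan.clearance import (
    DistanceField,
    DrillProfile,
    Trajectory,
    build_distance_field,
    drill_radius,
    entry_angle,
    exposed_area,
    trajectory_clearance,
)
from canalplan.errors import OutOfBoundsError, RangeError
from conftest import brute_force_distance


class TestDrillProfile:
    @pytest.mark.parametrize(
        "s,expected",
        [(0.0, 0.5), (3.999, 0.5), (4.0, 0.6), (5.0, 0.6), (13.999, 0.6), (14.0, 1.25), (20.0, 1.25)],
    )
    def test_stepped_radius(self, s, expected):
        assert drill_radius(s) == expected

    def test_negative_distance_raises(self):
        with pytest.raises(RangeError):
            drill_radius(-0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"steps": ((4.0, 0.4), (14.0, 1.25))},  # not increasing
            {"steps": ((14.0, 0.6), (4.0, 1.25))},  # thresholds reversed
            {"tip_radius": -0.5},
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(RangeError):
            DrillProfile(**{"tip_radius": 0.5, **kwargs})


class TestDistanceField:
    def test_sphere_oracle(self):
        sphere = trimesh.creation.icosphere(subdivisions=4)
        f = build_distance_field(sphere, spacing=0.125, bounds=([-2.5] * 3, [2.5] * 3))
        assert f.query([[2.0, 0.0, 0.0]])[0] == pytest.approx(1.0, abs=0.13)
        assert abs(f.query([[1.0, 0.0, 0.0]])[0]) <= 0.13
        assert f.query([[0.0, 0.0, 0.0]])[0] < 0  # signed: negative inside

    def test_interpolation_error_below_two_spacings(self):
        """1000 random off-node queries vs the exhaustive closest-point
        oracle: |interpolated - exact| <= 2 x spacing."""
        rng = np.random.default_rng(0)
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.3)
        spacing = 0.125
        f = build_distance_field(mesh, spacing=spacing, bounds=([-2] * 3, [2] * 3))
        pts = rng.uniform(-1.9, 1.9, size=(1000, 3))
        interp = f.query(pts)
        exact = brute_force_distance(pts, mesh)
        assert np.abs(np.abs(interp) - exact).max() <= 2 * spacing

    def test_out_of_bounds_raises(self):
        sphere = trimesh.creation.icosphere(subdivisions=1)
        f = build_distance_field(sphere, spacing=0.25, bounds=([-2] * 3, [2] * 3))
        with pytest.raises(OutOfBoundsError):
            f.query([[5.0, 0.0, 0.0]])

    def test_cache_roundtrip(self, tmp_path):
        sphere = trimesh.creation.icosphere(subdivisions=1)
        f = build_distance_field(sphere, spacing=0.25, bounds=([-2] * 3, [2] * 3))
        f.save(tmp_path / "field")
        g = DistanceField.load(tmp_path / "field")
        pts = np.random.default_rng(1).uniform(-1.5, 1.5, (50, 3))
        assert np.allclose(f.query(pts), g.query(pts), atol=1e-5)


@pytest.fixture(scope="module")
def sphere_obstacle_setup():
    """Sphere obstacle (radius 2) 3.5 mm perpendicular from a 20 mm path,
    more than 14 mm from the tip: closed-form margin 3.5 - 2 - 1.25."""
    obstacle = trimesh.creation.icosphere(subdivisions=4, radius=2.0)
    obstacle.apply_translation([-16.0, 3.5, 0.0])
    field = build_distance_field(
        obstacle, spacing=0.125, bounds=([-21, -1, -2], [1, 7, 2]), name="sphere"
    )
    traj = Trajectory(entry=[-20.0, 0.0, 0.0], fenestration=[0.0, 0.0, 0.0])
    return traj, field


class TestTrajectoryClearance:
    def test_sphere_obstacle_closed_form(self, sphere_obstacle_setup):
        traj, field = sphere_obstacle_setup
        report = trajectory_clearance(traj, {"sphere": field})
        assert report.safety_margin == pytest.approx(0.25, abs=0.15)

    def test_margin_is_min_over_obstacles(self, sphere_obstacle_setup):
        traj, near = sphere_obstacle_setup
        far_mesh = trimesh.creation.icosphere(subdivisions=2)
        far_mesh.apply_translation([-10.0, -40.0, 0.0])
        far = build_distance_field(
            far_mesh, spacing=0.5, bounds=([-25, -45, -5], [5, 10, 5])
        )
        both = trajectory_clearance(traj, {"near": near, "far": far})
        alone = trajectory_clearance(traj, {"near": near})
        assert both.safety_margin == alone.safety_margin
        # duplicating an obstacle never changes the margin
        dup = trajectory_clearance(traj, {"a": near, "b": near})
        assert dup.safety_margin == alone.safety_margin

    def test_margin_monotone_in_drill_radius(self, sphere_obstacle_setup):
        traj, field = sphere_obstacle_setup
        margins = []
        for tip in (0.3, 0.5, 0.8, 1.2):
            profile = DrillProfile(tip_radius=tip, steps=((4.0, tip + 0.1), (14.0, tip + 0.75)))
            margins.append(
                trajectory_clearance(traj, {"s": field}, profile).safety_margin
            )
        assert np.all(np.diff(margins) < 0)

    def test_stepped_profile_not_safer_than_uniform_tip(self, sphere_obstacle_setup):
        traj, field = sphere_obstacle_setup
        stepped = trajectory_clearance(traj, {"s": field}, DrillProfile())
        uniform = trajectory_clearance(
            traj, {"s": field}, DrillProfile(tip_radius=0.5, steps=())
        )
        assert stepped.safety_margin <= uniform.safety_margin


class TestEntryAngle:
    @pytest.mark.parametrize(
        "direction,expected",
        [((1, 0, 0), 0.0), ((0, 1, 0), 90.0), ((-1, 0, 0), 180.0)],
    )
    def test_axis_aligned_cases(self, direction, expected):
        targets = CanalTargets(
            electrode_target=np.array([1.0, 0, 0]),
            fenestration_site=np.zeros(3),
            tangent=np.array([1.0, 0, 0]),
            offset=1.0,
        )
        traj = Trajectory(entry=-np.asarray(direction, float), fenestration=[0, 0, 0])
        assert entry_angle(traj, targets) == pytest.approx(expected, abs=1e-9)

    def test_random_configurations_match_closed_form(self):
        """100 random tangent/direction pairs: computed angle equals the
        closed-form arccos of the dot product within 0.5 degrees."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            tangent = rng.normal(size=3)
            tangent /= np.linalg.norm(tangent)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            expected = np.degrees(np.arccos(np.clip(np.dot(direction, tangent), -1, 1)))
            targets = CanalTargets(
                electrode_target=tangent,
                fenestration_site=np.zeros(3),
                tangent=tangent,
                offset=1.0,
            )
            traj = Trajectory(entry=-10 * direction, fenestration=[0, 0, 0])
            assert entry_angle(traj, targets) == pytest.approx(expected, abs=0.5)


def _voxel_exposed_area_oracle(theta_deg, lumen_d, tip_r, h=0.02):
    """Independent voxel-boolean oracle: count voxels in a thin shell
    around the canal wall that fall inside the swept drill volume; area =
    count * h^3 / shell thickness."""
    rc = lumen_d / 2.0
    theta = np.radians(theta_deg)
    drill_dir = np.array([np.cos(theta), 0.0, -np.sin(theta)])
    ext = tip_r / np.sin(theta) + tip_r + 2 * rc
    thick = 4 * h
    ax = np.arange(-ext, ext, h)
    ayz = np.arange(-rc - thick, rc + thick, h)
    X, Y, Z = np.meshgrid(ax, ayz, ayz, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.sqrt(pts[:, 1] ** 2 + pts[:, 2] ** 2)
    shell = np.abs(r - rc) <= thick / 2
    pts = pts[shell]
    proj = np.maximum(pts @ (-drill_dir), 0.0)
    closest = -proj[:, None] * drill_dir[None, :]
    inside = np.linalg.norm(pts - closest, axis=1) <= tip_r
    return inside.sum() * h**3 / thick


class TestExposedArea:
    def test_right_angle_matches_voxel_oracle(self):
        area = exposed_area(90.0, 1.1, 0.5)
        oracle = _voxel_exposed_area_oracle(90.0, 1.1, 0.5)
        assert area == pytest.approx(oracle, rel=0.05)

    def test_strictly_decreasing_with_angle(self):
        thetas = np.arange(10.0, 91.0, 10.0)
        areas = [exposed_area(t) for t in thetas]
        assert np.all(np.diff(areas) < 0)

    def test_dimensional_scaling(self):
        a = exposed_area(90.0, 1.1, 0.5)
        b = exposed_area(90.0, 2.2, 1.0)
        assert b / a == pytest.approx(4.0, rel=0.02)

    @pytest.mark.parametrize("theta", [0.0, -5.0, 90.5])
    def test_angle_out_of_range_raises(self, theta):
        with pytest.raises(RangeError):
            exposed_area(theta)
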