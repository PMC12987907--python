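"""Accessibility classification, access maps, mutual optimization and
reporting."""

import itertools

import numpy as np
import pytest
import trimesh

from canalplan.centreline import CanalTargets
from canalplan.clearance import DrillProfile, build_distance_field
from canalplan.errors import ConfigurationError, ParameterError
from canalplan.feasibility import (
    AccessMap,
    case_report,
    classify_access,
    cohort_summary,
    compute_access_map,
    optimize_mutual,
)


class TestClassifyAccess:
    @pytest.mark.parametrize(
        "margin,angle,threshold,expected",
        [
            (1.2, 45.0, 1.0, True),
            (0.9, 30.0, 1.0, False),  # margin fails
            (1.5, 80.0, 1.0, False),  # angle boundary is strict
            (1.0, 45.0, 1.0, False),  # margin boundary is strict
            (2.5, 79.9, 2.0, True),
        ],
    )
    def test_threshold_logic(self, margin, angle, threshold, expected):
        assert classify_access(margin, angle, threshold) is expected


def _toy_maps(rng, n=8, spread=20.0, canals=("superior", "lateral", "posterior")):
    pts = rng.uniform(0, spread, size=(n, 3))
    pts[:, 0] = 0.0
    maps = {}
    for c in canals:
        maps[c] = AccessMap(
            canal=c,
            entry_points=pts,
            uv=pts[:, 1:].copy(),
            fenestration_site=np.zeros(3),
            margins=rng.uniform(0, 3, n),
            angles=rng.uniform(0, 120, n),
            per_obstacle={},
            threshold=1.0,
        )
    return maps


def _brute_force_plan(maps, max_pairwise=12.5, ideal=30.0):
    canals = list(maps)
    pts = maps[canals[0]].entry_points
    idxs = {c: np.flatnonzero(maps[c].accessible) for c in canals}
    best = None
    for triple in itertools.product(*[idxs[c] for c in canals]):
        ps = [pts[i] for i in triple]
        dd = [np.linalg.norm(a - b) for a, b in itertools.combinations(ps, 2)]
        if max(dd) >= max_pairwise:
            continue
        obj = sum((maps[c].angles[i] - ideal) ** 2 for c, i in zip(canals, triple))
        if best is None or obj < best:
            best = obj
    return best


class TestOptimizeMutual:
    def test_equals_exhaustive_search_on_random_instances(self):
        """Pruned discrete optimization returns exactly the exhaustive
        minimum on 20 random toy instances (<= 1000 triples each)."""
        rng = np.random.default_rng(42)
        n_feasible = 0
        for _ in range(20):
            maps = _toy_maps(rng, n=int(rng.integers(5, 11)))
            plan = optimize_mutual(maps)
            oracle = _brute_force_plan(maps)
            if oracle is None:
                assert not plan.feasible
            else:
                n_feasible += 1
                assert plan.objective == pytest.approx(oracle, abs=1e-9)
                checks = plan.verify_constraints()
                assert all(checks.values())
                # the 12.5 mm pairwise bound implies the 15 mm circle
                assert plan.enclosing_diameter <= 2 * 12.5 / np.sqrt(3) + 1e-9
                assert plan.enclosing_diameter <= 15.0
        assert n_feasible >= 5  # the ensemble exercises feasible instances

    def test_forced_unique_solution(self):
        rng = np.random.default_rng(1)
        maps = _toy_maps(rng, n=6, spread=8.0)
        for c, idx in zip(maps, (2, 3, 4)):
            maps[c].margins[:] = 0.0
            maps[c].margins[idx] = 2.0
            maps[c].angles[:] = 90.0
            maps[c].angles[idx] = 40.0
        plan = optimize_mutual(maps)
        assert plan.feasible
        assert plan.entry_indices == {"superior": 2, "lateral": 3, "posterior": 4}

    def test_far_apart_points_are_infeasible(self):
        rng = np.random.default_rng(2)
        maps = _toy_maps(rng, n=3, spread=1.0)
        # separate the accessible point of each canal by > 12.5 mm
        for k, c in enumerate(maps):
            maps[c].margins[:] = 0.0
            maps[c].angles[:] = 90.0
            maps[c].margins[k] = 2.0
            maps[c].angles[k] = 30.0
            maps[c].entry_points = maps[c].entry_points.copy()
        pts = maps["superior"].entry_points
        pts[0] = [0, 0, 0]
        pts[1] = [0, 20, 0]
        pts[2] = [0, 0, 20]
        for c in maps:
            maps[c].entry_points = pts
        plan = optimize_mutual(maps)
        assert not plan.feasible
        assert plan.diagnostics

    def test_mismatched_entry_sets_rejected(self):
        rng = np.random.default_rng(3)
        maps = _toy_maps(rng)
        maps["lateral"].entry_points = maps["lateral"].entry_points + 1.0
        with pytest.raises(ConfigurationError):
            optimize_mutual(maps)

    def test_deterministic_under_tie(self):
        """Two identical-cost triples: the tie-break (smaller max pairwise
        distance, then lexicographic indices) is deterministic."""
        pts = np.array(
            [[0, 0, 0], [0, 1, 0], [0, 0, 1], [0, 5, 5]], dtype=float
        )
        maps = {}
        for c in ("superior", "lateral", "posterior"):
            maps[c] = AccessMap(
                canal=c,
                entry_points=pts,
                uv=pts[:, 1:].copy(),
                fenestration_site=np.array([-5.0, 0.0, 0.0]),
                margins=np.full(4, 2.0),
                angles=np.full(4, 30.0),  # every triple has objective 0
                per_obstacle={},
                threshold=1.0,
            )
        p1 = optimize_mutual(maps)
        p2 = optimize_mutual(maps)
        assert p1.entry_indices == p2.entry_indices
        assert p1.objective == 0.0
        # smallest max-pairwise triple is (0, 0, 0) and similar; verify the
        # tie-break chose a minimal-diameter configuration
        assert p1.max_pairwise == 0.0


@pytest.fixture(scope="module")
def phantom_access_setup():
    """Flat-plate phantom: entry region on a plate at x = 10, canal target
    at the origin, obstacles far away (50 mm)."""
    from canalplan.surfaces import build_entry_region

    plate = trimesh.creation.box(extents=[1.0, 60, 60])
    plate.apply_translation([10, -10, 0])
    region = build_entry_region(plate, [10.5, 8.0, 0.0], n_points=60)
    # deep target: every approach direction clusters around -x, so all
    # entry angles to the -x tangent stay well below 80 degrees
    targets = CanalTargets(
        electrode_target=np.array([-42.0, 0.0, 0.0]),
        fenestration_site=np.array([-40.0, 0.0, 0.0]),
        tangent=np.array([-1.0, 0.0, 0.0]),
        offset=2.0,
    )
    far = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
    far.apply_translation([-20.0, -60.0, 0.0])
    bounds = ([-45, -25, -18], [12, 20, 18])
    far_field = build_distance_field(far, spacing=0.5, bounds=bounds, name="far")
    return region, targets, far_field, bounds


class TestComputeAccessMap:
    def test_obstacle_free_phantom_is_fully_accessible(self, phantom_access_setup):
        region, targets, far_field, _ = phantom_access_setup
        amap = compute_access_map(
            region, targets, {"far": far_field}, ["far"], sample_step=0.25
        )
        assert (amap.angles < 80).all()
        assert amap.accessibility() == 100.0

    def test_blocking_wall_drives_accessibility_to_zero(self, phantom_access_setup):
        region, targets, far_field, bounds = phantom_access_setup
        wall = trimesh.creation.box(extents=[0.5, 50, 30])
        wall.apply_translation([5.0, -5.0, 0.0])
        wall_field = build_distance_field(wall, spacing=0.5, bounds=bounds, name="wall")
        amap = compute_access_map(
            region,
            targets,
            {"far": far_field, "wall": wall_field},
            ["far", "wall"],
            sample_step=0.25,
        )
        assert amap.accessibility() == 0.0

    def test_flags_match_gridless_oracle(self, phantom_access_setup):
        """Map flags agree with a per-trajectory recomputation using exact
        (non-grid) closest-point distances, outside a +-0.25 mm band
        around the threshold."""
        from canalplan.geometry import MeshDistance

        region, targets, far_field, bounds = phantom_access_setup
        rng = np.random.default_rng(0)
        wall = trimesh.creation.box(extents=[0.5, 30, 10])
        wall.apply_translation([5.0, -14.0, 0.0])
        wall_field = build_distance_field(wall, spacing=0.5, bounds=bounds, name="wall")
        amap = compute_access_map(
            region,
            targets,
            {"wall": wall_field},
            ["wall"],
            sample_step=0.25,
        )
        md = MeshDistance(wall)
        profile = DrillProfile()
        sel = rng.choice(len(region), size=50, replace=False)
        for i in sel:
            entry = region.points[i]
            fen = targets.fenestration_site
            length = np.linalg.norm(fen - entry)
            t = np.linspace(0.0, length, int(np.ceil(length / 0.25)) + 1)
            pts = entry + np.outer(t, (fen - entry) / length)
            d = md.signed_distance(pts)
            margin = (d - profile.radius_at(length - t)).min()
            if abs(margin - 1.0) > 0.25:
                assert amap.accessible[i] == classify_access(
                    margin, amap.angles[i], 1.0
                )

    def test_missing_field_is_configuration_error(self, phantom_access_setup):
        region, targets, far_field, _ = phantom_access_setup
        with pytest.raises(ConfigurationError):
            compute_access_map(region, targets, {}, ["far"])


class TestReports:
    def test_accessibility_monotone_in_threshold(self, case_artifacts):
        report, _ = case_artifacts
        for canal, metrics in report.per_canal.items():
            a05 = metrics["accessibility_0.5mm_pct"]
            a1 = metrics["accessibility_1.0mm_pct"]
            a2 = metrics["accessibility_2.0mm_pct"]
            assert a05 >= a1 >= a2

    def test_ci_parallel_trajectory_has_zero_offset(self, case_artifacts):
        _, art = case_artifacts
        maps = art["maps"]
        plan = art["plan"]
        canal = list(plan.trajectories)[0]
        traj = plan.trajectories[canal]
        rep = case_report(
            "ci-test",
            {t: maps for t in (0.5, 1.0, 2.0)},
            plan,
            ci_trajectory=(traj.entry, traj.direction),
        )
        assert rep.mutual[canal]["ci_angle_deg"] == pytest.approx(0.0, abs=1e-9)
        assert rep.mutual[canal]["ci_entry_distance_mm"] == pytest.approx(0.0)

    def test_ci_metrics_absent_without_ci_trajectory(self, case_artifacts):
        _, art = case_artifacts
        rep = case_report(
            "no-ci", {t: art["maps"] for t in (0.5, 1.0, 2.0)}, art["plan"], None
        )
        for metrics in rep.per_canal.values():
            assert metrics["min_accessible_ci_angle_deg"] is None

    def test_enclosing_circle_bound_from_pairwise_constraint(self, case_artifacts):
        _, art = case_artifacts
        plan = art["plan"]
        if plan.feasible:
            assert plan.max_pairwise < 12.5
            assert plan.enclosing_diameter <= 2 * 12.5 / np.sqrt(3) + 1e-9


class TestCohortSummary:
    def _report(self, case_id, value):
        from canalplan.feasibility import CaseReport

        return CaseReport(
            case_id=case_id,
            per_canal={"lateral": {"accessibility_1.0mm_pct": value}},
            mutual={},
            feasible=True,
            enclosing_diameter=10.0,
        )

    def test_single_report_degenerate_statistics(self):
        s = cohort_summary([self._report("a", 42.0)])
        row = s[s.metric == "accessibility_1.0mm_pct"].iloc[0]
        assert row["median"] == 42.0
        assert row.q3 - row.q1 == 0.0
        assert row["max"] - row["min"] == 0.0

    def test_textbook_median(self):
        reports = [self._report(f"c{i}", v) for i, v in enumerate([1, 2, 3, 4, 5])]
        s = cohort_summary(reports)
        assert s[s.metric == "accessibility_1.0mm_pct"].iloc[0]["median"] == 3.0

    def test_permutation_invariance(self):
        reports = [self._report(f"c{i}", v) for i, v in enumerate([5, 1, 4, 2, 3])]
        a = cohort_summary(reports)
        b = cohort_summary(list(reversed(reports)))
        assert a.equals(b)

    def test_empty_cohort_raises(self):
        with pytest.raises(ParameterError):
            cohort_summary([])
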