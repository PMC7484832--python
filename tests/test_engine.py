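"""Collision engine: verdicts, routing, sweeps, maps, plan verification."""

import numpy as np
import pytest

from cps.engine import (
    ClearanceMap,
    PlanFormatError,
    SweepError,
    clearance_map,
    detect_collision,
    prefilter_points,
    sweep_boundary,
    verify_plan,
    _gantry_routing_test,
)
from cps.machine import ImagerState, MachineState, pose_machine
from cps.patient import PointCloud
from cps.synthetic import PhantomSpec, RigidTransform, make_humanoid_phantom, make_scene

from _oracles import brute_force_verdict


class TestPrefilter:
    def test_far_superior_points_removed(self, geom, lateral_gantry_state):
        posed = pose_machine(geom, lateral_gantry_state)
        cloud = PointCloud(np.tile([0.0, -20.0, 150.0], (40, 1)))
        assert len(prefilter_points(cloud, posed)) == 0

    def test_point_inside_gantry_survives(self, geom, lateral_gantry_state):
        posed = pose_machine(geom, lateral_gantry_state)
        inner = posed.gantry_cylinders[1].axis_start * 1.01
        cloud = PointCloud(np.vstack([[0, 0, 500.0], inner]))
        kept = prefilter_points(cloud, posed)
        assert any(np.allclose(p, inner) for p in kept.points)

    def test_filter_never_changes_verdict(self, geom):
        """Verdicts with and without the longitudinal pre-filter agree."""
        for seed in range(50):
            scene = make_scene(seed, mode="random")
            with_filter = detect_collision(geom, scene.state, scene.cloud,
                                           margin=scene.margin)
            # disabling the filter = an arbitrarily wide guard band
            without = detect_collision(geom, scene.state, scene.cloud,
                                       margin=scene.margin, guard=1e6)
            assert with_filter.collided == without.collided
            assert with_filter.pairs == without.pairs


class TestDetect:
    def test_empty_cloud_couch_clear_of_gantry(self, geom):
        state = MachineState(gantry_angle=0.0, couch_vrt_readout=30.0)
        report = detect_collision(geom, state, PointCloud(np.empty((0, 3))))
        assert not report.collided
        assert report.pairs == ()

    def test_planted_point_names_volume(self, geom):
        state = MachineState(gantry_angle=90.0, couch_vrt_readout=30.0)
        posed = pose_machine(geom, state)
        cyl = posed.gantry_cylinders[1]
        inner = (cyl.axis_start + cyl.axis_end) / 2
        # pull the point back into the couch home frame
        disp = posed.displacement
        from cps.geometry import couch_rotation_matrix

        home = couch_rotation_matrix(disp.rtn).T @ inner - np.array([-disp.lat, -disp.vrt, disp.lng])
        report = detect_collision(geom, state, PointCloud(home))
        assert report.collided
        assert ("patient", "gantry_cyl_2") in report.pairs

    def test_forced_scenes_match_expectation(self, geom):
        for seed in range(30):
            for mode in ("forced_collision", "forced_clear"):
                scene = make_scene(seed, mode=mode)
                report = detect_collision(geom, scene.state, scene.cloud, margin=scene.margin)
                assert report.collided == scene.expected_collision, (seed, mode)
                if scene.forced_volume is not None:
                    assert scene.forced_volume in {v for _, v in report.pairs}

    def test_oracle_equivalence_sample(self, geom):
        """Engine verdict equals the flat all-points/all-volumes oracle."""
        for seed in range(25):
            scene = make_scene(seed, mode="random")
            report = detect_collision(geom, scene.state, scene.cloud, margin=scene.margin)
            expected, volumes = brute_force_verdict(geom, scene.state, scene.cloud.points,
                                                    margin=scene.margin)
            assert report.collided == expected, seed
            assert {v for _, v in report.pairs} == volumes, seed

    def test_determinism(self, geom):
        scene = make_scene(11, mode="random")
        a = detect_collision(geom, scene.state, scene.cloud)
        b = detect_collision(geom, scene.state, scene.cloud)
        assert a.collided == b.collided
        assert a.pairs == b.pairs
        assert np.array_equal(a.offending_points, b.offending_points)

    def test_margin_is_monotone(self, geom):
        """Inflating the margin can only add collisions, never remove them."""
        for seed in (3, 7, 19):
            scene = make_scene(seed, mode="random")
            collided = [
                detect_collision(geom, scene.state, scene.cloud, margin=m).collided
                for m in (0.0, 1.0, 3.0)
            ]
            assert collided == sorted(collided)


class TestGantryRouting:
    def test_routing_equals_naive_per_cylinder(self, geom, rng):
        """Plane-pair routing must reproduce the per-cylinder test exactly,
        including points placed exactly on shared cap planes."""
        for gantry in (0.0, 47.0, 90.0, 213.0):
            for margin in (0.0, 1.5):
                posed = pose_machine(geom, MachineState(gantry_angle=gantry,
                                                        couch_vrt_readout=30.0))
                pts = rng.uniform(-100, 100, size=(4000, 3))
                # add points exactly on every cap plane at varied radii
                a = posed.gantry_axis
                perp = np.cross(a, [0, 0, 1.0])
                perp /= np.linalg.norm(perp)
                offs = posed.gantry_plane_offsets
                radii = posed.gantry_radii
                extra = [off * a + r * perp
                         for off in offs
                         for r in np.concatenate([radii, radii + margin, [0.5, 60.0]])]
                pts = np.vstack([pts] + [np.array(extra)])
                routed = _gantry_routing_test(pts, posed, margin)
                for k, cyl in enumerate(posed.gantry_cylinders):
                    assert np.array_equal(routed[:, k], cyl.contains(pts, margin=margin)), k


class TestSweep:
    def test_clear_to_limit_below_gantry(self, geom):
        state = MachineState(gantry_angle=0.0, couch_vrt_readout=30.0)
        result = sweep_boundary(geom, state, axis="couch_lat", direction=1)
        assert result.clear_to_limit
        assert result.first_collide is None

    def test_bracketing_one_step_apart(self, geom, lateral_gantry_state):
        result = sweep_boundary(geom, lateral_gantry_state, axis="couch_rtn",
                                direction=1, step=0.25)
        assert not result.clear_to_limit
        assert result.first_collide - result.last_clear == pytest.approx(0.25)
        clear_state = lateral_gantry_state.with_(couch_rtn=result.last_clear)
        hit_state = lateral_gantry_state.with_(couch_rtn=result.first_collide)
        assert not detect_collision(geom, clear_state).collided
        assert detect_collision(geom, hit_state).collided

    def test_lateral_sweep_toward_gantry_head(self, geom, lateral_gantry_state):
        """At gantry 90 the head sits on the -x1 side; sweeping the couch
        toward it must find a boundary, away from it must clear to limit."""
        toward = sweep_boundary(geom, lateral_gantry_state, axis="couch_lat", direction=1)
        away = sweep_boundary(geom, lateral_gantry_state, axis="couch_lat", direction=-1)
        assert not toward.clear_to_limit
        assert away.clear_to_limit

    def test_starting_in_collision_raises(self, geom):
        scene = make_scene(2, mode="forced_collision")
        with pytest.raises(SweepError):
            sweep_boundary(geom, scene.state, scene.cloud, axis="couch_rtn")

    def test_inflated_radii_never_later_boundary(self, geom, lateral_gantry_state):
        """Growing every gantry radius by 1 cm gives an earlier (or equal)
        collision along the same sweep path."""
        from dataclasses import replace
        from cps.machine import GantrySpec

        bigger = replace(
            geom,
            gantry=GantrySpec(
                plane_offsets=geom.gantry.plane_offsets,
                radii=tuple(r + 1.0 for r in geom.gantry.radii),
            ),
        )
        base = sweep_boundary(geom, lateral_gantry_state, axis="couch_rtn", direction=1)
        inflated = sweep_boundary(bigger, lateral_gantry_state, axis="couch_rtn", direction=1)
        assert inflated.first_collide <= base.first_collide


@pytest.fixture(scope="module")
def symmetric_phantom():
    spec = PhantomSpec(
        kind="humanoid",
        pose=RigidTransform(np.eye(3), np.array([0.0, 0.0, -40.0])),
        point_density=0.2,
        noise_sigma=0.0,
        seed=5,
    )
    return make_humanoid_phantom(spec)


class TestClearanceMap:
    rtn_grid = np.arange(-90.0, 91.0, 15.0)
    gantry_grid = np.arange(0.0, 360.0, 20.0)

    def test_no_patient_couch_lowered_all_clear(self, geom):
        """Couch dropped below the reach of any beam from above: the
        whole (rtn x upper-hemisphere gantry) map is collision free."""
        state = MachineState(gantry_angle=0.0, couch_vrt_readout=50.0)
        upper = np.concatenate([np.arange(0.0, 91.0, 15.0), np.arange(270.0, 360.0, 15.0)])
        cmap = clearance_map(geom, state, None, self.rtn_grid, upper)
        assert cmap.clear.all()

    def test_adding_patient_only_removes_clear_cells(self, geom, symmetric_phantom):
        state = MachineState(couch_lng_readout=100.0, couch_vrt_readout=12.0)
        without = clearance_map(geom, state, None, self.rtn_grid, self.gantry_grid)
        with_patient = clearance_map(geom, state, symmetric_phantom,
                                     self.rtn_grid, self.gantry_grid)
        assert np.all(with_patient.clear <= without.clear)
        assert not with_patient.clear.all()

    def test_mirror_symmetry(self, geom, symmetric_phantom):
        """Symmetric phantom + symmetric machine: map invariant under
        (rtn, gantry) -> (-rtn, 360 - gantry)."""
        state = MachineState(couch_lng_readout=100.0, couch_vrt_readout=12.0)
        cmap = clearance_map(geom, state, symmetric_phantom,
                             self.rtn_grid, self.gantry_grid)
        n_r = len(self.rtn_grid)
        for i in range(n_r):
            for j, g in enumerate(self.gantry_grid):
                g_m = (360.0 - g) % 360.0
                j_m = int(np.where(np.isclose(cmap.gantry_grid, g_m))[0][0])
                assert cmap.clear[i, j] == cmap.clear[n_r - 1 - i, j_m], (i, j)

    def test_csv_export(self, geom, tmp_path):
        state = MachineState(gantry_angle=0.0, couch_vrt_readout=45.0, couch_lng_readout=0.0)
        cmap = clearance_map(geom, state, None, [-10.0, 0.0, 10.0], [0.0, 90.0])
        path = tmp_path / "map.csv"
        cmap.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].split(",")[1:] == ["0", "90"]
        assert len(lines) == 4
        assert all(cell in ("0", "1") for line in lines[1:] for cell in line.split(",")[1:])


class TestVerifyPlan:
    def test_known_clear_plan_passes(self, geom):
        state = MachineState(gantry_angle=0.0, couch_vrt_readout=40.0)
        cps = [{"gantry": 0.0, "rtn": 0.0}] * 4
        reports = verify_plan(geom, state, None, cps)
        assert all(not r.collided for r in reports)

    def test_injected_collision_fails_at_exact_index(self, geom, lateral_gantry_state):
        sweep = sweep_boundary(geom, lateral_gantry_state, axis="couch_rtn", direction=1)
        cps = [
            {"rtn": 0.0},
            {"rtn": sweep.last_clear},
            {"rtn": sweep.first_collide},
            {"rtn": 0.0},
        ]
        reports = verify_plan(geom, lateral_gantry_state, None, cps)
        assert [r.collided for r in reports] == [False, False, True, False]

    def test_matches_independent_detect_calls(self, geom, lateral_gantry_state):
        cps = [{"gantry": g, "rtn": r} for g, r in [(0, 0), (90, 10), (270, -20)]]
        reports = verify_plan(geom, lateral_gantry_state, None, cps)
        for cp, rep in zip(cps, reports):
            state = lateral_gantry_state.with_(gantry_angle=cp["gantry"], couch_rtn=cp["rtn"])
            assert rep.collided == detect_collision(geom, state, None).collided

    def test_malformed_control_point_names_index(self, geom):
        with pytest.raises(PlanFormatError, match="control point 1"):
            verify_plan(geom, MachineState(), None, [{"gantry": 0.0}, {"bogus": 1.0}])
        with pytest.raises(PlanFormatError):
            verify_plan(geom, MachineState(), None, [])
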