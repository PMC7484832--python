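"""Machine geometry config, readout conversion, and component posing."""

import numpy as np
import pytest

from cps.geometry import couch_rotation_matrix, gantry_rotation_matrix
from cps.machine import (
    ConfigError,
    MachineState,
    ImagerState,
    MotionRangeError,
    CouchDisplacement,
    default_geometry,
    geometry_from_dict,
    iec_to_readout,
    load_machine_geometry,
    pose_machine,
    readout_to_iec,
    save_machine_geometry,
)


class TestReadoutConversion:
    def test_centered_readout_is_zero_displacement(self, geom):
        disp = readout_to_iec(MachineState(couch_lat_readout=1000.0), geom)
        assert disp.lat == 0.0

    def test_near_center_branch(self, geom):
        disp = readout_to_iec(MachineState(couch_lat_readout=997.6), geom)
        assert disp.lat == pytest.approx(2.4)

    def test_wrapped_branch(self, geom):
        disp = readout_to_iec(MachineState(couch_lat_readout=0.5), geom)
        assert disp.lat == pytest.approx(-0.5)

    def test_linear_axes(self, geom):
        disp = readout_to_iec(MachineState(couch_lng_readout=95.0, couch_vrt_readout=16.6), geom)
        assert disp.lng == 95.0
        assert disp.vrt == 16.6

    @pytest.mark.parametrize("readout", np.concatenate([np.arange(0.4, 24.4, 1.7),
                                                        np.arange(976.0, 1000.1, 1.7)]))
    def test_roundtrip_both_branches(self, geom, readout):
        state = MachineState(couch_lat_readout=float(readout))
        disp = readout_to_iec(state, geom)
        back = iec_to_readout(disp, geom)
        assert back.couch_lat_readout == pytest.approx(readout)
        assert readout_to_iec(back, geom).lat == pytest.approx(disp.lat)

    def test_out_of_limit_rejected(self, geom):
        with pytest.raises(MotionRangeError):
            readout_to_iec(MachineState(couch_lat_readout=900.0), geom)  # 100 cm displacement
        with pytest.raises(MotionRangeError):
            readout_to_iec(MachineState(couch_vrt_readout=500.0), geom)


class TestConfig:
    def test_default_profile_validates(self):
        geom = default_geometry()
        assert len(geom.gantry.radii) == 4
        assert geom.lat_center_readout == 1000.0

    def test_negative_dimension_names_key(self):
        with pytest.raises(ConfigError, match="radii"):
            geometry_from_dict({"gantry": {"plane_offsets": (40, 50, 60, 70, 80),
                                           "radii": (-5, 30, 35, 40)}})
        with pytest.raises(ConfigError, match="couch.length"):
            geometry_from_dict({"couch": {"length": -1.0}})

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_roundtrip_write_read(self, tmp_path, suffix):
        geom = default_geometry()
        path = tmp_path / f"machine{suffix}"
        save_machine_geometry(geom, path)
        assert load_machine_geometry(path) == geom

    def test_plane_offsets_must_ascend(self):
        with pytest.raises(ConfigError, match="ascending"):
            geometry_from_dict({"gantry": {"plane_offsets": (40, 30, 60, 70, 80),
                                           "radii": (25, 30, 35, 40)}})


def _home_couch_corners_reference(couch):
    """Independent reconstruction of the couch-top prism corners."""
    wh, wf, L, t = couch.width_head / 2, couch.width_foot / 2, couch.length, couch.thickness
    out = []
    for y in (-t, 0.0):
        out += [[-wf, y, -L], [wf, y, -L], [wh, y, 0.0], [-wh, y, 0.0]]
    return np.array(out)


class TestPosing:
    def test_home_pose_positions(self, geom):
        state = MachineState(gantry_angle=0, couch_lat_readout=1000.0,
                             couch_lng_readout=0.0, couch_vrt_readout=0.0, couch_rtn=0.0)
        posed = pose_machine(geom, state)
        c0 = posed.gantry_cylinders[0]
        assert np.allclose(c0.axis_start, [0, geom.gantry.plane_offsets[0], 0])
        assert np.allclose(posed.couch_volume.corners, _home_couch_corners_reference(geom.couch))

    def test_gantry_180_mirrors_lateral_and_vertical(self, geom):
        posed = pose_machine(geom, MachineState(gantry_angle=180.0))
        home = pose_machine(geom, MachineState(gantry_angle=0.0))
        for c180, c0 in zip(posed.gantry_cylinders, home.gantry_cylinders):
            assert np.allclose(c180.axis_start, c0.axis_start * np.array([-1, -1, 1]), atol=1e-9)

    def test_posing_equivariance(self, geom):
        """Pose at angle == pose at home followed by the gantry rotation."""
        theta = 123.0
        posed = pose_machine(geom, MachineState(gantry_angle=theta,
                                                mv_imager=ImagerState(True, 40.0)))
        home = pose_machine(geom, MachineState(gantry_angle=0.0,
                                               mv_imager=ImagerState(True, 40.0)))
        R = gantry_rotation_matrix(theta)
        for cp, ch in zip(posed.gantry_cylinders, home.gantry_cylinders):
            assert np.allclose(cp.axis_end, R @ ch.axis_end, atol=1e-9)
        assert np.allclose(posed.imaging_volumes["mv_imager"].corners,
                           home.imaging_volumes["mv_imager"].corners @ R.T, atol=1e-9)

    def test_couch_pose_matches_matrix_oracle(self, geom, rng):
        """20 random states: posed corners equal explicit matrix algebra."""
        for _ in range(20):
            lat = rng.uniform(-20, 20)
            state = MachineState(
                couch_lat_readout=1000 - lat if lat >= 0 else -lat,
                couch_lng_readout=rng.uniform(0, 170),
                couch_vrt_readout=rng.uniform(0, 40),
                couch_rtn=rng.uniform(-90, 90),
            )
            posed = pose_machine(geom, state)
            ref = _home_couch_corners_reference(geom.couch)
            ref = ref + np.array([-lat, -state.couch_vrt_readout, state.couch_lng_readout])
            ref = (couch_rotation_matrix(state.couch_rtn) @ ref.T).T
            assert np.allclose(posed.couch_volume.corners, ref, atol=1e-9)

    def test_isocenter_point_invariant_under_rtn(self, geom):
        """A point placed at the isocenter stays put under pure RTN changes."""
        from cps.machine import couch_transform

        state = MachineState(couch_lng_readout=95.0, couch_vrt_readout=16.6)
        disp0 = readout_to_iec(state, geom)
        # couch-home point that lands on the isocenter after translation
        home_point = np.array([disp0.lat, disp0.vrt, -disp0.lng])
        for rtn in (-45.0, 0.0, 30.0, 90.0):
            disp = CouchDisplacement(disp0.lat, disp0.lng, disp0.vrt, rtn)
            assert np.allclose(couch_transform(home_point, disp), [0, 0, 0], atol=1e-12)

    def test_surface_points_on_faces_and_density_scaling(self, geom):
        state = MachineState(couch_rtn=25.0, couch_lng_readout=80.0, couch_vrt_readout=10.0)
        posed = pose_machine(geom, state, sampling=2.0)
        prism = posed.couch_volume
        # each sampled point lies on at least one face plane (within 1e-9)
        dists = []
        for fp, n in prism.face_planes:
            dists.append(np.abs((posed.couch_surface_points - fp) @ n))
        assert np.all(np.min(dists, axis=0) < 1e-9)
        # halving the step roughly quadruples the count
        n1 = len(pose_machine(geom, state, sampling=2.0).couch_surface_points)
        n2 = len(pose_machine(geom, state, sampling=1.0).couch_surface_points)
        assert n2 / n1 == pytest.approx(4.0, rel=0.15)

    def test_state_outside_limits_raises(self, geom):
        with pytest.raises(MotionRangeError):
            pose_machine(geom, MachineState(couch_rtn=120.0))
        with pytest.raises(MotionRangeError):
            pose_machine(geom, MachineState(mv_imager=ImagerState(True, 500.0)))
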