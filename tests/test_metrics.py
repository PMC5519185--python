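"""Trajectory metrics: superposition, angles, contacts, grids, Rg, RMSF."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from lrpath.metrics import (
    DegenerateGeometryError,
    contact_series,
    count_in_region,
    gate_rg,
    hbond_series,
    helix_angle,
    kabsch_superpose,
    occupancy_grid,
    rmsd,
    rmsd_timeseries,
    rmsf,
    saltbridge_series,
)
from lrpath.trajectory import Frame, Trajectory


def quaternion_rmsd(mobile, reference):
    """Independent quaternion-eigenvalue (Horn) superposition oracle."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sxx, sxy, sxz = (x[:, 0] @ y[:, 0], x[:, 0] @ y[:, 1], x[:, 0] @ y[:, 2])
    syx, syy, syz = (x[:, 1] @ y[:, 0], x[:, 1] @ y[:, 1], x[:, 1] @ y[:, 2])
    szx, szy, szz = (x[:, 2] @ y[:, 0], x[:, 2] @ y[:, 1], x[:, 2] @ y[:, 2])
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / len(x)
    return np.sqrt(max(msd, 0.0))


def _traj(coords_list, topology=None):
    return Trajectory(
        topology, [Frame(c, time=float(t)) for t, c in enumerate(coords_list)]
    )


class TestKabsch:
    def test_identity_on_equal_inputs(self, rng):
        x = rng.normal(size=(7, 3))
        rot, trans, r = kabsch_superpose(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_removes_arbitrary_rigid_motion(self, rng):
        x = rng.normal(size=(6, 3))
        rot_true = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        y = x @ rot_true.T + np.array([1.0, -2.0, 0.5])
        _, _, r = kabsch_superpose(y, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_quaternion_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=(6, 3))
            y = rng.normal(size=(6, 3))
            assert kabsch_superpose(x, y)[2] == pytest.approx(
                quaternion_rmsd(x, y), abs=1e-8
            )

    def test_reflection_corrected_to_proper_rotation(self, rng):
        x = rng.normal(size=(5, 3))
        y = x.copy()
        y[:, 2] *= -1  # mirrored target
        rot, _, _ = kabsch_superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(x, x + 1.0)

    def test_weights_shift_the_fit(self, rng):
        x = rng.normal(size=(5, 3))
        y = x.copy()
        y[0] += 5.0
        w = np.array([10.0, 1, 1, 1, 1])
        r_w = kabsch_superpose(x, y, weights=w)[2]
        r_u = kabsch_superpose(x, y)[2]
        assert r_w != pytest.approx(r_u)


class TestRMSDSeries:
    def test_copies_of_reference_are_zero(self, rng):
        ref = rng.normal(size=(5, 3))
        series = rmsd_timeseries(_traj([ref] * 4), ref)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_linear_morph_gives_increasing_series(self, rng):
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=2.0, size=(6, 3))
        frames = [(1 - t) * a + t * b for t in np.linspace(0, 1, 11)]
        series = rmsd_timeseries(_traj(frames), a)
        assert np.all(np.diff(series.values) > 0)


class TestHelixAngle:
    def test_beads_along_z_have_zero_tilt(self):
        coords = np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)])
        coords[:, 0] += 1e-3 * np.arange(5)  # break exact degeneracy
        assert helix_angle(Frame(coords), np.arange(5)) < 0.1

    def test_beads_along_x_are_90_degrees(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        coords[:, 1] += 1e-3 * np.arange(5)
        assert helix_angle(Frame(coords), np.arange(5)) > 89.9

    def test_30_degree_rod(self):
        axis = np.array([np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))])
        coords = np.outer(np.arange(6.0), axis)
        got = helix_angle(Frame(coords), np.arange(6))
        assert got == pytest.approx(30.0, abs=1e-6)

    def test_isotropic_cloud_rejected(self):
        coords = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
             [0, 0, -1]],
            dtype=float,
        )
        with pytest.raises(DegenerateGeometryError):
            helix_angle(Frame(coords), np.arange(6))


class TestContacts:
    def test_fixed_distance_contact_flag(self):
        a = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        traj = _traj([a] * 5)
        on = contact_series(traj, [0], [1], cutoff=4.5)
        off = contact_series(traj, [0], [1], cutoff=2.0)
        assert on.events["in_contact"].all()
        assert not off.events["in_contact"].any()

    def test_min_distance_matches_brute_force(self, rng):
        frames = rng.normal(scale=4.0, size=(6, 10, 3))
        traj = _traj(list(frames))
        sel_a, sel_b = np.arange(4), np.arange(4, 10)
        series = contact_series(traj, sel_a, sel_b, cutoff=3.0)
        for f, got in zip(frames, series.values):
            expected = cdist(f[sel_a], f[sel_b]).min()
            assert got == pytest.approx(expected)

    def test_fraction_pairs_mode(self):
        a = np.array([[0.0, 0, 0], [10.0, 0, 0], [0.0, 2, 0], [10, 2, 0]])
        traj = _traj([a])
        series = contact_series(traj, [0, 1], [2, 3], cutoff=3.0,
                                mode="fraction_pairs")
        assert series.values[0] == pytest.approx(0.5)

    def test_overlapping_selections_rejected(self):
        traj = _traj([np.zeros((4, 3))])
        with pytest.raises(ValueError, match="disjoint"):
            contact_series(traj, [0, 1], [1, 2], cutoff=3.0)


class TestSaltBridge:
    def test_single_crossing_gives_one_form_event(self):
        frames = [
            np.array([[0.0, 0, 0], [d, 0, 0]])
            for d in [6.0, 5.0, 3.5, 3.0, 3.2]
        ]
        series = saltbridge_series(_traj(frames), [0], [1], cutoff=4.0)
        assert list(series.events["form_events"]) == [2]
        assert list(series.events["break_events"]) == []

    def test_hysteresis_suppresses_flicker(self):
        # distance oscillates inside [cutoff, cutoff+margin): no breaks
        ds = [3.0, 4.2, 3.9, 4.3, 3.8, 4.4]
        frames = [np.array([[0.0, 0, 0], [d, 0, 0]]) for d in ds]
        series = saltbridge_series(_traj(frames), [0], [1], cutoff=4.0,
                                   margin=0.5)
        assert series.events["formed"].all()
        assert len(series.events["break_events"]) == 0

    def test_symmetric_in_selections(self, rng):
        frames = list(rng.normal(scale=3.0, size=(5, 6, 3)))
        a = saltbridge_series(_traj(frames), [0, 1], [4, 5]).values
        b = saltbridge_series(_traj(frames), [4, 5], [0, 1]).values
        np.testing.assert_array_equal(a, b)


class TestHBond:
    def test_distance_criterion(self):
        near = _traj([np.array([[0.0, 0, 0], [2.8, 0, 0]])])
        far = _traj([np.array([[0.0, 0, 0], [5.0, 0, 0]])])
        assert hbond_series(near, [0], [1]).events["bonded"].all()
        assert not hbond_series(far, [0], [1]).events["bonded"].any()

    def test_fraction_bonded_counts_frames(self):
        ds = [2.0, 2.5, 5.0, 3.0, 6.0, 7.0, 2.9, 8.0, 9.0, 10.0]
        frames = [np.array([[0.0, 0, 0], [d, 0, 0]]) for d in ds]
        series = hbond_series(_traj(frames), [0], [1], d_cut=3.5)
        assert series.events["fraction_bonded"] == pytest.approx(0.4)


class TestOccupancyGrid:
    def test_static_particle_fills_exactly_one_voxel(self):
        frames = [np.array([[0.25, 0.25, 0.25]])] * 6
        grid = occupancy_grid(_traj(frames), [0], spacing=1.0,
                              origin=np.zeros(3), dims=(2, 2, 2))
        assert grid.values[0, 0, 0] == 1.0
        assert grid.values.sum() == 1.0

    def test_partial_occupancy_is_exact_rational(self):
        inside = np.array([[0.5, 0.5, 0.5]])
        outside = np.array([[5.5, 0.5, 0.5]])
        frames = [inside] * 4 + [outside] * 6
        grid = occupancy_grid(_traj(frames), [0], spacing=1.0,
                              origin=np.zeros(3), dims=(6, 1, 1))
        assert grid.values[0, 0, 0] == pytest.approx(0.4)
        assert grid.threshold_mask(0.3)[0, 0, 0]

    def test_trailing_window(self):
        inside = np.array([[0.5, 0.5, 0.5]])
        outside = np.array([[3.5, 0.5, 0.5]])
        frames = [outside] * 5 + [inside] * 5
        grid = occupancy_grid(_traj(frames), [0], spacing=1.0, window=5,
                              origin=np.zeros(3), dims=(4, 1, 1))
        assert grid.values[0, 0, 0] == 1.0

    def test_half_open_voxel_membership(self):
        # a particle exactly on a voxel face counts in the upper voxel only
        frames = [np.array([[1.0, 0.5, 0.5]])]
        grid = occupancy_grid(_traj(frames), [0], spacing=1.0,
                              origin=np.zeros(3), dims=(2, 1, 1))
        assert grid.values[1, 0, 0] == 1.0
        assert grid.values[0, 0, 0] == 0.0

    def test_dx_export(self, tmp_path):
        frames = [np.array([[0.5, 0.5, 0.5]])]
        grid = occupancy_grid(_traj(frames), [0], spacing=1.0,
                              origin=np.zeros(3), dims=(2, 2, 2))
        path = tmp_path / "g.dx"
        grid.write_dx(path)
        assert "gridpositions counts 2 2 2" in path.read_text()


class TestCountInRegion:
    def test_static_tracers_in_slab(self):
        coords = np.array([[0, 0, z] for z in [1.0, 2.0, 3.0, 9.0, -5.0]])
        traj = _traj([coords] * 3)
        series = count_in_region(traj, None,
                                 {"kind": "z_slab", "z_min": 0, "z_max": 4})
        np.testing.assert_array_equal(series.values, [3, 3, 3])

    def test_empty_selection_counts_zero(self):
        traj = _traj([np.zeros((3, 3))])
        series = count_in_region(traj, [],
                                 {"kind": "sphere", "center": (0, 0, 0),
                                  "radius": 1.0})
        assert series.values[0] == 0

    def test_matches_brute_force_point_test(self, rng):
        frames = list(rng.normal(scale=5.0, size=(4, 20, 3)))
        region = {"kind": "sphere", "center": (1.0, -1.0, 0.5), "radius": 4.0}
        series = count_in_region(_traj(frames), None, region)
        c = np.array(region["center"])
        for f, got in zip(frames, series.values):
            assert got == int(
                (np.linalg.norm(f - c, axis=1) < region["radius"]).sum()
            )


class TestGateRg:
    def test_symmetric_ring_rg_equals_radius(self):
        r = 7.0
        angles = np.radians([0, 120, 240])
        coords = np.column_stack(
            [r * np.cos(angles), r * np.sin(angles), np.full(3, 2.0)]
        )
        assert gate_rg(Frame(coords), [0, 1, 2]) == pytest.approx(r)

    def test_homogeneous_scaling(self, rng):
        coords = rng.normal(size=(5, 3))
        r1 = gate_rg(Frame(coords), np.arange(5))
        r2 = gate_rg(Frame(2.0 * coords), np.arange(5))
        assert r2 == pytest.approx(2.0 * r1)

    def test_axis_projection_drops_z_spread(self):
        coords = np.array(
            [[3.0, 0, -5.0], [-3.0, 0, 5.0], [0, 3.0, 0.0], [0, -3.0, 0.0]]
        )
        full = gate_rg(Frame(coords), np.arange(4))
        proj = gate_rg(Frame(coords), np.arange(4), axis_projection=True)
        assert proj == pytest.approx(3.0)
        assert full > proj

    def test_single_site_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            gate_rg(Frame(np.zeros((2, 3))), [0])


class TestRMSF:
    def test_static_trajectory_is_zero(self, rng):
        frame = rng.normal(size=(5, 3))
        values = rmsf(_traj([frame] * 6))
        np.testing.assert_allclose(values, 0.0, atol=1e-12)

    def test_invariant_under_global_rigid_motion(self, rng):
        frames = list(rng.normal(size=(8, 5, 3)) * 0.3 + rng.normal(size=(5, 3)))
        base = rmsf(_traj(frames))
        moved = []
        for t, f in enumerate(frames):
            rot = Rotation.from_euler("z", 20 * t, degrees=True).as_matrix()
            moved.append(f @ rot.T + np.array([t, -t, 0.5 * t]))
        shifted = rmsf(_traj(moved))
        np.testing.assert_allclose(shifted, base, atol=1e-6)


class TestRigidMotionInvariance:
    def test_distance_metrics_unchanged_by_uniform_rigid_motion(self, rng):
        frames = list(rng.normal(scale=4.0, size=(5, 8, 3)))
        rot = Rotation.from_euler("xyz", [10, -30, 55], degrees=True).as_matrix()
        moved = [f @ rot.T + np.array([2.0, -1.0, 3.0]) for f in frames]
        for sel_a, sel_b in [([0, 1], [4, 5])]:
            a = contact_series(_traj(frames), sel_a, sel_b, cutoff=3.0).values
            b = contact_series(_traj(moved), sel_a, sel_b, cutoff=3.0).values
            np.testing.assert_allclose(a, b, atol=1e-9)
        ga = [gate_rg(Frame(f), np.arange(4)) for f in frames]
        gb = [gate_rg(Frame(f), np.arange(4)) for f in moved]
        np.testing.assert_allclose(ga, gb, atol=1e-9)
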