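"""Perturbation designers, the LRPF cycle, and staged pipelines."""

import numpy as np
import pytest

from lrpath.engine import LangevinParams, run_langevin
from lrpath.forces import PairDistanceCoordinate
from lrpath.protocol import (
    LRPFConfig,
    LRPFState,
    MonitorSpec,
    design_outward_push,
    design_pair_contraction,
    run_lrpf,
    run_stage_sequence,
)
from lrpath.toy import rotation_z


class TestOutwardPush:
    def test_equilateral_triangle_forces_sum_to_zero_and_point_outward(self):
        angles = np.radians([90, 210, 330])
        coords = np.column_stack(
            [np.cos(angles), np.sin(angles), np.zeros(3)]
        )
        pset = design_outward_push(coords, [0, 1, 2], magnitude=2.0)
        forces = np.array([v for _, v in pset.entries])
        np.testing.assert_allclose(forces.sum(axis=0), 0.0, atol=1e-12)
        for p, f in zip(coords, forces):
            radial = p / np.linalg.norm(p)
            assert f @ radial == pytest.approx(2.0)

    def test_threefold_symmetric_sites_give_threefold_forces(self):
        angles = np.radians([0, 120, 240])
        coords = np.column_stack(
            [3 * np.cos(angles), 3 * np.sin(angles), np.full(3, -5.0)]
        )
        pset = design_outward_push(coords, [0, 1, 2], magnitude=1.0)
        forces = np.array([v for _, v in pset.entries])
        rot = rotation_z(2 * np.pi / 3)
        # rotating the force on site i gives the force on the next site
        np.testing.assert_allclose(forces[0] @ rot.T, forces[1], atol=1e-9)
        np.testing.assert_allclose(forces[1] @ rot.T, forces[2], atol=1e-9)

    def test_two_collinear_sites_push_apart_along_x(self):
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        pset = design_outward_push(coords, [0, 1], magnitude=1.5, axis=(0, 0, 1))
        forces = dict((i, v) for i, v in pset.entries)
        np.testing.assert_allclose(forces[0], [1.5, 0, 0], atol=1e-12)
        np.testing.assert_allclose(forces[1], [-1.5, 0, 0], atol=1e-12)

    def test_site_at_centroid_rejected(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 1.0], [0.0, 0, -1.0]])
        with pytest.raises(ValueError, match="centroid"):
            design_outward_push(coords, [0, 1, 2], magnitude=1.0)


class TestPairContraction:
    def test_single_pair_net_force_and_torque_vanish(self):
        coords = np.array([[0.0, 0, 0], [4.0, 2.0, 1.0]])
        pset = design_pair_contraction(coords, [(0, 1)], magnitude=2.0)
        forces = {i: v for i, v in pset.entries}
        np.testing.assert_allclose(forces[0] + forces[1], 0.0, atol=1e-12)
        torque = np.cross(coords[0], forces[0]) + np.cross(coords[1], forces[1])
        np.testing.assert_allclose(torque, 0.0, atol=1e-12)
        # directed to shrink the distance
        d = coords[1] - coords[0]
        assert forces[0] @ d > 0 and forces[1] @ d < 0

    def test_overdamped_pair_distance_strictly_decreases(self):
        """1D overdamped integration oracle: x' = f / gamma."""
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        magnitude, gamma, dt = 1.0, 2.0, 0.01
        x = coords.copy()
        distances = [5.0]
        for _ in range(200):
            pset = design_pair_contraction(x, [(0, 1)], magnitude)
            f = np.zeros_like(x)
            for i, v in pset.entries:
                f[i] = v
            x = x + dt * f / gamma
            distances.append(float(np.linalg.norm(x[1] - x[0])))
        assert all(b < a for a, b in zip(distances, distances[1:]))

    def test_shared_site_contributions_sum(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 3.0, 0]])
        pset = design_pair_contraction(coords, [(0, 1), (0, 2)], magnitude=1.0)
        forces = {i: v for i, v in pset.entries}
        np.testing.assert_allclose(forces[0], [1.0, 1.0, 0.0], atol=1e-12)

    def test_degenerate_pair_rejected(self):
        coords = np.zeros((2, 3))
        with pytest.raises(ValueError, match="degenerate"):
            design_pair_contraction(coords, [(0, 1)], magnitude=1.0)


def tiny_benchmark(reference_pair, double_basin, seed=1, **overrides):
    cfg = dict(
        perturbation_design="outward_push",
        sites="tag:acidic",
        magnitude=1.0,
        biased_steps=200,
        unbiased_steps=200,
        f_max=0.5,
        max_cycles=2,
        seed=seed,
        covariance_stride=5,
        monitors=[
            MonitorSpec(
                name="rmsd_to_if",
                reference=reference_pair.if_state.coords,
                threshold=1.5,
            )
        ],
    )
    cfg.update(overrides)
    config = LRPFConfig(**cfg)
    state = LRPFState(
        reference_pair.of_state.coords.copy(), None, 0,
        reference_pair.topology, stage=f"tiny{seed}",
    )
    params = LangevinParams(
        temperature=1.0, friction=1.0, dt=0.02, n_steps=1, seed=seed,
        save_stride=10,
    )
    return state, config, params


class TestRunLRPF:
    def test_max_cycles_one_gives_one_record(self, reference_pair, double_basin):
        state, config, params = tiny_benchmark(
            reference_pair, double_basin, max_cycles=1
        )
        result = run_lrpf(state, config, double_basin.terms, params)
        assert len(result.records) == 1
        assert result.termination in ("exhausted", "monitor:rmsd_to_if")

    def test_records_carry_every_configured_monitor(
        self, reference_pair, double_basin
    ):
        state, config, params = tiny_benchmark(reference_pair, double_basin)
        result = run_lrpf(state, config, double_basin.terms, params)
        for record in result.records:
            assert "rmsd_to_if" in record.monitors
            assert set(record.domain_displacement) == {"I", "II", "III"}
            assert np.isfinite(record.asymmetry)

    def test_replay_reproduces_monitor_series(self, reference_pair, double_basin):
        state, config, params = tiny_benchmark(reference_pair, double_basin)
        a = run_lrpf(state, config, double_basin.terms, params)
        state2, config2, params2 = tiny_benchmark(reference_pair, double_basin)
        b = run_lrpf(state2, config2, double_basin.terms, params2)
        sa = [r.monitors["rmsd_to_if"] for r in a.records]
        sb = [r.monitors["rmsd_to_if"] for r in b.records]
        assert sa == sb

    def test_null_bias_is_bit_identical_to_unbiased(
        self, reference_pair, double_basin
    ):
        """f_max = 0 reproduces one continuous unbiased run frame-for-frame."""
        state, config, params = tiny_benchmark(
            reference_pair, double_basin, f_max=0.0, max_cycles=2,
            covariance_stride=10,
        )
        result = run_lrpf(state, config, double_basin.terms, params)
        total = config.unbiased_steps + config.max_cycles * (
            config.biased_steps + config.unbiased_steps
        )
        plain = run_langevin(
            reference_pair.of_state.coords,
            double_basin.terms,
            params.replace(n_steps=total, seed=config.seed),
            topology=reference_pair.topology,
            stage=state.stage,
        )
        np.testing.assert_array_equal(
            result.final_state.coords, plain.final_coords
        )
        # frame times of the concatenated run are a superset; compare the
        # frames both saved
        times_a = {f.time: f for f in result.trajectory.frames}
        shared = [
            (f, times_a[f.time]) for f in plain.trajectory.frames
            if f.time in times_a
        ]
        assert len(shared) > 10
        for pf, lf in shared:
            np.testing.assert_array_equal(pf.coords, lf.coords)

    def test_bias_moves_mean_structure_toward_if(
        self, reference_pair, double_basin
    ):
        """After a couple of biased cycles the mean structure has advanced
        along the OF->IF direction, unlike a null-bias control."""
        of = reference_pair.of_state.coords
        if_ = reference_pair.if_state.coords
        direction = (if_ - of).ravel()
        direction /= np.linalg.norm(direction)

        def progress(result):
            return float(
                (result.records[-1].mean_structure - of).ravel() @ direction
            )

        state, config, params = tiny_benchmark(
            reference_pair, double_basin, seed=5, max_cycles=2,
            biased_steps=600, unbiased_steps=600, f_max=2.0,
        )
        biased = progress(run_lrpf(state, config, double_basin.terms, params))
        state2, config2, params2 = tiny_benchmark(
            reference_pair, double_basin, seed=5, max_cycles=2,
            biased_steps=600, unbiased_steps=600, f_max=0.0,
        )
        control = progress(
            run_lrpf(state2, config2, double_basin.terms, params2)
        )
        assert biased > control + 0.5


class TestMonitors:
    def test_comparator_directions(self):
        m_lt = MonitorSpec(name="m", threshold=1.0, comparator="<")
        m_gt = MonitorSpec(name="m", threshold=1.0, comparator=">")
        assert m_lt.fired([2.0, 0.5])
        assert not m_lt.fired([2.0])
        assert m_gt.fired([2.0])

    def test_plateau_fires_on_flat_series(self):
        m = MonitorSpec(name="p", kind="plateau", threshold=0.01, window=5,
                        source="m")
        assert m.fired([3.0, 3.001, 2.999, 3.0, 3.0])
        assert not m.fired([1.0, 2.0, 3.0, 4.0, 5.0])
        assert not m.fired([3.0, 3.0])  # window not yet filled


class TestStageSequence:
    def test_empty_stage_list_runs_nothing(self, reference_pair):
        state = LRPFState(
            reference_pair.of_state.coords.copy(), None, 0,
            reference_pair.topology, stage="empty",
        )
        params = LangevinParams(n_steps=1, seed=0)
        reports, final, traj = run_stage_sequence(state, [], [], params)
        assert reports == []
        assert traj.n_frames == 0
        np.testing.assert_array_equal(final.coords, state.coords)

    def test_unknown_stage_kind_rejected_before_any_run(self, reference_pair):
        state = LRPFState(
            reference_pair.of_state.coords.copy(), None, 0,
            reference_pair.topology, stage="bad",
        )
        params = LangevinParams(n_steps=1, seed=0)
        with pytest.raises(ValueError, match="unknown stage kind"):
            run_stage_sequence(
                state,
                [{"kind": "unbiased", "n_steps": 10}, {"kind": "wrong"}],
                [],
                params,
            )

    def test_stages_chain_on_final_coordinates(
        self, reference_pair, double_basin
    ):
        state = LRPFState(
            reference_pair.of_state.coords.copy(), None, 0,
            reference_pair.topology, stage="chain",
        )
        params = LangevinParams(
            temperature=1.0, friction=1.0, dt=0.02, n_steps=1, seed=2,
            save_stride=20,
        )
        stages = [
            {"kind": "unbiased", "name": "relax1", "n_steps": 200},
            {"kind": "targeted", "name": "pull_to_if", "n_steps": 300,
             "target": reference_pair.if_state.coords, "k_t": 20.0},
            {"kind": "steered", "name": "drag", "n_steps": 200,
             "coordinate": PairDistanceCoordinate(0, 8), "k_pull": 5.0,
             "velocity": 0.01},
        ]
        reports, final, traj = run_stage_sequence(
            state, stages, double_basin.terms, params
        )
        assert [r.name for r in reports] == ["relax1", "pull_to_if", "drag"]
        for prev, nxt in zip(reports, reports[1:]):
            np.testing.assert_array_equal(prev.end_coords, nxt.start_coords)
        assert reports[-1].work is not None
        np.testing.assert_array_equal(reports[-1].end_coords, final.coords)
        assert traj.n_frames > 0

    def test_targeted_stage_moves_toward_target(
        self, reference_pair, double_basin
    ):
        from lrpath.metrics import rmsd

        state = LRPFState(
            reference_pair.of_state.coords.copy(), None, 0,
            reference_pair.topology, stage="tmd",
        )
        params = LangevinParams(
            temperature=0.5, friction=1.0, dt=0.02, n_steps=1, seed=3,
            save_stride=50,
        )
        stages = [
            {"kind": "targeted", "n_steps": 2000,
             "target": reference_pair.if_state.coords, "k_t": 200.0},
        ]
        reports, final, _ = run_stage_sequence(
            state, stages, double_basin.terms, params
        )
        before = rmsd(state.coords, reference_pair.if_state.coords)
        after = rmsd(final.coords, reference_pair.if_state.coords)
        assert after < 0.5 * before


class TestCanonicalDemo:
    def test_demo_pipeline_ends_stably_in_if_basin(
        self, reference_pair, double_basin
    ):
        """The staged demo (matrix-opening LRPF, cytoplasmic-closing LRPF,
        relaxation, steered drag, apo relaxation) finishes with the apo
        stage resident in the IF basin."""
        from lrpath.benchmark import canonical_demo_stages, benchmark_params
        from lrpath.metrics import rmsd, superpose_frames

        stages = canonical_demo_stages(reference_pair)
        state = LRPFState(
            reference_pair.of_state.coords.copy(), None, 0,
            reference_pair.topology, stage="demo",
        )
        params = benchmark_params(reference_pair.spec, seed=3)
        reports, final, traj = run_stage_sequence(
            state, stages, double_basin.terms, params
        )
        assert [r.name for r in reports] == [
            "open_matrix", "close_cytoplasm", "relax", "expel", "apo",
        ]
        assert reports[0].termination.startswith("monitor")
        # the whole apo stage stays within the IF threshold
        apo_start = reports[-1].step_range[0]
        apo_frames = [f for f in traj.frames
                      if f.time >= apo_start * params.dt]
        coords = np.array([f.coords for f in apo_frames])
        mean = superpose_frames(coords).mean(axis=0)
        assert rmsd(mean, reference_pair.if_state.coords) < 1.5
        half = coords[: len(coords) // 2]
        mean_early = superpose_frames(half).mean(axis=0)
        assert rmsd(mean_early, reference_pair.if_state.coords) < 1.5


class TestCovarianceRoundtrip:
    def test_save_load_roundtrip(self, tmp_path, reference_pair, double_basin):
        from lrpath.engine import LangevinParams, run_langevin
        from lrpath.response import CovarianceModel, estimate_covariance

        params = LangevinParams(
            temperature=1.0, friction=1.0, dt=0.02, n_steps=400, seed=1,
            save_stride=10,
        )
        res = run_langevin(
            reference_pair.of_state.coords, double_basin.terms, params,
            topology=reference_pair.topology, stage="cov",
        )
        model = estimate_covariance(res.trajectory, temperature=1.0)
        model.save(tmp_path / "model")
        again = CovarianceModel.load(tmp_path / "model")
        np.testing.assert_array_equal(model.covariance, again.covariance)
        np.testing.assert_array_equal(model.mean_coords, again.mean_coords)
        assert again.shrinkage == model.shrinkage
        assert again.n_frames == model.n_frames
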