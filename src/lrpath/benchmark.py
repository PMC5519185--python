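"""The canonical desk-scale LRPF benchmark.

A 12 kT double-basin toy transporter where unbiased Langevin runs stay in
the outward-facing basin for the whole benchmark length, while LRPF runs
— biased by the linear response to an outward push on the three acidic
matrix-motif beads — reach the inward-facing basin within a handful of
bias-update cycles.  Success and residence are judged on unbiased-segment
mean structures (trailing-window means for plain runs) against the 1.5
model-unit RMSD thresholds.

Problem sizes (48 protein beads, 1500-step segments, 10 seeds) are chosen
so the full benchmark runs in minutes on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import LangevinParams, run_langevin
from .metrics import rmsd, superpose_frames
from .protocol import LRPFConfig, LRPFState, MonitorSpec, run_lrpf
from .toy import (
    DoubleBasinModel,
    ReferencePair,
    ToyTransporterSpec,
    build_double_basin_spec,
    build_reference_states,
)

#: Success / residence threshold on superposed RMSD (model units).
RMSD_THRESHOLD = 1.5
#: LRPF cycle budget.
MAX_CYCLES = 40
BIASED_STEPS = 1500
UNBIASED_STEPS = 1500
F_MAX = 1.0


def benchmark_system(
    spec: ToyTransporterSpec | None = None,
) -> tuple[ReferencePair, DoubleBasinModel]:
    """The default toy and its calibrated 12 kT landscape."""
    spec = spec or ToyTransporterSpec()
    ref = build_reference_states(spec)
    return ref, build_double_basin_spec(ref)


def benchmark_params(spec: ToyTransporterSpec, seed: int = 0) -> LangevinParams:
    return LangevinParams(
        temperature=spec.temperature,
        friction=1.0,
        dt=0.02,
        n_steps=1,
        seed=seed,
        save_stride=50,
    )


def benchmark_config(ref: ReferencePair, seed: int) -> LRPFConfig:
    return LRPFConfig(
        perturbation_design="outward_push",
        sites="tag:acidic",
        magnitude=1.0,
        biased_steps=BIASED_STEPS,
        unbiased_steps=UNBIASED_STEPS,
        f_max=F_MAX,
        max_cycles=MAX_CYCLES,
        seed=seed,
        monitors=[
            MonitorSpec(
                name="rmsd_to_if",
                kind="rmsd_to_ref",
                reference=ref.if_state.coords,
                comparator="<",
                threshold=RMSD_THRESHOLD,
                persistence=2,
            )
        ],
    )


def trailing_mean_structure(result, n_frames: int = 40) -> np.ndarray:
    coords = np.array(
        [f.coords for f in result.trajectory.frames[-n_frames:]]
    )
    return superpose_frames(coords).mean(axis=0)


@dataclass
class TransitionBenchmark:
    """Outcome of the paired LRPF / unbiased seed sweep."""

    lrpf_success: int
    n_seeds: int
    cycles_used: list[int]
    unbiased_stayed: int
    unbiased_rmsd_of: list[float]
    final_states: list = field(default_factory=list)
    asymmetries: list[float] = field(default_factory=list)


def run_transition_benchmark(
    base_seed: int = 1,
    n_seeds: int = 10,
    spec: ToyTransporterSpec | None = None,
) -> TransitionBenchmark:
    """LRPF vs unbiased on the default toy, ``n_seeds`` paired runs.

    The unbiased control for each seed gets the same total step count the
    LRPF run consumed (bootstrap plus all biased+unbiased segments).
    """
    ref, db = benchmark_system(spec)
    spec = ref.spec
    success = 0
    cycles: list[int] = []
    finals = []
    asyms: list[float] = []
    for k in range(n_seeds):
        seed = base_seed + k
        cfg = benchmark_config(ref, seed)
        state = LRPFState(
            ref.of_state.coords.copy(), None, 0, ref.topology,
            stage=f"lrpf{seed}",
        )
        result = run_lrpf(state, cfg, db.terms, benchmark_params(spec, seed))
        ok = result.termination.startswith("monitor")
        success += ok
        cycles.append(len(result.records))
        finals.append(result.final_state)
        if result.records:
            asyms.append(
                float(np.nanmax([r.asymmetry for r in result.records]))
            )
    stayed = 0
    rmsds: list[float] = []
    for k, nc in enumerate(cycles):
        seed = base_seed + k
        total = UNBIASED_STEPS + nc * (BIASED_STEPS + UNBIASED_STEPS)
        params = benchmark_params(spec, seed).replace(n_steps=total, seed=seed)
        res = run_langevin(
            ref.of_state.coords, db.terms, params,
            topology=ref.topology, stage=f"unbiased{seed}",
        )
        r = rmsd(trailing_mean_structure(res), ref.of_state.coords)
        rmsds.append(r)
        stayed += r < RMSD_THRESHOLD
    return TransitionBenchmark(
        lrpf_success=success,
        n_seeds=n_seeds,
        cycles_used=cycles,
        unbiased_stayed=stayed,
        unbiased_rmsd_of=rmsds,
        final_states=finals,
        asymmetries=asyms,
    )


@dataclass
class StabilityBenchmark:
    stayed: int
    n_seeds: int
    rmsd_if: list[float]


def run_stability_benchmark(
    bench: TransitionBenchmark,
    base_seed: int = 1,
    spec: ToyTransporterSpec | None = None,
    duration_factor: int = 10,
) -> StabilityBenchmark:
    """Continue each successful LRPF endpoint unbiased for
    ``duration_factor`` times the biased duration it consumed; count runs
    whose trailing mean structure stays within the IF threshold."""
    ref, db = benchmark_system(spec)
    spec = ref.spec
    stayed = 0
    rmsds: list[float] = []
    n = 0
    for k, (state, nc) in enumerate(zip(bench.final_states, bench.cycles_used)):
        seed = base_seed + k
        duration = duration_factor * nc * BIASED_STEPS
        params = benchmark_params(spec, seed).replace(
            n_steps=duration, seed=seed, save_stride=100
        )
        res = run_langevin(
            state.coords, db.terms, params,
            velocities=state.velocities,
            topology=ref.topology,
            stage=state.stage,
            step_offset=state.step,
        )
        r = rmsd(trailing_mean_structure(res), ref.if_state.coords)
        rmsds.append(r)
        stayed += r < RMSD_THRESHOLD
        n += 1
    return StabilityBenchmark(stayed=stayed, n_seeds=n, rmsd_if=rmsds)


def canonical_demo_stages(ref: ReferencePair) -> list[dict]:
    """The canonical staged pipeline on the toy.

    Matrix-opening LRPF (outward push on the acidic motif beads), then a
    cytoplasmic-closing LRPF (contraction of the inter-domain cytoplasmic
    gate pairs), a long unbiased relaxation, a steered drag of the first
    matrix bead pair (a stand-in for substrate expulsion), and a final
    apo relaxation.
    """
    from .forces import PairDistanceCoordinate
    from .topology import select

    gate = ref.topology.indices_with_tag("gate_cyt")
    lrpf_open = benchmark_config(ref, seed=0)
    lrpf_close = LRPFConfig(
        perturbation_design="pair_contraction",
        pairs=[("tag:gate_cyt and domain:I", "tag:gate_cyt and domain:II"),
               ("tag:gate_cyt and domain:II", "tag:gate_cyt and domain:III"),
               ("tag:gate_cyt and domain:III", "tag:gate_cyt and domain:I")],
        magnitude=1.0,
        biased_steps=BIASED_STEPS,
        unbiased_steps=UNBIASED_STEPS,
        f_max=F_MAX,
        max_cycles=10,
        seed=0,
        monitors=[
            MonitorSpec(
                name="gate_rg_cyt",
                kind="gate_rg",
                selection="tag:gate_cyt",
                comparator="<",
                threshold=10.0,
            )
        ],
    )
    acidic = ref.topology.indices_with_tag("acidic")
    return [
        {"kind": "lrpf", "name": "open_matrix", "config": lrpf_open},
        {"kind": "lrpf", "name": "close_cytoplasm", "config": lrpf_close},
        {"kind": "unbiased", "name": "relax", "n_steps": 4000},
        {"kind": "steered", "name": "expel", "n_steps": 2000,
         "coordinate": PairDistanceCoordinate(int(acidic[0]), int(acidic[1])),
         "k_pull": 2.0, "velocity": 0.005},
        {"kind": "unbiased", "name": "apo", "n_steps": 6000},
    ]
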