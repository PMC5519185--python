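"""The LRPF cycle: perturbation design, bias update, staged pipelines.

One LRPF cycle runs a biased segment (constant bias field on every
protein site), then an unbiased relaxation segment; the covariance and
mean structure of the relaxation segment give, through linear response,
the next cycle's bias field.  Perturbation *sites* keep their identity
(tags) across cycles while their force *directions* are refreshed from
each new mean structure, so the bias follows the evolving, nonlinear
transition path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import LangevinParams, LangevinResult, run_langevin
from .forces import ConstantForceTerm, ForceTerm
from .metrics import rmsd, superpose_frames
from .response import (
    BiasField,
    CovarianceModel,
    PerturbationSet,
    build_bias,
    estimate_covariance,
    predict_response,
)
from .topology import SiteModel, resolve_selection
from .trajectory import Trajectory


# ---------------------------------------------------------------------------
# Perturbation designers
# ---------------------------------------------------------------------------


def design_outward_push(
    mean_coords: np.ndarray,
    sites: Sequence[int] | np.ndarray,
    magnitude: float,
    axis=(0.0, 0.0, 1.0),
    label: str = "outward_push",
) -> PerturbationSet:
    """Radially outward forces at the given sites.

    Each site gets ``magnitude`` times the unit vector from the sites'
    centroid to the site, projected onto the plane normal to ``axis`` and
    renormalized — the "push the acidic motif residues outward" design
    that opens the matrix side of the channel.
    """
    sites = np.asarray(sites, dtype=int)
    if len(sites) < 2:
        raise ValueError("outward push needs >= 2 sites")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    pts = mean_coords[sites]
    centroid = pts.mean(axis=0)
    entries = []
    for s, p in zip(sites, pts):
        d = p - centroid
        d = d - (d @ ax) * ax
        n = np.linalg.norm(d)
        if n < 1e-10:
            raise ValueError(
                f"site {s} coincides with the centroid in the push plane"
            )
        entries.append((int(s), magnitude * d / n))
    return PerturbationSet(entries, label=label)


def design_pair_contraction(
    mean_coords: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    magnitude: float,
    label: str = "pair_contraction",
) -> PerturbationSet:
    """Equal and opposite forces pulling each site pair together.

    The design that closes the cytoplasmic side: forces of the given
    magnitude along each pair's connecting unit vector, oriented to
    shrink the distance; contributions on shared sites are summed.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    acc: dict[int, np.ndarray] = {}
    for i, j in pairs:
        d = mean_coords[j] - mean_coords[i]
        n = np.linalg.norm(d)
        if n < 1e-10:
            raise ValueError(f"degenerate pair ({i}, {j}): zero separation")
        u = d / n
        acc[i] = acc.get(i, np.zeros(3)) + magnitude * u
        acc[j] = acc.get(j, np.zeros(3)) - magnitude * u
    return PerturbationSet(
        [(s, v) for s, v in sorted(acc.items())], label=label
    )


# ---------------------------------------------------------------------------
# Configuration and records
# ---------------------------------------------------------------------------


@dataclass
class MonitorSpec:
    """Declarative convergence monitor evaluated on each cycle's
    unbiased-segment mean structure.

    kinds: ``rmsd_to_ref`` (needs ``reference``), ``gate_rg`` (needs
    ``selection``), ``plateau`` (fires when the least-squares slope of
    ``source`` monitor values over the trailing ``window`` cycles falls
    below ``threshold`` in magnitude).

    Threshold monitors fire only once the condition has held for
    ``persistence`` consecutive cycles: a single cycle whose mean
    structure dips under an RMSD threshold can still straddle the basin
    seam, and demanding persistence makes the basin call a confirmed
    residence rather than a grazing contact.
    """

    name: str
    kind: str = "rmsd_to_ref"
    reference: np.ndarray | None = None
    selection: str | np.ndarray | None = None
    comparator: str = "<"
    threshold: float = 0.0
    window: int = 5
    persistence: int = 1
    source: str | None = None
    fire: bool = True  # whether firing terminates the run

    def evaluate(self, mean_coords: np.ndarray, topology: SiteModel) -> float:
        if self.kind == "rmsd_to_ref":
            idx = resolve_selection(topology, self.selection)
            ref = self.reference
            ref_sel = ref[idx] if ref.shape[0] == topology.n_sites else ref
            return rmsd(mean_coords[idx], ref_sel)
        if self.kind == "gate_rg":
            from .metrics import gate_rg

            idx = resolve_selection(topology, self.selection)
            return gate_rg(mean_coords, idx)
        raise ValueError(f"unknown monitor kind {self.kind!r}")

    def fired(self, history: list[float]) -> bool:
        if not history:
            return False
        if self.kind == "plateau":
            if len(history) < self.window:
                return False
            y = np.asarray(history[-self.window :])
            x = np.arange(len(y), dtype=float)
            slope = np.polyfit(x, y, 1)[0]
            return bool(abs(slope) < self.threshold)
        if len(history) < self.persistence:
            return False
        recent = history[-self.persistence:]
        if self.comparator == "<":
            return bool(all(v < self.threshold for v in recent))
        if self.comparator == ">":
            return bool(all(v > self.threshold for v in recent))
        raise ValueError(f"unknown comparator {self.comparator!r}")


@dataclass
class LRPFConfig:
    """Per-simulation LRPF protocol parameters."""

    perturbation_design: str = "outward_push"  # or "pair_contraction"
    sites: str | np.ndarray | None = "tag:acidic"
    pairs: list[tuple] | None = None  # selection pairs for contraction
    magnitude: float = 1.0
    biased_steps: int = 1500
    unbiased_steps: int = 1500
    f_max: float = 1.0
    max_cycles: int = 40
    monitors: list[MonitorSpec] = field(default_factory=list)
    seed: int = 0
    shrinkage: float = 0.05
    superpose: bool = True
    covariance_stride: int = 5

    def __post_init__(self) -> None:
        if self.biased_steps < 1 or self.unbiased_steps < 1:
            raise ValueError("segment lengths must be >= 1")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if self.f_max < 0:
            raise ValueError("f_max must be >= 0")
        if self.perturbation_design not in ("outward_push", "pair_contraction"):
            raise ValueError(
                f"unknown perturbation design {self.perturbation_design!r}"
            )


@dataclass
class CycleRecord:
    """Append-only log entry for one LRPF cycle."""

    cycle: int
    mean_structure: np.ndarray
    bias_max_norm: float
    domain_displacement: dict[str, float]
    asymmetry: float
    monitors: dict[str, float]
    step_range: tuple[int, int]
    seed: int
    failed: bool = False


@dataclass
class LRPFState:
    """Chainable dynamical state between segments and stages."""

    coords: np.ndarray
    velocities: np.ndarray | None
    step: int
    topology: SiteModel
    stage: str = "lrpf"


def _domain_displacement(
    mean_now: np.ndarray,
    mean_prev: np.ndarray,
    topology: SiteModel,
    protein_idx: np.ndarray,
) -> tuple[dict[str, float], float]:
    """Mean per-site displacement magnitude per domain, plus an asymmetry
    score (max-min over mean): the per-domain monitor that logs whether a
    symmetric bias produced an asymmetric path."""
    disp = np.linalg.norm(mean_now - mean_prev, axis=1)
    by_domain: dict[str, list[float]] = {}
    pset = set(int(i) for i in protein_idx)
    for s in topology:
        if s.site_id in pset:
            by_domain.setdefault(s.domain, []).append(disp[s.site_id])
    means = {d: float(np.mean(v)) for d, v in sorted(by_domain.items())}
    vals = np.array(list(means.values()))
    asym = float((vals.max() - vals.min()) / vals.mean()) if vals.mean() > 0 else 0.0
    return means, asym


def _design_perturbation(
    config: LRPFConfig, mean_full: np.ndarray, topology: SiteModel
) -> PerturbationSet:
    if config.perturbation_design == "outward_push":
        sites = resolve_selection(topology, config.sites)
        return design_outward_push(mean_full, sites, config.magnitude)
    pair_indices: list[tuple[int, int]] = []
    for a, b in config.pairs or []:
        ia = resolve_selection(topology, a)
        ib = resolve_selection(topology, b)
        if len(ia) != 1 or len(ib) != 1:
            # pair selections resolving to groups: pair up nearest sites
            for i in ia:
                j = ib[
                    int(
                        np.argmin(
                            np.linalg.norm(mean_full[ib] - mean_full[i], axis=1)
                        )
                    )
                ]
                pair_indices.append((int(i), int(j)))
        else:
            pair_indices.append((int(ia[0]), int(ib[0])))
    return design_pair_contraction(mean_full, pair_indices, config.magnitude)


def _segment_mean(
    result: LangevinResult, protein_idx: np.ndarray, superpose: bool
) -> np.ndarray:
    coords = np.array([f.coords[protein_idx] for f in result.trajectory.frames])
    if superpose and len(protein_idx) >= 3:
        coords = superpose_frames(coords)
    return coords.mean(axis=0)


def bootstrap_covariance(
    state: LRPFState,
    config: LRPFConfig,
    force_terms: Sequence[ForceTerm],
    params: LangevinParams,
    protein_idx: np.ndarray,
) -> tuple[CovarianceModel, LRPFState, LangevinResult]:
    """Cycle-0 unbiased segment: the first covariance necessarily
    predates any bias."""
    seg = params.replace(
        n_steps=config.unbiased_steps, seed=config.seed,
        save_stride=config.covariance_stride,
    )
    result = run_langevin(
        state.coords,
        force_terms,
        seg,
        velocities=state.velocities,
        topology=state.topology,
        stage=state.stage,
        step_offset=state.step,
    )
    model = estimate_covariance(
        result.trajectory,
        selection=protein_idx,
        superpose=config.superpose,
        shrinkage=config.shrinkage,
        temperature=params.temperature,
    )
    new_state = LRPFState(
        coords=result.final_coords,
        velocities=result.final_velocities,
        step=result.final_step,
        topology=state.topology,
        stage=state.stage,
    )
    return model, new_state, result


def run_cycle(
    state: LRPFState,
    config: LRPFConfig,
    force_terms: Sequence[ForceTerm],
    params: LangevinParams,
    model: CovarianceModel,
    cycle_index: int,
    prev_mean: np.ndarray | None = None,
) -> tuple[CycleRecord, LRPFState, CovarianceModel, Trajectory]:
    """One biased + unbiased cycle.

    Returns the cycle record, the chained state, the refreshed covariance
    model (from this cycle's unbiased segment) and the concatenated
    segment trajectory.
    """
    protein_idx = model.selection
    topology = state.topology
    n_top = topology.n_sites

    # bias from the incoming covariance model and its mean structure
    mean_full = state.coords.copy()
    mean_full[protein_idx] = model.mean_coords
    perturb = _design_perturbation(config, mean_full, topology)
    disp = predict_response(model, perturb)
    bias = build_bias(
        disp,
        config.f_max,
        n_topology=n_top,
        selection=protein_idx,
        source=f"{perturb.label}@cycle{cycle_index}",
    )

    start_step = state.step
    biased_params = params.replace(n_steps=config.biased_steps, seed=config.seed)
    terms_biased = list(force_terms) + [ConstantForceTerm(bias.forces, name="bias")]
    res_b = run_langevin(
        state.coords,
        terms_biased,
        biased_params,
        velocities=state.velocities,
        topology=topology,
        stage=state.stage,
        step_offset=state.step,
    )
    unbiased_params = params.replace(
        n_steps=config.unbiased_steps, seed=config.seed,
        save_stride=config.covariance_stride,
    )
    res_u = run_langevin(
        res_b.final_coords,
        force_terms,
        unbiased_params,
        velocities=res_b.final_velocities,
        topology=topology,
        stage=state.stage,
        step_offset=res_b.final_step,
    )

    new_model = estimate_covariance(
        res_u.trajectory,
        selection=protein_idx,
        superpose=config.superpose,
        shrinkage=config.shrinkage,
        temperature=params.temperature,
    )
    mean_now_full = res_u.final_coords.copy()
    mean_now_full[protein_idx] = new_model.mean_coords

    monitors: dict[str, float] = {}
    for m in config.monitors:
        if m.kind != "plateau":
            monitors[m.name] = m.evaluate(mean_now_full, topology)

    ref_prev = prev_mean if prev_mean is not None else mean_full[protein_idx]
    dom, asym = _domain_displacement(
        new_model.mean_coords, ref_prev, topology, protein_idx
    )
    record = CycleRecord(
        cycle=cycle_index,
        mean_structure=mean_now_full,
        bias_max_norm=bias.max_site_norm(),
        domain_displacement=dom,
        asymmetry=asym,
        monitors=monitors,
        step_range=(start_step, res_u.final_step),
        seed=config.seed,
    )
    traj = Trajectory(
        topology,
        list(res_b.trajectory.frames) + list(res_u.trajectory.frames),
        units=res_b.trajectory.units,
    )
    new_state = LRPFState(
        coords=res_u.final_coords,
        velocities=res_u.final_velocities,
        step=res_u.final_step,
        topology=topology,
        stage=state.stage,
    )
    return record, new_state, new_model, traj


@dataclass
class LRPFResult:
    trajectory: Trajectory
    records: list[CycleRecord]
    termination: str  # "monitor:<name>", "exhausted", "failed:<msg>"
    final_state: LRPFState


def run_lrpf(
    initial: LRPFState,
    config: LRPFConfig,
    force_terms: Sequence[ForceTerm],
    params: LangevinParams,
    protein_idx: np.ndarray | None = None,
) -> LRPFResult:
    """Full iterative LRPF run: bootstrap, then cycles until a monitor
    fires, max_cycles is exhausted, or the engine fails.

    All randomness derives from (params.seed via config.seed, stage,
    global step); a replay with identical inputs is bit-identical.
    """
    from .engine import IntegrationError

    topology = initial.topology
    if protein_idx is None:
        protein_idx = np.array(
            [s.site_id for s in topology if "tracer" not in s.group_tags],
            dtype=int,
        )
    model, state, boot = bootstrap_covariance(
        initial, config, force_terms, params, protein_idx
    )
    frames = list(boot.trajectory.frames)
    records: list[CycleRecord] = []
    histories: dict[str, list[float]] = {m.name: [] for m in config.monitors}
    termination = "exhausted"
    prev_mean = model.mean_coords
    for cycle in range(config.max_cycles):
        try:
            record, state, model, traj = run_cycle(
                state, config, force_terms, params, model, cycle,
                prev_mean=prev_mean,
            )
        except IntegrationError as exc:
            records.append(
                CycleRecord(
                    cycle=cycle,
                    mean_structure=state.coords,
                    bias_max_norm=float("nan"),
                    domain_displacement={},
                    asymmetry=float("nan"),
                    monitors={},
                    step_range=(state.step, state.step),
                    seed=config.seed,
                    failed=True,
                )
            )
            termination = f"failed:{exc}"
            break
        prev_mean = model.mean_coords
        records.append(record)
        frames.extend(traj.frames)
        fired_name = None
        for m in config.monitors:
            if m.kind == "plateau":
                src = histories.get(m.source or "", [])
                histories[m.name].append(src[-1] if src else float("nan"))
                if m.fire and m.fired(src):
                    fired_name = m.name
                    break
            else:
                histories[m.name].append(record.monitors[m.name])
                if m.fire and m.fired(histories[m.name]):
                    fired_name = m.name
                    break
        if fired_name is not None:
            termination = f"monitor:{fired_name}"
            break
    return LRPFResult(
        trajectory=Trajectory(topology, frames),
        records=records,
        termination=termination,
        final_state=state,
    )


# ---------------------------------------------------------------------------
# Staged pipelines
# ---------------------------------------------------------------------------


@dataclass
class StageReport:
    name: str
    kind: str
    start_coords: np.ndarray
    end_coords: np.ndarray
    step_range: tuple[int, int]
    monitors: dict[str, float] = field(default_factory=dict)
    termination: str = "completed"
    records: list[CycleRecord] = field(default_factory=list)
    work: float | None = None


def run_stage_sequence(
    initial: LRPFState,
    stages: Sequence[dict],
    force_terms: Sequence[ForceTerm],
    params: LangevinParams,
) -> tuple[list[StageReport], LRPFState, Trajectory]:
    """Chain stages on final coordinates/velocities.

    Each stage dict has ``kind`` in {"lrpf", "unbiased", "steered",
    "targeted"} plus kind-specific keys (see the pipeline docs).  Unknown
    kinds raise before any stage runs.  The canonical demo encodes:
    matrix-opening LRPF -> cytoplasmic-closing LRPF -> long unbiased
    relaxation -> steered expulsion -> apo relaxation.
    """
    known = {"lrpf", "unbiased", "steered", "targeted"}
    for st in stages:
        if st.get("kind") not in known:
            raise ValueError(f"unknown stage kind {st.get('kind')!r}")
    reports: list[StageReport] = []
    state = initial
    all_frames: list = []
    for st in stages:
        kind = st["kind"]
        name = st.get("name", kind)
        start = state.coords.copy()
        start_step = state.step
        stage_state = LRPFState(
            coords=state.coords,
            velocities=state.velocities,
            step=state.step,
            topology=state.topology,
            stage=state.stage,
        )
        if kind == "lrpf":
            result = run_lrpf(
                stage_state, st["config"], force_terms, params
            )
            state = result.final_state
            all_frames.extend(result.trajectory.frames)
            reports.append(
                StageReport(
                    name=name,
                    kind=kind,
                    start_coords=start,
                    end_coords=state.coords.copy(),
                    step_range=(start_step, state.step),
                    termination=result.termination,
                    records=result.records,
                    monitors=(
                        result.records[-1].monitors if result.records else {}
                    ),
                )
            )
        elif kind == "unbiased":
            seg = params.replace(n_steps=st["n_steps"], seed=st.get(
                "seed", params.seed))
            res = run_langevin(
                state.coords,
                force_terms,
                seg,
                velocities=state.velocities,
                topology=state.topology,
                stage=state.stage,
                step_offset=state.step,
            )
            state = LRPFState(res.final_coords, res.final_velocities,
                              res.final_step, state.topology, state.stage)
            all_frames.extend(res.trajectory.frames)
            reports.append(
                StageReport(name=name, kind=kind, start_coords=start,
                            end_coords=state.coords.copy(),
                            step_range=(start_step, state.step))
            )
        elif kind == "steered":
            from .engine import steered_segment

            seg = params.replace(n_steps=st["n_steps"], seed=st.get(
                "seed", params.seed))
            res = steered_segment(
                state.coords,
                force_terms,
                st["coordinate"],
                st["k_pull"],
                st["velocity"],
                seg,
                velocities=state.velocities,
                topology=state.topology,
                stage=state.stage,
                step_offset=state.step,
            )
            state = LRPFState(res.final_coords, res.final_velocities,
                              res.final_step, state.topology, state.stage)
            all_frames.extend(res.trajectory.frames)
            reports.append(
                StageReport(name=name, kind=kind, start_coords=start,
                            end_coords=state.coords.copy(),
                            step_range=(start_step, state.step),
                            work=float(res.work[-1]) if res.work is not None
                            else None)
            )
        else:  # targeted
            from .forces import TargetedRMSDRestraint

            seg = params.replace(n_steps=st["n_steps"], seed=st.get(
                "seed", params.seed))
            restraint = TargetedRMSDRestraint(
                target=st["target"],
                k=st["k_t"],
                rmsd0=st.get("rmsd0", 0.0),
                indices=st.get("indices"),
            )
            res = run_langevin(
                state.coords,
                list(force_terms) + [restraint],
                seg,
                velocities=state.velocities,
                topology=state.topology,
                stage=state.stage,
                step_offset=state.step,
            )
            state = LRPFState(res.final_coords, res.final_velocities,
                              res.final_step, state.topology, state.stage)
            all_frames.extend(res.trajectory.frames)
            reports.append(
                StageReport(name=name, kind=kind, start_coords=start,
                            end_coords=state.coords.copy(),
                            step_range=(start_step, state.step))
            )
    traj = Trajectory(initial.topology, all_frames)
    return reports, state, traj
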