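"""BAOAB Langevin dynamics over pluggable force terms.

Reproducibility contract: the noise for step ``s`` of a stage is a fixed
function of ``(seed, stage, s)`` — a Philox counter stream advanced to the
step index, with normals produced by Box–Muller so the per-step draw count
is constant.  Segment boundaries therefore do not change the noise
sequence: an LRPF run chopped into biased/unbiased segments with zero bias
is bit-identical to one continuous unbiased run at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .forces import (
    ForceTerm,
    MovingRestraint,
    NumericalForceError,
    ReactionCoordinate,
    evaluate,
)
from .topology import SiteModel
from .trajectory import Frame, Trajectory

_ENERGY_BLOWUP = 1e10


class IntegrationError(RuntimeError):
    """Raised when the integrator diverges; message carries the step index."""


@dataclass
class LangevinParams:
    """Integrator settings.

    temperature is in kT units (Boltzmann constant = 1), friction in
    inverse model time, dt in model time.  Stability requires
    dt * friction < 0.5.
    """

    temperature: float = 1.0
    friction: float = 1.0
    dt: float = 0.01
    n_steps: int = 1000
    seed: int = 0
    save_stride: int = 10
    nonbonded_cutoff: float = 12.0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction <= 0 or self.dt <= 0:
            raise ValueError("friction and dt must be positive")
        if self.dt * self.friction >= 0.5:
            raise ValueError(
                f"dt*friction = {self.dt * self.friction:.3g} >= 0.5; unstable"
            )
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def replace(self, **kw) -> "LangevinParams":
        d = self.__dict__.copy()
        d.update(kw)
        return LangevinParams(**d)


@dataclass
class LangevinResult:
    trajectory: Trajectory
    final_coords: np.ndarray
    final_velocities: np.ndarray
    potential: np.ndarray  # per saved frame
    kinetic: np.ndarray  # per saved frame
    work: np.ndarray | None = None  # per saved frame (steered runs)
    final_step: int = 0


def _stage_key(seed: int, stage: int | str) -> np.random.SeedSequence:
    if isinstance(stage, str):
        stage_id = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
        stage_id &= (1 << 63) - 1
    else:
        stage_id = int(stage)
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(stage_id,))


def _noise_generator(seed: int, stage: int | str, step_offset: int, n_draw: int):
    """Philox stream for the stage, advanced to ``step_offset`` steps.

    ``n_draw`` must be a multiple of 4: Philox.advance counts 128-bit
    counter blocks, each worth four float64 draws.
    """
    assert n_draw % 4 == 0
    key = _stage_key(seed, stage).generate_state(4)
    bitgen = np.random.Philox(key=key[:2].astype(np.uint64))
    bitgen.advance(step_offset * n_draw // 4)
    return np.random.Generator(bitgen)


def _box_muller(u: np.ndarray) -> np.ndarray:
    """Normals from uniform pairs with fixed consumption (last axis even)."""
    u = u.reshape(*u.shape[:-1], -1, 2)
    r = np.sqrt(-2.0 * np.log1p(-u[..., 0]))  # 1-u in (0,1], log finite
    theta = 2.0 * np.pi * u[..., 1]
    z = np.empty(u.shape[:-1] + (2,))
    z[..., 0] = r * np.cos(theta)
    z[..., 1] = r * np.sin(theta)
    return z.reshape(*u.shape[:-2], -1)


def draw_velocities(
    n_sites: int,
    temperature: float,
    seed: int,
    stage: int | str = 0,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Maxwell–Boltzmann velocities from the stage's dedicated init stream."""
    key = _stage_key(seed, stage).generate_state(4)
    gen = np.random.Generator(
        np.random.Philox(key=key[2:].astype(np.uint64))
    )
    v = gen.standard_normal((n_sites, 3))
    if masses is None:
        return np.sqrt(temperature) * v
    return np.sqrt(temperature / masses)[:, None] * v


def run_langevin(
    coords: np.ndarray,
    force_terms: Sequence[ForceTerm],
    params: LangevinParams,
    *,
    velocities: np.ndarray | None = None,
    topology: SiteModel | None = None,
    stage: int | str = 0,
    step_offset: int = 0,
    masses: np.ndarray | None = None,
    units: str = "model",
    moving_restraint: MovingRestraint | None = None,
    pull_velocity: float = 0.0,
) -> LangevinResult:
    """Integrate BAOAB Langevin dynamics.

    Frames are saved every ``save_stride`` steps (and at the final step);
    frame times are ``(step_offset + step) * dt`` so chained segments keep
    a continuous clock.  Same (seed, stage, step_offset) -> bit-identical
    output.
    """
    x = np.asarray(coords, dtype=float).copy()
    n = x.shape[0]
    m = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    if velocities is None:
        v = draw_velocities(n, params.temperature, params.seed, stage, m)
    else:
        v = np.asarray(velocities, dtype=float).copy()

    dt = params.dt
    c1 = np.exp(-params.friction * dt)
    sigma = np.sqrt(params.temperature * (1.0 - c1 * c1) / m)[:, None]
    inv_m = (1.0 / m)[:, None]

    n_draw = -4 * (-(3 * n) // 4)  # round up to a multiple of 4
    gen = _noise_generator(params.seed, stage, step_offset, n_draw)

    steered = moving_restraint is not None
    center0 = moving_restraint.center if steered else 0.0
    work = 0.0

    terms = list(force_terms)
    if steered:
        terms = terms + [moving_restraint]

    e_pot, f = evaluate(x, terms)
    frames: list[Frame] = []
    pot: list[float] = []
    kin: list[float] = []
    works: list[float] = []
    # noise drawn in chunks to bound memory
    chunk = max(1, min(params.n_steps, max(1, 2_000_000 // n_draw)))
    step = 0
    while step < params.n_steps:
        n_here = min(chunk, params.n_steps - step)
        u = gen.random((n_here, n_draw))
        xi = _box_muller(u)[:, : 3 * n].reshape(n_here, n, 3)
        for s in range(n_here):
            step += 1
            if steered:
                moving_restraint.center = center0 + pull_velocity * (
                    (step_offset + step) * dt
                )
            v += 0.5 * dt * f * inv_m
            x += 0.5 * dt * v
            v = c1 * v + sigma * xi[s]
            x += 0.5 * dt * v
            e_pot, f = evaluate(x, terms)
            v += 0.5 * dt * f * inv_m
            if steered:
                q = moving_restraint.coordinate.value(x)
                work += (
                    moving_restraint.k
                    * (moving_restraint.center - q)
                    * pull_velocity
                    * dt
                )
            if abs(e_pot) > _ENERGY_BLOWUP or not np.isfinite(e_pot):
                raise IntegrationError(
                    f"energy divergence at step {step_offset + step}"
                )
            if step % params.save_stride == 0 or step == params.n_steps:
                if frames and frames[-1].time == (step_offset + step) * dt:
                    continue
                frames.append(Frame(x.copy(), time=(step_offset + step) * dt))
                pot.append(e_pot)
                kin.append(0.5 * float(np.sum(m[:, None] * v * v)))
                works.append(work)

    traj = Trajectory(topology, frames, units=units)
    return LangevinResult(
        trajectory=traj,
        final_coords=x,
        final_velocities=v,
        potential=np.array(pot),
        kinetic=np.array(kin),
        work=np.array(works) if steered else None,
        final_step=step_offset + params.n_steps,
    )


def steered_segment(
    coords: np.ndarray,
    force_terms: Sequence[ForceTerm],
    coordinate: ReactionCoordinate,
    k_pull: float,
    velocity: float,
    params: LangevinParams,
    **kw,
) -> LangevinResult:
    """Steered run: a harmonic center moving at constant velocity.

    The center starts at the coordinate's initial value; accumulated work
    W = sum k (x0 - q) v dt is reported per saved frame.
    """
    if k_pull <= 0:
        raise ValueError("k_pull must be positive")
    x = np.asarray(coords, dtype=float)
    step_offset = kw.get("step_offset", 0)
    q0 = coordinate.value(x) - velocity * step_offset * params.dt
    restraint = MovingRestraint(coordinate=coordinate, k=k_pull, center=q0)
    return run_langevin(
        x,
        force_terms,
        params,
        moving_restraint=restraint,
        pull_velocity=velocity,
        **kw,
    )


def targeted_restraint_force(
    coords: np.ndarray,
    target: np.ndarray,
    k_t: float,
    rmsd0: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Energy and forces of the targeted-RMSD restraint
    V = 1/2 k_t (RMSD(coords, target) - rmsd0)^2 through the optimal
    superposition."""
    from .forces import TargetedRMSDRestraint

    return TargetedRMSDRestraint(
        target=np.asarray(target, dtype=float), k=k_t, rmsd0=rmsd0
    ).energy_forces(np.asarray(coords, dtype=float))


def kinetic_temperature(result: LangevinResult, n_dof: int) -> float:
    """Mean kinetic energy per degree of freedom times 2 (i.e. kT estimate)."""
    return float(2.0 * result.kinetic.mean() / n_dof)
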