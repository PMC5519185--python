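"""Potential-energy terms for the coarse-grained engine.

Every term exposes ``energy_forces(coords) -> (E, F)`` with ``F`` the exact
negative analytic gradient of ``E`` (an invariant the test suite checks by
central differences).  Terms flag themselves ``internal=True`` when they
depend only on internal coordinates and therefore contribute zero net
force; external-frame terms (constant biases, spatial walls, moving
restraints) are exempt from that check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform


class NumericalForceError(RuntimeError):
    """Raised when a term produces a non-finite energy or force."""


class ForceTerm:
    """Base class; subclasses implement energy_forces."""

    name: str = "term"
    internal: bool = True

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError


def evaluate(
    coords: np.ndarray, terms: Sequence[ForceTerm]
) -> tuple[float, np.ndarray]:
    """Total energy and forces of a term set.

    Raises NumericalForceError naming the offending term if any term
    returns a non-finite energy or force.
    """
    coords = np.asarray(coords, dtype=float)
    total_e = 0.0
    total_f = np.zeros_like(coords)
    for term in terms:
        e, f = term.energy_forces(coords)
        if not np.isfinite(e) or not np.all(np.isfinite(f)):
            raise NumericalForceError(
                f"non-finite energy/forces from term {term.name!r}"
            )
        total_e += e
        total_f += f
    return total_e, total_f


# ---------------------------------------------------------------------------
# Elastic network
# ---------------------------------------------------------------------------


@dataclass
class ENMTerm(ForceTerm):
    """Pairwise harmonic network anchored at a reference structure.

    V = sum_pairs k/2 (d_ij - d_ij^ref)^2 over pairs within ``cutoff`` in
    the reference.  Spring constants may be uniform or per-pair.
    """

    pairs_i: np.ndarray
    pairs_j: np.ndarray
    rest_lengths: np.ndarray
    spring: np.ndarray  # per-pair
    n_sites: int
    name: str = "enm"
    internal: bool = True

    @classmethod
    def from_reference(
        cls,
        reference: np.ndarray,
        cutoff: float,
        spring: float,
        *,
        indices: np.ndarray | None = None,
        name: str = "enm",
    ) -> "ENMTerm":
        """Build the network from all site pairs within ``cutoff``."""
        reference = np.asarray(reference, dtype=float)
        n = reference.shape[0]
        if indices is None:
            indices = np.arange(n)
        sub = reference[indices]
        d = squareform(pdist(sub))
        ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
        rest = d[ii, jj]
        if np.any(rest <= 0):
            raise ValueError("coincident sites in ENM reference")
        return cls(
            pairs_i=indices[ii],
            pairs_j=indices[jj],
            rest_lengths=rest,
            spring=np.full(rest.shape, float(spring)),
            n_sites=n,
            name=name,
        )

    @property
    def n_pairs(self) -> int:
        return len(self.rest_lengths)

    def scaled(self, factor: float) -> "ENMTerm":
        return ENMTerm(
            self.pairs_i,
            self.pairs_j,
            self.rest_lengths,
            self.spring * factor,
            self.n_sites,
            name=self.name,
        )

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        dvec = coords[self.pairs_i] - coords[self.pairs_j]
        d = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        delta = d - self.rest_lengths
        energy = 0.5 * float(np.dot(self.spring, delta * delta))
        # dV/dx_i = k * delta * unit(i->j)
        coef = self.spring * delta / d
        fpair = -coef[:, None] * dvec  # force on i
        n = coords.shape[0]
        forces = np.empty_like(coords)
        for c in range(3):
            forces[:, c] = np.bincount(
                self.pairs_i, weights=fpair[:, c], minlength=n
            ) - np.bincount(self.pairs_j, weights=fpair[:, c], minlength=n)
        return energy, forces


@dataclass
class QuadraticTerm(ForceTerm):
    """General anchored quadratic potential V = 1/2 (x-x0)^T K (x-x0).

    K is a dense 3N x 3N symmetric positive semidefinite matrix; used for
    harmonic-network oracles with an exactly known stiffness.
    """

    x0: np.ndarray  # (N, 3)
    stiffness: np.ndarray  # (3N, 3N)
    name: str = "quadratic"
    internal: bool = False  # anchored in space

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        dx = (coords - self.x0).ravel()
        g = self.stiffness @ dx
        return 0.5 * float(dx @ g), -g.reshape(coords.shape)




@dataclass
class AngleTerm(ForceTerm):
    """Angle stiffness V = k/2 (cos theta - cos theta0)^2 per bead triple.

    Smooth everywhere (no 1/sin singularity), zero at the reference
    angles, and supplies the transverse bending stiffness that along-chain
    pair springs cannot provide near collinear bead geometries.  A reduced
    spring at one designated "kinkable" bead per helix emulates a soft
    hinge.
    """

    triples: np.ndarray  # (n_angles, 3) site indices (i, center, k)
    k: np.ndarray  # per-angle spring
    rest_cos: np.ndarray | float = -1.0  # cos of the reference angle

    name: str = "angles"
    internal: bool = True

    def _cos(self, coords):
        i1, i2, i3 = self.triples[:, 0], self.triples[:, 1], self.triples[:, 2]
        a = coords[i1] - coords[i2]
        b = coords[i3] - coords[i2]
        na = np.sqrt(np.einsum("ij,ij->i", a, a))
        nb = np.sqrt(np.einsum("ij,ij->i", b, b))
        u = a / na[:, None]
        w = b / nb[:, None]
        return np.einsum("ij,ij->i", u, w), u, w, na, nb

    @classmethod
    def with_reference(cls, triples, k, reference, **kw) -> "AngleTerm":
        """Rest angles taken from a reference structure."""
        term = cls(triples=triples, k=k, **kw)
        c, *_ = term._cos(np.asarray(reference, dtype=float))
        term.rest_cos = c
        return term

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        i1, i2, i3 = self.triples[:, 0], self.triples[:, 1], self.triples[:, 2]
        c, u, w, na, nb = self._cos(coords)
        dev = c - self.rest_cos
        energy = 0.5 * float(np.dot(self.k, dev * dev))
        coef = (self.k * dev)[:, None]
        dc_d1 = (w - c[:, None] * u) / na[:, None]
        dc_d3 = (u - c[:, None] * w) / nb[:, None]
        g1 = -coef * dc_d1
        g3 = -coef * dc_d3
        forces = np.zeros_like(coords)
        np.add.at(forces, i1, g1)
        np.add.at(forces, i3, g3)
        np.add.at(forces, i2, -(g1 + g3))
        return energy, forces




@dataclass
class HarmonicTetherTerm(ForceTerm):
    """Isotropic positional tethers V = k/2 sum_i |x_i - x0_i|^2.

    Used as the membrane-scaffold surrogate: the helix ends that do not
    move between the reference states are softly pinned to their common
    position, standing in for the bilayer that suppresses whole-body
    drift and wobble of an embedded transporter.
    """

    indices: np.ndarray
    ref: np.ndarray  # (len(indices), 3)
    k: float
    name: str = "tether"
    internal: bool = False

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        dx = coords[self.indices] - self.ref
        forces = np.zeros_like(coords)
        forces[self.indices] = -self.k * dx
        return 0.5 * self.k * float(np.sum(dx * dx)), forces


# ---------------------------------------------------------------------------
# Double-basin mixing
# ---------------------------------------------------------------------------


def double_basin_energy(
    v_a: float, v_b: float, beta_mix: float, delta_v: float = 0.0
) -> float:
    """Smoothly mixed two-basin energy via a log-sum-exp of basin energies.

    E = -(1/beta_mix) * ln(exp(-beta_mix*(V_A + dV)) + exp(-beta_mix*V_B)).
    Overflow-guarded; never NaN for finite inputs.
    """
    if beta_mix <= 0:
        raise ValueError("beta_mix must be positive")
    ea = v_a + delta_v
    m = min(ea, v_b)
    return m - np.log(
        np.exp(-beta_mix * (ea - m)) + np.exp(-beta_mix * (v_b - m))
    ) / beta_mix


@dataclass
class DoubleBasinTerm(ForceTerm):
    """Two single-basin terms mixed into a smooth double-well landscape.

    The mixed energy interpolates between basins with a crossover width set
    by 1/beta_mix; forces are the exactly weighted basin forces with
    weights w_A = exp(-b(V_A+dV)) / (exp(-b(V_A+dV)) + exp(-b V_B)).
    """

    basin_a: ForceTerm
    basin_b: ForceTerm
    beta_mix: float
    delta_v: float = 0.0
    name: str = "double_basin"
    internal: bool = True

    def __post_init__(self) -> None:
        if self.beta_mix <= 0:
            raise ValueError("beta_mix must be positive")

    def basin_energies(self, coords: np.ndarray) -> tuple[float, float]:
        ea, _ = self.basin_a.energy_forces(coords)
        eb, _ = self.basin_b.energy_forces(coords)
        return ea, eb

    def basin_weights(self, coords: np.ndarray) -> tuple[float, float]:
        ea, eb = self.basin_energies(coords)
        ga = -self.beta_mix * (ea + self.delta_v)
        gb = -self.beta_mix * eb
        m = max(ga, gb)
        wa = np.exp(ga - m)
        wb = np.exp(gb - m)
        s = wa + wb
        return float(wa / s), float(wb / s)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        ea, fa = self.basin_a.energy_forces(coords)
        eb, fb = self.basin_b.energy_forces(coords)
        e = double_basin_energy(ea, eb, self.beta_mix, self.delta_v)
        ga = -self.beta_mix * (ea + self.delta_v)
        gb = -self.beta_mix * eb
        m = max(ga, gb)
        wa = np.exp(ga - m)
        wb = np.exp(gb - m)
        s = wa + wb
        return e, (wa / s) * fa + (wb / s) * fb


# ---------------------------------------------------------------------------
# External forces and restraints
# ---------------------------------------------------------------------------


@dataclass
class ConstantForceTerm(ForceTerm):
    """Constant per-site external force (the applied bias field).

    E = -sum_i f_i . x_i so that the force is exactly the stored field.
    """

    forces: np.ndarray  # (N, 3)
    name: str = "bias"
    internal: bool = False

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return -float(np.sum(self.forces * coords)), self.forces.copy()


@dataclass
class HarmonicPairRestraint(ForceTerm):
    """V = k/2 (d_ij - r0)^2 on one site pair."""

    i: int
    j: int
    k: float
    r0: float
    name: str = "pair_restraint"
    internal: bool = True

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        dvec = coords[self.i] - coords[self.j]
        d = float(np.linalg.norm(dvec))
        if d == 0.0:
            raise NumericalForceError("degenerate pair restraint (d=0)")
        delta = d - self.r0
        forces = np.zeros_like(coords)
        g = self.k * delta * dvec / d
        forces[self.i] -= g
        forces[self.j] += g
        return 0.5 * self.k * delta * delta, forces


class ReactionCoordinate:
    """Scalar coordinate with value and gradient, for steered restraints."""

    def value(self, coords: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class PairDistanceCoordinate(ReactionCoordinate):
    i: int
    j: int

    def value(self, coords: np.ndarray) -> float:
        return float(np.linalg.norm(coords[self.i] - coords[self.j]))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        dvec = coords[self.i] - coords[self.j]
        d = np.linalg.norm(dvec)
        g = np.zeros_like(coords)
        if d == 0:
            return g
        g[self.i] = dvec / d
        g[self.j] = -dvec / d
        return g


@dataclass
class ProjectionCoordinate(ReactionCoordinate):
    """Projection of the centroid of a site group onto a unit direction."""

    indices: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.direction = self.direction / np.linalg.norm(self.direction)
        self.indices = np.asarray(self.indices, dtype=int)

    def value(self, coords: np.ndarray) -> float:
        return float(coords[self.indices].mean(axis=0) @ self.direction)

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        g = np.zeros_like(coords)
        g[self.indices] = self.direction / len(self.indices)
        return g


@dataclass
class MovingRestraint(ForceTerm):
    """Harmonic restraint V = k/2 (q(x) - center)^2 with a settable center.

    The steered-MD driver advances ``center`` linearly in time.
    """

    coordinate: ReactionCoordinate
    k: float
    center: float
    name: str = "moving_restraint"
    internal: bool = False

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        q = self.coordinate.value(coords)
        delta = q - self.center
        grad = self.coordinate.gradient(coords)
        return 0.5 * self.k * delta * delta, -self.k * delta * grad


@dataclass
class TargetedRMSDRestraint(ForceTerm):
    """V = k/2 (RMSD(x, target) - rmsd0)^2 through optimal superposition.

    The gradient uses the envelope theorem: at the optimal rigid fit the
    derivative through rotation and translation vanishes, leaving
    dRMSD/dx_i = (x_i - y'_i) / (N * RMSD) with y' the fitted target.
    """

    target: np.ndarray
    k: float
    rmsd0: float = 0.0
    indices: np.ndarray | None = None
    name: str = "targeted_rmsd"
    internal: bool = True  # depends only on shape, invariant to rigid motion

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        from .metrics import kabsch_superpose  # local import, avoids cycle

        idx = (
            np.arange(coords.shape[0])
            if self.indices is None
            else np.asarray(self.indices, dtype=int)
        )
        if len(idx) < 3:
            raise NumericalForceError(
                "targeted restraint needs >= 3 sites for superposition"
            )
        x = coords[idx]
        y = np.asarray(self.target, dtype=float)
        if y.shape[0] == coords.shape[0] and self.indices is not None:
            y = y[idx]
        # fit the target onto the instantaneous coordinates
        rot, trans, rmsd = kabsch_superpose(y, x)
        y_fit = y @ rot.T + trans
        delta = rmsd - self.rmsd0
        energy = 0.5 * self.k * delta * delta
        forces = np.zeros_like(coords)
        if rmsd > 1e-12:
            drmsd = (x - y_fit) / (len(idx) * rmsd)
            forces[idx] = -self.k * delta * drmsd
        return energy, forces


# ---------------------------------------------------------------------------
# Tracer interactions
# ---------------------------------------------------------------------------


@dataclass
class SoftCoreRepulsion(ForceTerm):
    """Truncated purely repulsive pair term between two site groups.

    V = k/2 (sigma - d)^2 for d < sigma, zero beyond the core diameter
    (continuous value and derivative at the cutoff).  Evaluated brute
    force over the group_a x group_b rectangle, which is faster than any
    neighbor list at the few-hundred-site scale this engine targets.
    """

    group_a: np.ndarray
    group_b: np.ndarray
    sigma: float
    k: float
    name: str = "soft_repulsion"
    internal: bool = True

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        forces = np.zeros_like(coords)
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            return 0.0, forces
        xa = coords[self.group_a]
        xb = coords[self.group_b]
        dvec = xa[:, None, :] - xb[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", dvec, dvec))
        mask = d < self.sigma
        if not np.any(mask):
            return 0.0, forces
        ii, jj = np.nonzero(mask)
        dm = d[ii, jj]
        dm = np.maximum(dm, 1e-12)
        delta = self.sigma - dm
        energy = 0.5 * self.k * float(np.dot(delta, delta))
        g = (self.k * delta / dm)[:, None] * dvec[ii, jj]
        np.add.at(forces, self.group_a[ii], g)
        np.add.at(forces, self.group_b[jj], -g)
        return energy, forces


def _cos2_window(z: np.ndarray, center: float, halfwidth: float):
    """C1 bump: cos^2(pi (z-c) / (2 w)) inside |z-c| < w, else 0."""
    u = (z - center) / halfwidth
    inside = np.abs(u) < 1.0
    w = np.where(inside, np.cos(0.5 * np.pi * u) ** 2, 0.0)
    dw = np.where(
        inside,
        -(0.5 * np.pi / halfwidth) * np.sin(np.pi * u),
        0.0,
    )
    return w, dw


def _plateau_window(z: np.ndarray, lo: float, hi: float, ramp: float):
    """C1 plateau: 1 on [lo+ramp, hi-ramp], cos^2 ramps to 0 at lo and hi."""
    z = np.asarray(z, dtype=float)
    w = np.zeros_like(z)
    dw = np.zeros_like(z)
    w[(z >= lo + ramp) & (z <= hi - ramp)] = 1.0
    up = (z > lo) & (z < lo + ramp)
    if np.any(up):
        wu, du = _cos2_window(z[up], lo + ramp, ramp)
        w[up], dw[up] = wu, du
    dn = (z > hi - ramp) & (z < hi)
    if np.any(dn):
        wd, dd = _cos2_window(z[dn], hi - ramp, ramp)
        w[dn], dw[dn] = wd, dd
    return w, dw


@dataclass
class ChannelWallTerm(ForceTerm):
    """Analytic channel surrogate coupling tracer passage to gate geometry.

    Three C1 pieces act on tracer particles only:

    * a body wall excluding tracers from the protein annulus
      ``r_in < rho < r_out`` over the membrane span, so the channel
      interior is reachable only along the axis through a gate;
    * two gate walls, each covering its *entire half-channel* in z (the
      closed side of a carrier is packed, not merely pinched at a point):
      within the half a tracer pays ``k_gate/2 * (rho - a)^2`` beyond the
      aperture radius ``a = R_gate - r_closed - aperture_offset``, where
      ``R_gate`` is the *instantaneous* mean radial distance of that
      gate's ring beads.  A closed ring (R ~ r_closed) gives a negative
      aperture and a finite barrier even on the axis, so the whole half
      excludes tracers; an open ring leaves an axial corridor.  The
      chain-rule reaction force on the ring beads is included, so forces
      remain the exact gradient;
    * a harmonic box keeping tracers within ``box_half`` on each axis.

    Three beads per gate ring cannot sterically occlude a channel mouth,
    so the gating itself is carried by this aperture coupling rather than
    by pair repulsion; see the methods note.
    """

    tracer_idx: np.ndarray
    gate_cyt_idx: np.ndarray
    gate_mat_idx: np.ndarray
    z_gate_cyt: float  # z of the cytoplasmic mouth (top of the span)
    z_gate_mat: float  # z of the matrix mouth (bottom of the span)
    r_closed_cyt: float
    r_closed_mat: float
    aperture_offset: float = 1.0
    ramp: float = 2.0
    gate_radial_off: float = 12.0  # gate penalty fades out by this radius
    gate_radial_on: float = 8.0
    r_in: float = 5.0
    r_out: float = 16.0
    k_gate: float = 20.0
    k_body: float = 60.0
    box_half: float = 18.0
    k_box: float = 10.0
    name: str = "channel_walls"
    internal: bool = False

    def _gate(self, coords, energy_f, gate_idx, z_lo, z_hi, r_closed):
        t = self.tracer_idx
        xy_t = coords[t, :2]
        z_t = coords[t, 2]
        rho_t = np.sqrt(np.einsum("ij,ij->i", xy_t, xy_t))
        wz, dwz = _plateau_window(z_t, z_lo, z_hi, self.ramp)
        if not np.any(wz > 0):
            return 0.0
        xy_g = coords[gate_idx, :2]
        rho_g = np.sqrt(np.einsum("ij,ij->i", xy_g, xy_g))
        r_ring = float(rho_g.mean())
        a = r_ring - r_closed - self.aperture_offset
        # radial fade-out so the gate term only acts inside the channel
        ron, roff = self.gate_radial_on, self.gate_radial_off
        s = np.ones_like(rho_t)
        ds = np.zeros_like(rho_t)
        ramp_mask = (rho_t > ron) & (rho_t < roff)
        s[rho_t >= roff] = 0.0
        if np.any(ramp_mask):
            sw, dsw = _cos2_window(rho_t[ramp_mask], ron, roff - ron)
            s[ramp_mask] = sw
            ds[ramp_mask] = dsw
        pen = np.maximum(0.0, rho_t - a)
        energy = float(np.sum(0.5 * self.k_gate * wz * s * pen**2))
        du_drho = (
            self.k_gate * wz * s * pen
            + 0.5 * self.k_gate * wz * ds * pen**2
        )
        du_dz = 0.5 * self.k_gate * dwz * s * pen**2
        unit_xy = np.where(
            rho_t[:, None] > 1e-12, xy_t / np.maximum(rho_t, 1e-12)[:, None], 0.0
        )
        energy_f[t, :2] -= du_drho[:, None] * unit_xy
        energy_f[t, 2] -= du_dz
        # reaction on gate beads through a = mean(rho_g) - const
        du_da = -float(np.sum(self.k_gate * wz * s * pen))
        if du_da != 0.0:
            unit_g = xy_g / np.maximum(rho_g, 1e-12)[:, None]
            energy_f[gate_idx, :2] -= (du_da / len(gate_idx)) * unit_g
        return energy

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        forces = np.zeros_like(coords)
        t = self.tracer_idx
        if len(t) == 0:
            return 0.0, forces
        energy = 0.0
        mid = 0.5 * (self.z_gate_cyt + self.z_gate_mat)
        energy += self._gate(
            coords, forces, self.gate_cyt_idx,
            mid, self.z_gate_cyt + self.ramp, self.r_closed_cyt,
        )
        energy += self._gate(
            coords, forces, self.gate_mat_idx,
            self.z_gate_mat - self.ramp, mid, self.r_closed_mat,
        )

        # body annulus: smooth quartic bump in rho over the membrane span
        xy = coords[t, :2]
        z = coords[t, 2]
        rho = np.sqrt(np.einsum("ij,ij->i", xy, xy))
        wz, dwz = _plateau_window(
            z, self.z_gate_mat - self.ramp, self.z_gate_cyt + self.ramp,
            self.ramp,
        )
        in_ann = (rho > self.r_in) & (rho < self.r_out) & (wz > 0)
        if np.any(in_ann):
            q = (0.5 * (self.r_out - self.r_in)) ** 2
            u = (rho[in_ann] - self.r_in) * (self.r_out - rho[in_ann]) / q
            du_drho = (self.r_in + self.r_out - 2 * rho[in_ann]) / q
            b = u * u
            db = 2 * u * du_drho
            energy += float(np.sum(self.k_body * wz[in_ann] * b))
            du_r = self.k_body * wz[in_ann] * db
            du_z = self.k_body * dwz[in_ann] * b
            unit_xy = xy[in_ann] / np.maximum(rho[in_ann], 1e-12)[:, None]
            idx = t[in_ann]
            np.add.at(forces, idx, np.column_stack(
                [-du_r * unit_xy[:, 0], -du_r * unit_xy[:, 1], -du_z]))

        # confining box on tracers
        x = coords[t]
        over = np.abs(x) - self.box_half
        outside = over > 0
        if np.any(outside):
            pen = np.where(outside, over, 0.0)
            energy += 0.5 * self.k_box * float(np.sum(pen**2))
            forces[t] -= self.k_box * pen * np.sign(x)
        return energy, forces
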