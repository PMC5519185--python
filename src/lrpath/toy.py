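"""Synthetic two-state toy transporter.

A pseudo three-fold-symmetric bundle of six bead helices (two per domain,
domains I-III) emulating the alternating-access architecture of a
mitochondrial-carrier-like transporter:

* even helices carry the cytoplasmic gate at their top beads — open
  (ring radius 13 model units) in the outward-facing (OF) state, closed
  (9) in the inward-facing (IF) state;
* odd helices carry the matrix gate at their bottom beads — the reverse
  (9 in OF, 13 in IF); those beads double as the acidic MCF-motif analogs;
* the two reference geometries anchor a double-basin elastic-network
  potential whose barrier is calibrated to a prescribed height in kT,
  high enough that unbiased desk-scale runs never cross it;
* optional tracer particles (a solvent surrogate) experience soft
  repulsion from the beads plus channel walls whose gate apertures follow
  the instantaneous gate ring radii, so the open side of the channel
  admits tracers and the closed side excludes them.

The default gate radii 13 / 9 model units mirror the cytoplasmic
channel radius-of-gyration values characteristic of the open and closed
states of mitochondrial-carrier transporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .forces import (
    AngleTerm,
    HarmonicTetherTerm,
    ChannelWallTerm,
    DoubleBasinTerm,
    ENMTerm,
    ForceTerm,
    SoftCoreRepulsion,
    double_basin_energy,
)
from .metrics import rmsd
from .topology import Site, SiteModel
from .trajectory import Frame

_DOMAIN_LABELS = ("I", "II", "III")


class GeometryError(ValueError):
    """Raised when spec radii produce overlapping beads."""


class CalibrationError(RuntimeError):
    """Raised when barrier calibration cannot bracket the target."""


@dataclass
class ToyTransporterSpec:
    """Parameters of the toy transporter and its landscape.

    Lengths are model units; ``temperature`` and ``barrier_height`` are in
    kT units with Boltzmann constant 1.
    """

    n_domains: int = 3
    sites_per_helix: int = 8
    helices_per_domain: int = 2
    gate_radius_cyt_OF: float = 13.0
    gate_radius_cyt_IF: float = 9.0
    gate_radius_mat_OF: float = 9.0
    gate_radius_mat_IF: float = 13.0
    anchor_radius: float = 13.0
    helix_length: float = 24.0
    twist_deg: float = 15.0
    barrier_height: float = 12.0
    temperature: float = 1.0
    enm_cutoff: float = 27.0
    strut_cutoff: float = 30.0
    enm_spring: float = 1.0
    k_angle: float = 20.0
    k_kink: float = 4.0
    helical_amplitude: float = 1.2
    helical_period: float = 3.6
    k_anchor: float = 10.0
    beta_mix: float = 2.0
    strain_tol: float = 0.5
    strut_factor: float = 4.0
    delta_v: float = 0.0
    n_tracers: int = 0
    tracer_sigma: float = 2.0
    tracer_k: float = 25.0
    min_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gate_radius_cyt_OF > self.gate_radius_cyt_IF:
            raise ValueError("cytoplasmic gate must be wider in OF than IF")
        if not self.gate_radius_mat_IF > self.gate_radius_mat_OF:
            raise ValueError("matrix gate must be wider in IF than OF")
        for r in (
            self.gate_radius_cyt_OF,
            self.gate_radius_cyt_IF,
            self.gate_radius_mat_OF,
            self.gate_radius_mat_IF,
            self.anchor_radius,
        ):
            if r <= 0:
                raise ValueError("all radii must be positive")
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.sites_per_helix < 2:
            raise ValueError("need >= 2 sites per helix")
        if self.n_tracers < 0:
            raise ValueError("n_tracers must be >= 0")

    @property
    def n_helices(self) -> int:
        return self.n_domains * self.helices_per_domain

    @property
    def n_protein_sites(self) -> int:
        return self.n_helices * self.sites_per_helix

    @property
    def z_half(self) -> float:
        return self.helix_length / 2.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReferencePair:
    """The two reference basins of the toy (OF and IF) plus topology."""

    of_state: Frame
    if_state: Frame
    topology: SiteModel
    spec: ToyTransporterSpec

    def __post_init__(self) -> None:
        if self.of_state.n_sites != self.if_state.n_sites:
            raise ValueError("OF and IF frames must have equal site counts")
        if rmsd(self.of_state.coords, self.if_state.coords) <= 0:
            raise ValueError("OF and IF references must differ")

    @property
    def protein_indices(self) -> np.ndarray:
        return np.array(
            [s.site_id for s in self.topology if "tracer" not in s.group_tags],
            dtype=int,
        )

    @property
    def tracer_indices(self) -> np.ndarray:
        return self.topology.indices_with_tag("tracer")


def _helix_endpoints(spec: ToyTransporterSpec, helix: int, state: str):
    """Cartesian endpoints (bottom, top) of one helix in one state."""
    theta = 2.0 * np.pi * helix / spec.n_helices
    twist = np.radians(spec.twist_deg)
    z = spec.z_half
    if helix % 2 == 0:  # cytoplasmic-gate helix: top bead moves
        r_top = (
            spec.gate_radius_cyt_OF if state == "OF" else spec.gate_radius_cyt_IF
        )
        th_top = theta if state == "OF" else theta + twist
        bottom = np.array(
            [spec.anchor_radius * np.cos(theta),
             spec.anchor_radius * np.sin(theta), -z]
        )
        top = np.array([r_top * np.cos(th_top), r_top * np.sin(th_top), z])
    else:  # matrix-gate helix: bottom bead moves
        r_bot = (
            spec.gate_radius_mat_OF if state == "OF" else spec.gate_radius_mat_IF
        )
        th_bot = theta if state == "IF" else theta - twist
        top = np.array(
            [spec.anchor_radius * np.cos(theta),
             spec.anchor_radius * np.sin(theta), z]
        )
        bottom = np.array([r_bot * np.cos(th_bot), r_bot * np.sin(th_bot), -z])
    return bottom, top


def _state_coords(spec: ToyTransporterSpec, state: str) -> np.ndarray:
    """Bead coordinates of one state.

    Beads interpolate linearly between the helix endpoints and carry a
    helical decoration (amplitude windowed to zero at both ends, so the
    gate and anchor beads sit exactly on their nominal rings).  The
    decoration gives the elastic network generic, non-coplanar spring
    directions; perfectly straight rods would have zero transverse pair
    stiffness.
    """
    coords = np.empty((spec.n_protein_sites, 3))
    k = 0
    for h in range(spec.n_helices):
        theta = 2.0 * np.pi * h / spec.n_helices
        bottom, top = _helix_endpoints(spec, h, state)
        axis = top - bottom
        u = axis / np.linalg.norm(axis)
        e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        n1 = e_r - (e_r @ u) * u
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(u, n1)
        for b in range(spec.sites_per_helix):
            t = b / (spec.sites_per_helix - 1)
            phase = 2.0 * np.pi * b / spec.helical_period
            amp = spec.helical_amplitude * np.sin(np.pi * t)
            offset = amp * (np.cos(phase) * n1 + np.sin(phase) * n2)
            coords[k] = (1 - t) * bottom + t * top + offset
            k += 1
    return coords


def anchor_indices(spec: ToyTransporterSpec) -> np.ndarray:
    """Beads whose position is common to both states (the immobile helix
    ends: bottoms of even helices, tops of odd ones)."""
    m = spec.sites_per_helix
    idx = []
    for h in range(spec.n_helices):
        idx.append(h * m if h % 2 == 0 else h * m + m - 1)
    return np.array(sorted(idx), dtype=int)


def build_reference_states(spec: ToyTransporterSpec) -> ReferencePair:
    """Generate the OF/IF reference geometries and their topology.

    Beads are ordered helix-major, bottom to top.  The construction is
    exactly three-fold symmetric: rotating either state by 120 degrees
    about z reproduces the coordinates of the next domain's sites.

    Raises GeometryError if any two beads fall closer than
    ``spec.min_separation``.
    """
    sites: list[Site] = []
    for h in range(spec.n_helices):
        d = h // spec.helices_per_domain
        domain = _DOMAIN_LABELS[d] if d < 3 else f"D{d + 1}"
        helix = f"TM{h + 1}"
        for b in range(spec.sites_per_helix):
            tags: set[str] = set()
            if h % 2 == 0:
                if b == spec.sites_per_helix - 1:
                    tags |= {"gate_cyt", "hydrophobic"}
                if b == 0:
                    tags.add("basic")
            else:
                if b == 0:
                    tags |= {"gate_mat", "acidic"}
            sites.append(
                Site(
                    site_id=len(sites),
                    name=f"B{b + 1}",
                    domain=domain,
                    helix=helix,
                    group_tags=frozenset(tags),
                )
            )
    topology = SiteModel(sites)
    of = _state_coords(spec, "OF")
    if_ = _state_coords(spec, "IF")
    for coords, label in ((of, "OF"), (if_, "IF")):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        np.fill_diagonal(dist, np.inf)
        if dist.min() < spec.min_separation:
            raise GeometryError(
                f"{label} reference has beads closer than min_separation "
                f"({dist.min():.3f} < {spec.min_separation})"
            )
    return ReferencePair(
        of_state=Frame(of, time=0.0),
        if_state=Frame(if_, time=0.0),
        topology=topology,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Double-basin potential
# ---------------------------------------------------------------------------


@dataclass
class DoubleBasinModel:
    """Calibrated two-basin ENM landscape for the toy.

    ``terms`` is the complete protein potential: the mixed double-basin
    elastic networks plus the backbone angle stiffness (zero in both
    reference states and along their linear interpolant, so it never
    enters the barrier).  Calibration softens only the *strained* pairs —
    those whose rest length differs between the two basins (or that exist
    in only one network) — by a common factor found by bisection, leaving
    the stiffness of the conserved contacts untouched.  The transition
    directions thus become exactly as soft as the target barrier demands
    while the rest of the structure keeps its native rigidity.
    """

    term: DoubleBasinTerm
    backbone: AngleTerm
    spring_scale: float  # factor applied to strained pairs
    barrier: float  # achieved barrier, kT units
    path_energies: np.ndarray  # along the 101-point OF->IF interpolation
    beta_mix: float
    delta_v: float
    protein_indices: np.ndarray

    anchor: "HarmonicTetherTerm | None" = None

    @property
    def terms(self) -> list[ForceTerm]:
        out: list[ForceTerm] = [self.term, self.backbone]
        if self.anchor is not None:
            out.append(self.anchor)
        return out

    def to_dict(self) -> dict:
        return {
            "spring_scale": self.spring_scale,
            "barrier_kT": self.barrier,
            "beta_mix": self.beta_mix,
            "delta_v": self.delta_v,
            "n_pairs_of": int(self.term.basin_a.n_pairs),
            "n_pairs_if": int(self.term.basin_b.n_pairs),
            "n_angles": int(len(self.backbone.k)),
        }


def backbone_angle_term(ref: ReferencePair) -> AngleTerm:
    """Angle springs over consecutive bead triples of each helix.

    The middle bead of every helix is the designated kinkable bead and
    gets the softer ``k_kink`` spring.
    """
    spec = ref.spec
    m = spec.sites_per_helix
    triples = []
    springs = []
    kink = m // 2
    for h in range(spec.n_helices):
        base = h * m
        for b in range(1, m - 1):
            triples.append((base + b - 1, base + b, base + b + 1))
            springs.append(spec.k_kink if b == kink else spec.k_angle)
    return AngleTerm.with_reference(
        triples=np.array(triples, dtype=int),
        k=np.array(springs, dtype=float),
        reference=ref.of_state.coords,
    )


def cylindrical_morph(of: np.ndarray, if_: np.ndarray, t: float) -> np.ndarray:
    """Interpolated structure at fraction ``t`` along the gate-rotation path.

    Each bead's cylindrical coordinates (radius, azimuth, z) about the
    channel axis are interpolated linearly, with the azimuth taken along
    the shorter arc.  This tracks the tilting/rotating helix motion of
    the alternating-access transition far more closely than a Cartesian
    chord, which foreshortens every rotating distance.
    """
    r0 = np.hypot(of[:, 0], of[:, 1])
    r1 = np.hypot(if_[:, 0], if_[:, 1])
    th0 = np.arctan2(of[:, 1], of[:, 0])
    th1 = np.arctan2(if_[:, 1], if_[:, 0])
    dth = np.arctan2(np.sin(th1 - th0), np.cos(th1 - th0))
    r = (1 - t) * r0 + t * r1
    th = th0 + t * dth
    z = (1 - t) * of[:, 2] + t * if_[:, 2]
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def _path_energies(
    terms: Sequence[ForceTerm], of: np.ndarray, if_: np.ndarray, n_points: int = 101
) -> np.ndarray:
    ts = np.linspace(0.0, 1.0, n_points)
    energies = np.empty(n_points)
    for k, t in enumerate(ts):
        x = cylindrical_morph(of, if_, t)
        energies[k] = sum(term.energy_forces(x)[0] for term in terms)
    return energies


def _strained_masks(enm_of: ENMTerm, enm_if: ENMTerm, tol: float):
    """Per-pair masks of pairs whose rest length differs between basins."""
    rest_of = {
        (int(i), int(j)): r
        for i, j, r in zip(enm_of.pairs_i, enm_of.pairs_j, enm_of.rest_lengths)
    }
    rest_if = {
        (int(i), int(j)): r
        for i, j, r in zip(enm_if.pairs_i, enm_if.pairs_j, enm_if.rest_lengths)
    }

    def mask(term: ENMTerm, other: dict) -> np.ndarray:
        out = np.empty(term.n_pairs, dtype=bool)
        for p, (i, j, r) in enumerate(
            zip(term.pairs_i, term.pairs_j, term.rest_lengths)
        ):
            r2 = other.get((int(i), int(j)))
            out[p] = r2 is None or abs(r - r2) > tol
        return out

    return mask(enm_of, rest_if), mask(enm_if, rest_of)


def build_double_basin_spec(
    ref: ReferencePair, spec: ToyTransporterSpec | None = None
) -> DoubleBasinModel:
    """Build and calibrate the double-basin potential.

    Two elastic networks anchored at the OF and IF references are mixed
    through a log-sum-exp with inverse width ``beta_mix``.  Bisection on
    the spring factor of the strained pairs places the energy maximum
    along the 101-point linear OF->IF interpolation at
    ``barrier_height * kT`` above the OF end (within 5%).
    """
    spec = spec or ref.spec
    prot = ref.protein_indices
    of = ref.of_state.coords
    if_ = ref.if_state.coords
    # network = all pairs within enm_cutoff plus any state-degenerate pair
    # within strut_cutoff (the long cytoplasmic-top <-> matrix-bottom
    # struts of the opposite-twist construction)
    enm_of = ENMTerm.from_reference(
        of, spec.strut_cutoff, spec.enm_spring, indices=prot, name="enm_of"
    )
    enm_if = ENMTerm.from_reference(
        if_, spec.strut_cutoff, spec.enm_spring, indices=prot, name="enm_if"
    )

    def trim(term: ENMTerm, other: ENMTerm) -> ENMTerm:
        rest_other = {
            (int(i), int(j)): r
            for i, j, r in zip(other.pairs_i, other.pairs_j,
                               other.rest_lengths)
        }
        keep = np.array(
            [
                r <= spec.enm_cutoff
                or abs(r - rest_other.get((int(i), int(j)), np.inf)) < 1e-9
                for i, j, r in zip(term.pairs_i, term.pairs_j,
                                   term.rest_lengths)
            ]
        )
        return ENMTerm(
            term.pairs_i[keep], term.pairs_j[keep],
            term.rest_lengths[keep], term.spring[keep],
            term.n_sites, name=term.name,
        )

    enm_of, enm_if = trim(enm_of, enm_if), trim(enm_if, enm_of)
    strained_of, strained_if = _strained_masks(enm_of, enm_if, spec.strain_tol)
    backbone = backbone_angle_term(ref)
    anchor = None
    if spec.k_anchor > 0:
        a_idx = anchor_indices(spec)
        anchor = HarmonicTetherTerm(
            indices=a_idx, ref=of[a_idx].copy(), k=spec.k_anchor,
            name="membrane_anchor",
        )
    static_terms: list[ForceTerm] = (
        [backbone] if anchor is None else [backbone, anchor]
    )
    target = spec.barrier_height * spec.temperature

    # exactly state-degenerate pairs (identical rest length in both
    # basins, e.g. the cytoplasmic-top <-> matrix-bottom "struts" of the
    # opposite-twist construction) are reinforced: they cannot tilt either
    # basin or the symmetric path, but they price asymmetric, one-domain-
    # at-a-time crossings that would otherwise undercut the calibrated
    # barrier.
    rest_if_map = {
        (int(i), int(j)): r
        for i, j, r in zip(enm_if.pairs_i, enm_if.pairs_j, enm_if.rest_lengths)
    }
    degenerate_of = np.array(
        [
            abs(r - rest_if_map.get((int(i), int(j)), np.inf)) < 1e-9
            for i, j, r in zip(
                enm_of.pairs_i, enm_of.pairs_j, enm_of.rest_lengths
            )
        ]
    )
    rest_of_map = {
        (int(i), int(j)): r
        for i, j, r in zip(enm_of.pairs_i, enm_of.pairs_j, enm_of.rest_lengths)
    }
    degenerate_if = np.array(
        [
            abs(r - rest_of_map.get((int(i), int(j)), np.inf)) < 1e-9
            for i, j, r in zip(
                enm_if.pairs_i, enm_if.pairs_j, enm_if.rest_lengths
            )
        ]
    )

    def networks(scale: float) -> tuple[ENMTerm, ENMTerm]:
        a = enm_of.scaled(1.0)
        a.spring = np.where(strained_of, spec.enm_spring * scale, spec.enm_spring)
        a.spring = np.where(
            degenerate_of, spec.enm_spring * spec.strut_factor, a.spring
        )
        b = enm_if.scaled(1.0)
        b.spring = np.where(strained_if, spec.enm_spring * scale, spec.enm_spring)
        b.spring = np.where(
            degenerate_if, spec.enm_spring * spec.strut_factor, b.spring
        )
        return a, b

    def barrier_of(scale: float) -> tuple[float, np.ndarray]:
        a, b = networks(scale)
        term = DoubleBasinTerm(a, b, spec.beta_mix, spec.delta_v)
        e = _path_energies([term, *static_terms], of, if_)
        return float(e.max() - e[0]), e

    lo, hi = 1e-6, 1.0
    b_hi, _ = barrier_of(hi)
    n_grow = 0
    while b_hi < target:
        hi *= 2.0
        b_hi, _ = barrier_of(hi)
        n_grow += 1
        if n_grow > 20:
            raise CalibrationError(
                f"cannot reach target barrier {target:.3g} kT "
                f"(got {b_hi:.3g} at scale {hi:.3g})"
            )
    b_lo, _ = barrier_of(lo)
    if b_lo > target:
        raise CalibrationError(
            f"barrier {b_lo:.3g} kT exceeds target {target:.3g} even with "
            "vanishing strained springs; the conserved-contact network is "
            "too strained along the path"
        )
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if barrier_of(mid)[0] < target:
            lo = mid
        else:
            hi = mid
        if (hi - lo) < 1e-7 * hi:
            break
    scale = 0.5 * (lo + hi)
    barrier, energies = barrier_of(scale)
    if abs(barrier - target) > 0.05 * target:
        raise CalibrationError(
            f"calibrated barrier {barrier:.3g} misses target {target:.3g}"
        )
    a, b = networks(scale)
    term = DoubleBasinTerm(
        basin_a=a, basin_b=b, beta_mix=spec.beta_mix, delta_v=spec.delta_v
    )
    return DoubleBasinModel(
        term=term,
        backbone=backbone,
        anchor=anchor,
        spring_scale=scale,
        barrier=barrier / spec.temperature,
        path_energies=energies,
        beta_mix=spec.beta_mix,
        delta_v=spec.delta_v,
        protein_indices=prot,
    )


# ---------------------------------------------------------------------------
# Tracers
# ---------------------------------------------------------------------------


def add_tracers(
    ref: ReferencePair, spec: ToyTransporterSpec | None = None
) -> ReferencePair:
    """Append tracer particles in a slab above the cytoplasmic gate.

    Tracers are seeded uniformly in a cylinder over the channel mouth,
    clear of the protein's repulsion core, identically in both reference
    frames.  ``n_tracers = 0`` returns an equivalent pair unchanged.
    """
    spec = spec or ref.spec
    if spec.n_tracers == 0:
        return ref
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(spec.seed, spawn_key=(7,)))
    )
    z_lo = ref.spec.z_half + spec.tracer_sigma + 0.5
    z_hi = z_lo + 4.0
    r_max = 8.0
    pts = np.empty((spec.n_tracers, 3))
    rr = r_max * np.sqrt(rng.random(spec.n_tracers))
    th = 2 * np.pi * rng.random(spec.n_tracers)
    pts[:, 0] = rr * np.cos(th)
    pts[:, 1] = rr * np.sin(th)
    pts[:, 2] = z_lo + (z_hi - z_lo) * rng.random(spec.n_tracers)
    tracer_sites = [
        Site(site_id=0, name=f"W{i + 1}", domain="S",
             group_tags=frozenset({"tracer"}))
        for i in range(spec.n_tracers)
    ]
    topology = ref.topology.with_sites_appended(tracer_sites)
    of = np.vstack([ref.of_state.coords, pts])
    if_ = np.vstack([ref.if_state.coords, pts])
    return ReferencePair(
        of_state=Frame(of, time=0.0),
        if_state=Frame(if_, time=0.0),
        topology=topology,
        spec=spec,
    )


def make_force_terms(
    ref: ReferencePair,
    db: DoubleBasinModel,
    spec: ToyTransporterSpec | None = None,
) -> list[ForceTerm]:
    """Assemble the full term list: landscape plus tracer terms if present."""
    spec = spec or ref.spec
    terms: list[ForceTerm] = list(db.terms)
    tracers = ref.tracer_indices
    if len(tracers):
        prot = ref.protein_indices
        terms.append(
            SoftCoreRepulsion(
                group_a=tracers,
                group_b=prot,
                sigma=spec.tracer_sigma,
                k=spec.tracer_k,
                name="tracer_repulsion",
            )
        )
        terms.append(
            ChannelWallTerm(
                tracer_idx=tracers,
                gate_cyt_idx=ref.topology.indices_with_tag("gate_cyt"),
                gate_mat_idx=ref.topology.indices_with_tag("gate_mat"),
                z_gate_cyt=spec.z_half,
                z_gate_mat=-spec.z_half,
                r_closed_cyt=spec.gate_radius_cyt_IF,
                r_closed_mat=spec.gate_radius_mat_OF,
            )
        )
    return terms


def rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def domain_permutation(spec: ToyTransporterSpec) -> np.ndarray:
    """Site permutation induced by a 120-degree rotation about z.

    Maps each protein site to the corresponding site two helices over
    (the next domain); used to check exact three-fold symmetry.
    """
    n_h = spec.n_helices
    m = spec.sites_per_helix
    perm = np.empty(spec.n_protein_sites, dtype=int)
    for h in range(n_h):
        h2 = (h + spec.helices_per_domain) % n_h
        for b in range(m):
            perm[h * m + b] = h2 * m + b
    return perm


def symmetry_mismatch(coords: np.ndarray, spec: ToyTransporterSpec) -> float:
    """Max |R120 x_i - x_perm(i)| over protein sites (0 for exact symmetry)."""
    rot = rotation_z(2.0 * np.pi / spec.n_domains)
    perm = domain_permutation(spec)
    n = spec.n_protein_sites
    rotated = coords[:n] @ rot.T
    return float(np.abs(rotated - coords[perm]).max())
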