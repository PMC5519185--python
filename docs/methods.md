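# Methods

## The method

`lrpath` implements linear-response path following (LRPF), an iterative
biased-dynamics scheme for driving large conformational transitions that
spontaneous simulation cannot reach.  The core identity is the static
linear-response (fluctuation–dissipation) relation: for a system
fluctuating about a mean structure with positional variance–covariance
matrix **C** (3N×3N, taken about the superposed mean), a small constant
force **f** shifts the mean by

    Δ⟨r⟩ = β C f,     β = 1/kT.

A sparse, functionally motivated *perturbative* force — applied at a few
sites chosen for their mechanistic role — therefore predicts a dense,
global displacement field.  The *biasing* force actually applied during
biased segments is taken parallel to that displacement field, rescaled so
the largest per-site force norm equals `f_max`.  One LRPF cycle is:

1. run a biased segment with the current bias field applied to every
   protein site;
2. run an unbiased relaxation segment;
3. re-estimate the mean structure and covariance from the unbiased
   segment;
4. re-derive the perturbative force directions from the new mean
   (site identities are fixed by tags; directions refresh every cycle);
5. produce the next bias field via the response relation.

Iterating makes the linear prediction follow a strongly nonlinear path.
Cycles stop when a declarative monitor fires (e.g. RMSD to a target
basin dropping below a threshold), when a cycle budget is exhausted, or
on engine failure.  Monitors are evaluated on the unbiased-segment
*mean structures*: the mean is what the covariance model describes, and
it suppresses the thermal scatter that instantaneous frames carry.

Two perturbation designs are built in, mirroring the alternating-access
use case: an *outward push* (radial forces on the matrix-motif acidic
sites, opening the matrix half) and a *pair contraction* (equal and
opposite forces shrinking chosen inter-domain distances, closing the
cytoplasmic half).  Both designs are exactly three-fold symmetric on
symmetric inputs, and the response relation transports that symmetry to
the bias field; any asymmetry of the realized path is therefore a
property of the sampled dynamics, and the per-domain displacement
monitor logs it each cycle.

## The toy transporter

The synthetic system is a pseudo three-fold-symmetric bundle of six bead
helices (two per domain, 8 beads each, 48 protein sites) spanning a
24-unit membrane slab, emulating a mitochondrial-carrier-like
transporter:

* **even helices** carry the cytoplasmic gate at their top beads: ring
  radius 13 model units in the outward-facing (OF) state, 9 in the
  inward-facing (IF) state.  13 and 9 model units are the channel
  radius-of-gyration values characteristic of the open and closed
  cytoplasmic channel of mitochondrial-carrier transporters, adopted
  here as the defining geometry;
* **odd helices** carry the matrix gate at their bottom beads, with the
  radii reversed (9 in OF, 13 in IF); these beads double as the acidic
  MCF-motif analogs and receive the outward-push perturbation;
* the mobile helix ends also rotate azimuthally by 15° between states,
  with *opposite* senses for even and odd helices.  This choice makes
  every cytoplasmic-top↔matrix-bottom bead distance exactly equal in
  the two states (the radii swap while the azimuthal offset is
  preserved), which the potential exploits (below);
* beads carry a small helical decoration (amplitude 1.2, period 3.6
  beads, windowed to zero at the helix ends so gate and anchor beads sit
  exactly on their nominal rings).  Perfectly straight bead rods have
  zero transverse pair-spring stiffness; the decoration gives the
  elastic network generic spring directions;
* the six helix ends whose positions are common to both states are
  softly pinned (k = 10) to those positions — a membrane-scaffold
  surrogate that suppresses whole-body wobble of the embedded bundle.

OF→IF separation is ≈2.6 model units of Cα-equivalent RMSD; equilibrium
thermal scatter about either basin is ≈0.3 (trailing-mean structures) —
comfortably inside the 1.5-unit monitor thresholds.

### Double-basin potential and barrier calibration

The protein potential is the smooth log-sum-exp mixture of two elastic
networks anchored at the OF and IF references,

    E = −(1/β_mix) ln( e^{−β_mix (V_OF + ΔV)} + e^{−β_mix V_IF} ),

plus a backbone angle term, V = k/2 (cos θ − cos θ₀)², with rest angles
from the reference geometry (zero in both basins, smooth everywhere,
soft at the designated mid-helix "kink" bead), plus the anchor tethers.
β_mix = 2 (inverse energy) keeps the crossover sharp; ΔV = 0 gives
degenerate basins.

Calibration targets a prescribed barrier (default 12 kT) along a
*cylindrical morph*: each bead's radius, azimuth (shorter arc) and z are
interpolated linearly between the states.  This path tracks the
tilting/rotating helix motion; a Cartesian chord would foreshorten every
rotating distance and count avoidable strain as "barrier" that real
trajectories never pay.  The bisection variable is a common spring
factor applied to the *strained* pairs only — those whose rest length
differs between the basins by more than `strain_tol` (0.5) or that
exist in only one network.  Conserved contacts keep their full
stiffness, so the thermal amplitudes of the non-transition modes are
unaffected by the barrier choice; only the transition directions soften
to meet the target.  The exactly state-degenerate pairs (notably the
long cytoplasmic-top↔matrix-bottom "struts" created by the
opposite-twist construction) are reinforced fourfold: they cannot tilt
either basin or the symmetric path, but they price asymmetric,
one-domain-at-a-time crossings that would otherwise undercut the
calibrated barrier.

With these choices the calibrated 12 kT is the barrier trajectories
actually feel: ten 40 000-step unbiased runs show no basin escape (and
none in the paired benchmark controls), while the same landscape remains
crossable under bias.

### Tracers and the channel surrogate

Optional tracer particles emulate the water-distribution analyses.
Tracers feel (i) a truncated harmonic soft-core repulsion from every
protein bead, (ii) a confining box, and (iii) an analytic channel wall:
a body term excluding them from the protein annulus (5 < ρ < 16 over
the membrane span) and two gate walls, each covering its entire
half-channel, with penalty k/2·(ρ − a)² beyond the aperture
a = R_gate − r_closed − 1, where R_gate is the *instantaneous* mean
radial distance of that gate's ring beads (reaction forces on the ring
beads included, so forces remain exact gradients).  A closed ring gives
a negative aperture — the whole half excludes tracers, as water is
excluded from the packed closed side of a carrier — while an open ring
leaves an axial corridor.  Three beads per ring cannot sterically
occlude a channel mouth, so this aperture coupling, not pair repulsion,
carries the gating; the pair term only provides excluded volume.  All
wall pieces are C¹ (cos² windows, quartic bumps).

What the toy does *not* emulate: atomistic packing and electrostatics,
lipids, explicit solvent thermodynamics, the substrate.  Passing tests
demonstrate the correctness and the qualitative phenomenology of the
method (covariance→response→bias chain, barrier-limited kinetics,
gated solvent access), not force-field realism.

## Engine

BAOAB-split Langevin dynamics; unit masses; temperature in kT units
(k_B = 1).  Defaults: friction γ = 1 /time, dt = 0.02 time units
(stability guard dt·γ < 0.5; the stiffest default force constants give
ω·dt ≈ 0.2).  Noise reproducibility: the normals for step s of a stage
are a fixed function of (seed, stage, s) — a Philox counter stream
advanced to the step index, with Box–Muller conversion so the per-step
draw count is constant.  Segment boundaries therefore cannot change the
noise sequence, which yields the exact null-bias contract: an LRPF run
with f_max = 0 is bit-identical to one continuous unbiased run at the
same seed.  Initial velocities, when not supplied, come from a separate
Maxwell–Boltzmann stream keyed by the same (seed, stage).

Steered segments move a harmonic restraint center at constant velocity
and accumulate the work W = Σ k (x₀ − q) v dt; targeted segments
restrain the superposed RMSD to a target structure, with the gradient
through the optimal rigid fit taken by the envelope theorem.  Nonbonded
tracer interactions are evaluated as dense group×group distance
rectangles — at ≤ 200 sites this is faster than any neighbor list.

## Covariance estimation

Frames are rigid-body superposed onto the iterated mean structure (two
refits) before moments are taken, removing the diffusive rigid-body
component that would otherwise dominate C.  The estimate is shrunk
toward its diagonal, Ĉ = (1−λ) S + λ diag(S), λ = 0.05 by default: a
3N×3N covariance from a few hundred frames is rank-deficient, and mild
shrinkage stabilizes the matrix–vector product without measurably
rotating the well-sampled directions (the harmonic self-test recovers
the analytic response to a few percent with this λ).  Bias
normalization is by the maximum per-site force norm, which bounds the
strongest force applied to any site regardless of system size or
covariance conditioning.

## Benchmark problem sizes

The canonical benchmark uses 1500-step biased and unbiased segments
(covariance from 300 frames at stride 5), f_max = 1.0, a 40-cycle
budget, and ten seeds, with unbiased controls matched per seed to the
total step count their LRPF run consumed, and stability continuations of
ten times each run's biased duration.  These sizes put the whole
benchmark at a few minutes on one core while keeping every quantity
well-resolved: the harmonic response and covariance oracles use 5·10⁴
saved frames, where the sampling error of the covariance is ≈3%.

## Numerical and design notes

* Selections are a small boolean grammar over name/domain/helix/tag
  atoms; ties and orderings are deterministic (ascending site indices).
* Monitors fire on threshold crossings of mean-structure metrics; among
  simultaneous firings the first in config order wins.  A plateau
  monitor (least-squares slope over a trailing window) is available for
  runs without a known target.
* Kabsch superposition corrects reflections by flipping the smallest
  singular direction; collinear inputs raise rather than returning a
  garbage rotation.  An independent quaternion-eigenvalue oracle is used
  in the tests, never in the implementation path.
* Occupancy grids use half-open voxel membership ([lo, hi) per axis), so
  faces never double count and occupancies are exact rationals
  k/window.
* Contact/salt-bridge/H-bond cutoffs default to 4.5 / 4.0 / 3.5 length
  units with a 0.5 hysteresis margin on the salt-bridge formed/broken
  track — field-standard surrogates, all configurable.  Bead models
  carry no donor-antecedent geometry, so the H-bond criterion is
  distance-only.
* The helix angle is the angle between the dominant principal axis of
  the centered selection and a reference axis, folded into [0°, 90°];
  isotropic clouds raise a degenerate-axis error.
* PDB output repurposes the B-factor column for per-site scalars (e.g.
  bias-force magnitudes) so standard viewers can color by them.

## Known limitations

* The linear-response step assumes near-Gaussian fluctuations within a
  cycle; strongly anharmonic intermediates are handled only through the
  iterative refresh, not within a cycle.
* The toy's barrier is calibrated along a fixed morph; the true saddle
  can sit slightly below the calibrated value (the struts bound, but do
  not eliminate, path relaxation).
* Tracer thermodynamics are schematic: walls are analytic and
  solvent–solvent interactions are absent, so occupancy contrasts are
  qualitative.
* `estimate_covariance` stores dense 3N×3N matrices; the intended scale
  is coarse-grained (hundreds of sites), not atomistic.
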