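"""Trajectory analysis: superposition RMSD, helix angles, contacts,
salt bridges, hydrogen-bond surrogates, occupancy grids, gate radius of
gyration, region counts and RMSF.

All distance-based metrics are invariant under a global rigid motion
applied uniformly to every frame.  Default cutoffs (hydrophobic contact
4.5, salt bridge 4.0, H-bond 3.5, hysteresis margin 0.5 length units) are
field-standard surrogates and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .topology import SiteModel, resolve_selection
from .trajectory import Frame, Trajectory

DEFAULT_CONTACT_CUTOFF = 4.5
DEFAULT_SALTBRIDGE_CUTOFF = 4.0
DEFAULT_HBOND_CUTOFF = 3.5
DEFAULT_HYSTERESIS_MARGIN = 0.5


class DegenerateGeometryError(ValueError):
    """Raised for rank-deficient or otherwise degenerate geometry."""


@dataclass
class MetricSeries:
    """A named per-frame scalar (or boolean) time series."""

    name: str
    times: np.ndarray
    values: np.ndarray
    selection: str = ""
    events: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.  The
    rotation is proper (det = +1); reflections are corrected by flipping
    the smallest singular direction.

    Raises DegenerateGeometryError for fewer than 3 sites or collinear
    configurations (rank < 2 cross-covariance).
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N x 3 arrays")
    n = x.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs >= 3 sites")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    xc = x - w @ x
    yc = y - w @ y
    h = (w[:, None] * xc).T @ yc  # cross-covariance
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(1.0, s[0]):
        raise DegenerateGeometryError(
            "collinear or degenerate configuration (rank < 2)"
        )
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = (w @ y) - (w @ x) @ rot.T
    resid = xc @ rot.T - yc
    rmsd = float(np.sqrt(np.sum(w[:, None] * resid**2)))
    return rot, trans, rmsd


def rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Superposed RMSD between two coordinate sets."""
    return kabsch_superpose(mobile, reference, weights)[2]


def rmsd_timeseries(
    traj: Trajectory,
    reference: Frame | np.ndarray,
    selection=None,
) -> MetricSeries:
    """Per-frame superposed RMSD to a reference over a selection."""
    ref = reference.coords if isinstance(reference, Frame) else np.asarray(reference)
    idx = resolve_selection(
        traj.topology if traj.topology is not None else _dummy_top(ref.shape[0]),
        selection,
    )
    ref_sel = ref[idx] if ref.shape[0] != len(idx) else ref
    values = np.array(
        [rmsd(f.coords[idx], ref_sel) for f in traj.frames]
    )
    return MetricSeries("rmsd", traj.times, values,
                        selection=str(selection) if selection is not None else "all")


def _dummy_top(n: int) -> SiteModel:
    from .topology import Site

    return SiteModel([Site(i, f"S{i}", "A") for i in range(n)])


# ---------------------------------------------------------------------------
# Helix geometry
# ---------------------------------------------------------------------------


def helix_angle(
    frame: Frame | np.ndarray,
    selection: Sequence[int] | np.ndarray,
    reference_axis=(0.0, 0.0, 1.0),
) -> float:
    """Tilt of a helix: angle between its dominant principal axis and a
    reference axis, folded into [0, 90] degrees.

    The dominant axis is the largest-variance direction of the centered
    selection coordinates.  Raises DegenerateGeometryError when no
    dominant direction exists (isotropic cloud).
    """
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame)
    idx = np.asarray(selection, dtype=int)
    if len(idx) < 3:
        raise DegenerateGeometryError("helix angle needs >= 3 sites")
    x = coords[idx]
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) < 1e-9 * max(evals[-1], 1e-30):
        raise DegenerateGeometryError("no dominant principal axis")
    axis = evecs[:, -1]
    ref = np.asarray(reference_axis, dtype=float)
    ref = ref / np.linalg.norm(ref)
    cosang = abs(float(axis @ ref))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def helix_angle_series(
    traj: Trajectory, selection, reference_axis=(0.0, 0.0, 1.0)
) -> MetricSeries:
    idx = resolve_selection(traj.topology, selection)
    values = np.array(
        [helix_angle(f, idx, reference_axis) for f in traj.frames]
    )
    return MetricSeries("helix_angle", traj.times, values, selection=str(selection))


# ---------------------------------------------------------------------------
# Contacts / salt bridges / H-bonds
# ---------------------------------------------------------------------------


def _min_distances(traj: Trajectory, idx_a, idx_b) -> np.ndarray:
    return np.array(
        [cdist(f.coords[idx_a], f.coords[idx_b]).min() for f in traj.frames]
    )


def contact_series(
    traj: Trajectory,
    sel_a,
    sel_b,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    mode: Literal["min_distance", "fraction_pairs"] = "min_distance",
) -> MetricSeries:
    """Per-frame inter-group contact metric.

    ``min_distance`` reports the minimum inter-selection distance;
    ``fraction_pairs`` the fraction of cross pairs within ``cutoff``.
    Either way a boolean ``in_contact`` track at the cutoff is attached
    in ``events``.
    """
    top = traj.topology if traj.topology is not None else _dummy_top(
        traj.frames[0].n_sites
    )
    idx_a = resolve_selection(top, sel_a)
    idx_b = resolve_selection(top, sel_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("contact selections must be non-empty")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("contact selections must be disjoint")
    if mode == "min_distance":
        values = _min_distances(traj, idx_a, idx_b)
        in_contact = values < cutoff
    elif mode == "fraction_pairs":
        values = np.array(
            [
                float(np.mean(cdist(f.coords[idx_a], f.coords[idx_b]) < cutoff))
                for f in traj.frames
            ]
        )
        in_contact = values > 0
    else:
        raise ValueError(f"unknown contact mode {mode!r}")
    return MetricSeries(
        f"contact_{mode}",
        traj.times,
        values,
        selection=f"{sel_a} | {sel_b}",
        events={"in_contact": in_contact},
    )


def saltbridge_series(
    traj: Trajectory,
    acidic_sel,
    basic_sel,
    cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF,
    margin: float = DEFAULT_HYSTERESIS_MARGIN,
) -> MetricSeries:
    """Minimum acidic–basic distance with a hysteretic formed/broken track.

    The bridge forms when the distance drops below ``cutoff`` and only
    breaks when it exceeds ``cutoff + margin``, suppressing flicker from
    frames oscillating inside the margin.  Symmetric in the two
    selections.
    """
    top = traj.topology if traj.topology is not None else _dummy_top(
        traj.frames[0].n_sites
    )
    idx_a = resolve_selection(top, acidic_sel)
    idx_b = resolve_selection(top, basic_sel)
    values = _min_distances(traj, idx_a, idx_b)
    formed = np.zeros(len(values), dtype=bool)
    state = values[0] < cutoff
    events_form = []
    events_break = []
    for i, d in enumerate(values):
        if not state and d < cutoff:
            state = True
            events_form.append(i)
        elif state and d > cutoff + margin:
            state = False
            events_break.append(i)
        formed[i] = state
    return MetricSeries(
        "saltbridge",
        traj.times,
        values,
        selection=f"{acidic_sel} | {basic_sel}",
        events={
            "formed": formed,
            "form_events": np.array(events_form, dtype=int),
            "break_events": np.array(events_break, dtype=int),
        },
    )


def hbond_series(
    traj: Trajectory,
    donor_sel,
    acceptor_sel,
    d_cut: float = DEFAULT_HBOND_CUTOFF,
) -> MetricSeries:
    """Distance-criterion hydrogen-bond surrogate for bead models.

    A frame is "bonded" when the minimum donor–acceptor distance is below
    ``d_cut``.  (Bead models carry no donor-antecedent geometry, so no
    angle criterion applies.)  ``events['fraction_bonded']`` gives the
    bonded fraction over the series.
    """
    top = traj.topology if traj.topology is not None else _dummy_top(
        traj.frames[0].n_sites
    )
    idx_d = resolve_selection(top, donor_sel)
    idx_a = resolve_selection(top, acceptor_sel)
    values = _min_distances(traj, idx_d, idx_a)
    bonded = values < d_cut
    return MetricSeries(
        "hbond",
        traj.times,
        values,
        selection=f"{donor_sel} | {acceptor_sel}",
        events={"bonded": bonded, "fraction_bonded": float(bonded.mean())},
    )


# ---------------------------------------------------------------------------
# Occupancy grids and region counts
# ---------------------------------------------------------------------------


@dataclass
class OccupancyGrid:
    """Regular voxel grid of per-voxel occupancy fractions in [0, 1].

    Voxel membership is half-open [lo, hi) per axis so faces never double
    count; occupancy is the exact rational k/window.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    values: np.ndarray
    window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.dims):
            raise ValueError("values shape does not match dims")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("occupancy values must lie in [0, 1]")

    def threshold_mask(self, level: float) -> np.ndarray:
        """Boolean mask of voxels at or above the contour level."""
        return self.values >= level

    def voxel_of(self, point) -> tuple[int, int, int]:
        ijk = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        return tuple(ijk)

    def write_dx(self, path) -> None:
        """Write as an OpenDX-style scalar field."""
        nx, ny, nz = self.dims
        with open(path, "w") as fh:
            fh.write(
                f"object 1 class gridpositions counts {nx} {ny} {nz}\n"
                f"origin {self.origin[0]:.6f} {self.origin[1]:.6f} "
                f"{self.origin[2]:.6f}\n"
                f"delta {self.spacing:.6f} 0 0\n"
                f"delta 0 {self.spacing:.6f} 0\n"
                f"delta 0 0 {self.spacing:.6f}\n"
                f"object 2 class gridconnections counts {nx} {ny} {nz}\n"
                f"object 3 class array type double rank 0 items "
                f"{nx * ny * nz} data follows\n"
            )
            flat = self.values.ravel()
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6f}" for v in flat[i : i + 3]) + "\n")


def occupancy_grid(
    traj: Trajectory,
    selection,
    spacing: float = 1.0,
    window: int | None = None,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
) -> OccupancyGrid:
    """Per-voxel fraction of trailing-window frames containing a selected site.

    ``window`` counts frames from the end of the trajectory (the "last
    portion" convention); default is all frames.  The grid extent defaults
    to the bounding box of the selected sites over the window.
    """
    top = traj.topology if traj.topology is not None else _dummy_top(
        traj.frames[0].n_sites
    )
    idx = resolve_selection(top, selection)
    n = traj.n_frames
    if window is None:
        window = n
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}]")
    frames = traj.frames[n - window :]
    pts = np.array([f.coords[idx] for f in frames])  # (window, k, 3)
    if origin is None or dims is None:
        lo = pts.reshape(-1, 3).min(axis=0)
        hi = pts.reshape(-1, 3).max(axis=0)
        if np.any(hi - lo < 0):
            raise ValueError("zero-volume bounding box")
        origin = lo
        dims = tuple(
            (np.floor((hi - origin) / spacing).astype(int) + 1).tolist()
        )
    origin = np.asarray(origin, dtype=float)
    counts = np.zeros(dims, dtype=int)
    for fpts in pts:
        ijk = np.floor((fpts - origin) / spacing).astype(int)
        ok = np.all((ijk >= 0) & (ijk < np.array(dims)), axis=1)
        ijk = np.unique(ijk[ok], axis=0)
        if len(ijk):
            counts[ijk[:, 0], ijk[:, 1], ijk[:, 2]] += 1
    return OccupancyGrid(
        origin=origin,
        spacing=spacing,
        dims=tuple(dims),
        values=counts / window,
        window=(n - window, n),
    )


def count_in_region(
    traj: Trajectory,
    selection,
    region: dict,
) -> MetricSeries:
    """Per-frame count of selected sites inside a region.

    ``region`` is ``{"kind": "z_slab", "z_min": ..., "z_max": ...,
    "r_max": optional radial bound}`` or ``{"kind": "sphere",
    "center": (x,y,z), "radius": r}``.
    """
    top = traj.topology if traj.topology is not None else _dummy_top(
        traj.frames[0].n_sites
    )
    idx = resolve_selection(top, selection)
    kind = region.get("kind")
    values = np.zeros(traj.n_frames, dtype=int)
    if len(idx):
        if kind == "z_slab":
            zmin, zmax = float(region["z_min"]), float(region["z_max"])
            rmax = region.get("r_max")
            for t, f in enumerate(traj.frames):
                x = f.coords[idx]
                inside = (x[:, 2] >= zmin) & (x[:, 2] < zmax)
                if rmax is not None:
                    inside &= np.hypot(x[:, 0], x[:, 1]) < float(rmax)
                values[t] = int(inside.sum())
        elif kind == "sphere":
            c = np.asarray(region["center"], dtype=float)
            r = float(region["radius"])
            for t, f in enumerate(traj.frames):
                values[t] = int(
                    (np.linalg.norm(f.coords[idx] - c, axis=1) < r).sum()
                )
        else:
            raise ValueError(f"unknown region kind {kind!r}")
    return MetricSeries("count_in_region", traj.times, values,
                        selection=str(selection))


# ---------------------------------------------------------------------------
# Gate radius of gyration and RMSF
# ---------------------------------------------------------------------------


def gate_rg(
    frame: Frame | np.ndarray,
    gate_selection,
    axis_projection: bool = False,
) -> float:
    """RMS distance of gate sites from their centroid (channel-closure metric).

    With ``axis_projection`` the computation uses only the x/y components,
    i.e. the plane normal to the channel (z) axis.
    """
    coords = frame.coords if isinstance(frame, Frame) else np.asarray(frame)
    idx = np.asarray(gate_selection, dtype=int)
    if len(idx) < 2:
        raise DegenerateGeometryError("gate Rg needs >= 2 sites")
    x = coords[idx]
    if axis_projection:
        x = x[:, :2]
    xc = x - x.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(xc**2, axis=1))))


def gate_rg_series(traj: Trajectory, gate_selection,
                   axis_projection: bool = False) -> MetricSeries:
    idx = resolve_selection(traj.topology, gate_selection)
    values = np.array(
        [gate_rg(f, idx, axis_projection) for f in traj.frames]
    )
    return MetricSeries("gate_rg", traj.times, values, selection=str(gate_selection))


def rmsf(
    traj: Trajectory,
    selection=None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-site root-mean-square fluctuation about the (superposed) mean.

    Frames are iteratively superposed onto the running mean structure
    before moments are taken, so a rigid-body motion shared by all frames
    contributes nothing.
    """
    top = traj.topology if traj.topology is not None else _dummy_top(
        traj.frames[0].n_sites
    )
    idx = resolve_selection(top, selection)
    if traj.n_frames < 2:
        raise ValueError("RMSF needs >= 2 frames")
    coords = np.array([f.coords[idx] for f in traj.frames])
    if superpose and len(idx) >= 3:
        coords = superpose_frames(coords)
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def superpose_frames(coords: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Superpose each frame onto the iterated mean structure.

    ``coords`` is (n_frames, N, 3); two iterations of mean-refit are
    enough for the mean to stop moving at the tolerances used here.
    """
    out = np.array(coords, dtype=float, copy=True)
    mean = out[0]
    for _ in range(n_iter):
        for t in range(out.shape[0]):
            rot, trans, _ = kabsch_superpose(out[t], mean)
            out[t] = out[t] @ rot.T + trans
        mean = out.mean(axis=0)
    return out
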