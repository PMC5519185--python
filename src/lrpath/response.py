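"""Linear-response core: covariance estimation and bias-field derivation.

Linear response theory relates the mean conformational shift of a system
under a small constant force f to its unperturbed positional fluctuations:

    d<r> = beta * C * f,      beta = 1 / kT,

where C is the 3N x 3N variance-covariance matrix of positions about the
mean structure.  A sparse, functionally motivated *perturbative* force
applied at a few sites therefore predicts a dense global displacement
field; normalizing that field gives the *biasing* force actually applied
to every site during the biased segments of an LRPF cycle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .metrics import superpose_frames
from .topology import SiteModel, resolve_selection
from .trajectory import Trajectory


@dataclass
class CovarianceModel:
    """Mean structure plus positional covariance at temperature T.

    ``selection`` maps the model's local site order to topology indices.
    ``covariance`` is symmetric PSD after shrinkage regularization
    C_hat = (1 - lambda) S + lambda diag(S).
    """

    mean_coords: np.ndarray  # (n_sel, 3)
    covariance: np.ndarray  # (3 n_sel, 3 n_sel)
    n_frames: int
    temperature: float
    shrinkage: float
    selection: np.ndarray  # topology indices, ascending
    singular: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        n3 = 3 * self.mean_coords.shape[0]
        if self.covariance.shape != (n3, n3):
            raise ValueError("covariance shape does not match mean structure")

    @property
    def n_sites(self) -> int:
        return self.mean_coords.shape[0]

    def save(self, path) -> None:
        """Write the model as a binary .npz plus a JSON sidecar carrying
        shape, temperature, shrinkage and frame-count provenance."""
        path = Path(path)
        np.savez(
            path,
            mean_coords=self.mean_coords,
            covariance=self.covariance,
            selection=self.selection,
        )
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "n_sites": int(self.n_sites),
                    "n_frames": int(self.n_frames),
                    "temperature": self.temperature,
                    "shrinkage": self.shrinkage,
                    "singular": self.singular,
                }
            )
        )

    @classmethod
    def load(cls, path) -> "CovarianceModel":
        path = Path(path)
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        arrays = np.load(npz_path)
        meta = json.loads(npz_path.with_suffix(".json").read_text())
        return cls(
            mean_coords=arrays["mean_coords"],
            covariance=arrays["covariance"],
            n_frames=meta["n_frames"],
            temperature=meta["temperature"],
            shrinkage=meta["shrinkage"],
            selection=arrays["selection"],
            singular=meta["singular"],
        )

    def local_index(self, site: int) -> int:
        pos = np.searchsorted(self.selection, site)
        if pos >= len(self.selection) or self.selection[pos] != site:
            raise KeyError(f"site {site} not in covariance selection")
        return int(pos)


@dataclass
class PerturbationSet:
    """Sparse local perturbative forces: (site index, 3-vector) entries."""

    entries: list[tuple[int, np.ndarray]]
    label: str = "perturbation"

    def __post_init__(self) -> None:
        self.entries = [
            (int(i), np.asarray(v, dtype=float)) for i, v in self.entries
        ]
        for i, v in self.entries:
            if v.shape != (3,):
                raise ValueError("perturbation vectors must be 3-vectors")
            if not np.all(np.isfinite(v)):
                raise ValueError("non-finite perturbation vector")

    def dense(self, model: CovarianceModel) -> np.ndarray:
        """Zero-padded (n_sel, 3) force array in the model's local order."""
        f = np.zeros((model.n_sites, 3))
        for site, vec in self.entries:
            f[model.local_index(site)] += vec
        return f

    def scaled(self, factor: float) -> "PerturbationSet":
        return PerturbationSet(
            [(i, v * factor) for i, v in self.entries], label=self.label
        )


@dataclass
class BiasField:
    """Dense biasing forces over the full topology.

    The maximum per-site force norm equals ``f_max`` whenever the field is
    nonzero; ``source`` records the perturbation label and covariance
    provenance.
    """

    forces: np.ndarray  # (N_topology, 3)
    f_max: float
    source: str = ""

    def max_site_norm(self) -> float:
        return float(np.linalg.norm(self.forces, axis=1).max())

    def is_zero(self) -> bool:
        return not np.any(self.forces)


def estimate_covariance(
    traj: Trajectory,
    selection=None,
    superpose: bool = True,
    shrinkage: float = 0.05,
    temperature: float = 1.0,
) -> CovarianceModel:
    """Positional mean and covariance from an unbiased trajectory segment.

    When ``superpose`` is set, every frame is rigid-body superposed onto
    the iterated mean structure before moments are taken, removing
    diffusion of the overall position and orientation.  Shrinkage toward
    the diagonal, C_hat = (1-l) S + l diag(S), keeps the matrix
    well-conditioned when frames are few relative to 3N.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance needs >= 2 frames")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    top = traj.topology
    if top is None:
        from .metrics import _dummy_top

        top = _dummy_top(traj.frames[0].n_sites)
    idx = resolve_selection(top, selection)
    if len(idx) == 0:
        raise ValueError("empty covariance selection")
    if traj.n_frames < 10:
        warnings.warn(
            f"covariance from only {traj.n_frames} frames", stacklevel=2
        )
    coords = np.array([f.coords[idx] for f in traj.frames])
    if superpose and len(idx) >= 3:
        coords = superpose_frames(coords)
    mean = coords.mean(axis=0)
    x = (coords - mean).reshape(traj.n_frames, -1)
    s = (x.T @ x) / traj.n_frames
    c = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
    c = 0.5 * (c + c.T)
    singular = bool(np.linalg.eigvalsh(c).min() < 1e-12) if shrinkage == 0 else False
    return CovarianceModel(
        mean_coords=mean,
        covariance=c,
        n_frames=traj.n_frames,
        temperature=temperature,
        shrinkage=shrinkage,
        selection=idx,
        singular=singular,
    )


def predict_response(
    model: CovarianceModel, perturb: PerturbationSet
) -> np.ndarray:
    """Linear-response displacement field d<r> = beta C f, shape (n_sel, 3)."""
    f = perturb.dense(model).ravel()
    disp = model.covariance @ f / model.temperature
    return disp.reshape(-1, 3)


def build_bias(
    displacement: np.ndarray,
    f_max: float,
    *,
    n_topology: int | None = None,
    selection: np.ndarray | None = None,
    source: str = "",
) -> BiasField:
    """Biasing forces parallel to the displacement field, rescaled so the
    largest per-site force norm equals ``f_max``.

    A zero displacement field maps to a zero field (with a warning): the
    response direction is then undefined and no bias should be applied.
    """
    if f_max < 0:
        raise ValueError("f_max must be >= 0")
    disp = np.asarray(displacement, dtype=float)
    norms = np.linalg.norm(disp, axis=1)
    peak = norms.max() if norms.size else 0.0
    n_top = n_topology if n_topology is not None else disp.shape[0]
    forces = np.zeros((n_top, 3))
    if peak == 0.0 or f_max == 0.0:
        if peak == 0.0 and f_max > 0.0:
            warnings.warn("all-zero displacement field; bias is zero",
                          stacklevel=2)
        return BiasField(forces=forces, f_max=f_max, source=source)
    scaled = disp * (f_max / peak)
    if selection is None:
        forces[: disp.shape[0]] = scaled
    else:
        forces[np.asarray(selection, dtype=int)] = scaled
    return BiasField(forces=forces, f_max=f_max, source=source)


@dataclass
class ResponseVerification:
    """Fluctuation-dissipation self-test report."""

    predicted: np.ndarray
    observed: np.ndarray
    cosine_per_site: np.ndarray
    mean_cosine: float
    magnitude_ratio: float
    n_repeats: int
    passed: bool
    cosine_threshold: float = 0.9
    ratio_bounds: tuple[float, float] = (0.8, 1.2)


def verify_response(
    model: CovarianceModel,
    perturb: PerturbationSet,
    run_perturbed: Callable[[np.ndarray, int], np.ndarray],
    n_repeats: int = 4,
    cosine_threshold: float = 0.9,
    ratio_bounds: tuple[float, float] = (0.8, 1.2),
    min_site_norm_quantile: float = 0.5,
) -> ResponseVerification:
    """Compare predicted against brute-force perturbed mean displacements.

    ``run_perturbed(dense_force, repeat_index)`` must run the engine with
    the given constant force field applied and return the sampled mean
    coordinates (n_sel, 3).  Per-site cosines are evaluated on sites whose
    predicted displacement norm exceeds the given quantile, avoiding
    noise-dominated near-zero sites.
    """
    predicted = predict_response(model, perturb)
    observed = np.mean(
        [run_perturbed(perturb.dense(model), r) for r in range(n_repeats)],
        axis=0,
    ) - model.mean_coords
    pn = np.linalg.norm(predicted, axis=1)
    on = np.linalg.norm(observed, axis=1)
    if pn.max() == 0.0:
        cos = np.zeros(model.n_sites)
        ratio = 1.0 if on.max() < 1e-12 else np.inf
        passed = bool(on.max() < 1e-12)
        return ResponseVerification(predicted, observed, cos, 0.0, ratio,
                                    n_repeats, passed)
    denom = np.maximum(pn * on, 1e-300)
    cos = np.einsum("ij,ij->i", predicted, observed) / denom
    strong = pn >= np.quantile(pn, min_site_norm_quantile)
    mean_cos = float(cos[strong].mean())
    ratio = float(
        np.linalg.norm(observed[strong]) / np.linalg.norm(predicted[strong])
    )
    passed = mean_cos > cosine_threshold and (
        ratio_bounds[0] <= ratio <= ratio_bounds[1]
    )
    return ResponseVerification(
        predicted=predicted,
        observed=observed,
        cosine_per_site=cos,
        mean_cosine=mean_cos,
        magnitude_ratio=ratio,
        n_repeats=n_repeats,
        passed=passed,
        cosine_threshold=cosine_threshold,
        ratio_bounds=ratio_bounds,
    )
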