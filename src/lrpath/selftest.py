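"""Self-contained physics checks on harmonic networks.

These exercise the fluctuation-dissipation chain end to end: sample an
exactly known harmonic system with the Langevin engine, estimate the
covariance, push a perturbative force through linear response, and
compare against the closed-form displacement K^-1 f.  Used by the
``lrpath verify`` subcommand and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import LangevinParams, run_langevin
from .forces import QuadraticTerm
from .response import (
    PerturbationSet,
    ResponseVerification,
    estimate_covariance,
    predict_response,
)
from .trajectory import Trajectory


def make_random_spd_network(
    n_sites: int, seed: int, eig_range: tuple[float, float] = (0.5, 3.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Random anchored harmonic network: reference coords and an exactly
    known symmetric positive-definite 3N x 3N stiffness matrix."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(scale=3.0, size=(n_sites, 3))
    n3 = 3 * n_sites
    q, _ = np.linalg.qr(rng.normal(size=(n3, n3)))
    evals = rng.uniform(*eig_range, size=n3)
    stiffness = (q * evals) @ q.T
    return x0, 0.5 * (stiffness + stiffness.T)


def sample_harmonic(
    x0: np.ndarray,
    stiffness: np.ndarray,
    *,
    temperature: float = 1.0,
    n_frames: int = 50_000,
    stride: int = 20,
    dt: float = 0.05,
    friction: float = 1.0,
    seed: int = 0,
    stage: str = "selftest",
    extra_terms=(),
) -> Trajectory:
    """Equilibrium BAOAB sampling of the quadratic potential."""
    term = QuadraticTerm(x0=x0, stiffness=stiffness)
    params = LangevinParams(
        temperature=temperature,
        friction=friction,
        dt=dt,
        n_steps=n_frames * stride,
        seed=seed,
        save_stride=stride,
    )
    result = run_langevin(
        x0, [term, *extra_terms], params, stage=stage
    )
    return result.trajectory


@dataclass
class HarmonicResponseReport(ResponseVerification):
    frobenius_error: float = float("nan")


def harmonic_response_check(
    seed: int = 0,
    n_sites: int = 5,
    n_frames: int = 50_000,
    temperature: float = 1.0,
    force_magnitude: float = 1.0,
    shrinkage: float = 0.05,
) -> HarmonicResponseReport:
    """Predict the response of a known harmonic network from sampled
    fluctuations and compare with the analytic K^-1 f displacement.

    Returns a report carrying per-site cosine similarities, the overall
    magnitude ratio, and the Frobenius relative error of the estimated
    covariance against kT K^-1.
    """
    x0, stiffness = make_random_spd_network(n_sites, seed)
    traj = sample_harmonic(
        x0, stiffness, temperature=temperature, n_frames=n_frames, seed=seed
    )
    model = estimate_covariance(
        traj, superpose=False, shrinkage=shrinkage, temperature=temperature
    )
    c_exact = temperature * np.linalg.inv(stiffness)
    frob = float(
        np.linalg.norm(model.covariance - c_exact) / np.linalg.norm(c_exact)
    )
    rng = np.random.default_rng(seed + 1)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    perturb = PerturbationSet(
        [(0, force_magnitude * direction)], label="selftest_push"
    )
    predicted = predict_response(model, perturb)
    f = perturb.dense(model).ravel()
    exact = np.linalg.solve(stiffness, f).reshape(-1, 3)
    pn = np.linalg.norm(predicted, axis=1)
    en = np.linalg.norm(exact, axis=1)
    cos = np.einsum("ij,ij->i", predicted, exact) / np.maximum(pn * en, 1e-300)
    ratio = float(np.linalg.norm(predicted) / np.linalg.norm(exact))
    mean_cos = float(cos.mean())
    passed = mean_cos > 0.9 and 0.8 <= ratio <= 1.2
    return HarmonicResponseReport(
        predicted=predicted,
        observed=exact,
        cosine_per_site=cos,
        mean_cosine=mean_cos,
        magnitude_ratio=ratio,
        n_repeats=1,
        passed=passed,
        frobenius_error=frob,
    )


def ou_covariance_check(
    seed: int = 0,
    n_sites: int = 5,
    n_frames: int = 50_000,
    temperature: float = 1.0,
) -> float:
    """Frobenius relative error of the estimated stationary covariance of
    a harmonic (Ornstein-Uhlenbeck) network against kT K^-1."""
    x0, stiffness = make_random_spd_network(n_sites, seed)
    traj = sample_harmonic(
        x0, stiffness, temperature=temperature, n_frames=n_frames,
        seed=seed, stage="ou",
    )
    model = estimate_covariance(
        traj, superpose=False, shrinkage=0.0, temperature=temperature
    )
    c_exact = temperature * np.linalg.inv(stiffness)
    return float(
        np.linalg.norm(model.covariance - c_exact) / np.linalg.norm(c_exact)
    )
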