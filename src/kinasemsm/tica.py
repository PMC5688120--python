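"""Time-lagged independent component analysis (tICA).

Finds the linear combinations of input features that decorrelate slowest at
a chosen lag by solving the generalized eigenproblem

    C(τ) ν = λ Σ ν

where Σ is the instantaneous covariance and C(τ) the (symmetrized)
time-lagged correlation matrix of the mean-free features. Eigenvalues relate
to relaxation times via t_i = −τ / ln λ_i; with *kinetic mapping* each
projected component is scaled by its eigenvalue so that Euclidean distances
in tIC space approximate kinetic distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .features import FeatureTrajectory

__all__ = [
    "TICAModel",
    "estimate_covariances",
    "solve_tica",
    "fit_tica",
    "transform",
    "timescale_of_component",
]


@dataclass
class TICAModel:
    means: np.ndarray
    cov: np.ndarray             # Σ, instantaneous covariance
    cov_lagged: np.ndarray      # symmetrized C(τ)
    lag_frames: int
    lag_ns: float
    eigenvalues: np.ndarray     # descending
    eigenvectors: np.ndarray    # columns, Σ-orthonormal
    n_components: int
    kinetic_mapping: bool
    shrinkage: float

    def timescales(self) -> np.ndarray:
        return np.array([timescale_of_component(l, self.lag_ns) for l in self.eigenvalues])


def estimate_covariances(trajs, lag: int):
    """Pooled mean-free covariance Σ and symmetrized lagged correlation C(τ).

    Σ uses every frame; C(τ) uses every in-trajectory (t, t+lag) pair —
    no pairs are formed across trajectory boundaries. At lag 0 the two
    estimates coincide exactly.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories given")
    if lag < 0:
        raise ValueError("lag must be non-negative")
    d = trajs[0].values.shape[1]
    for t in trajs:
        if t.values.shape[1] != d:
            raise ValueError("feature dimension mismatch across trajectories")
        if t.values.shape[0] <= lag:
            raise ValueError(f"lag {lag} not shorter than a trajectory of length {t.values.shape[0]}")

    n_total = sum(t.values.shape[0] for t in trajs)
    mean = sum(t.values.sum(axis=0) for t in trajs) / n_total

    sigma = np.zeros((d, d))
    ctau = np.zeros((d, d))
    n_pairs = 0
    for t in trajs:
        x = t.values - mean
        sigma += x.T @ x
        if lag == 0:
            ctau += x.T @ x
            n_pairs += x.shape[0]
        else:
            ctau += x[:-lag].T @ x[lag:]
            n_pairs += x.shape[0] - lag
    sigma /= n_total
    ctau /= n_pairs
    ctau = 0.5 * (ctau + ctau.T)
    return mean, sigma, ctau


def _shrink(sigma: np.ndarray, gamma: float) -> np.ndarray:
    """Shrink Σ toward its diagonal, plus a tiny absolute ridge so that
    exactly-zero-variance columns cannot produce a singular metric."""
    d = sigma.shape[0]
    diag = np.diag(np.diag(sigma))
    ridge = 1e-12 * max(1.0, float(np.trace(sigma)) / d)
    return (1.0 - gamma) * sigma + gamma * diag + ridge * np.eye(d)


def solve_tica(
    sigma: np.ndarray,
    ctau: np.ndarray,
    n_components: int,
    shrinkage: float = 1e-8,
    lag_frames: int = 1,
    lag_ns: float = 1.0,
    means: np.ndarray | None = None,
    kinetic_mapping: bool = False,
) -> TICAModel:
    """Solve C(τ) ν = λ Σ_γ ν with Σ_γ = (1−γ)Σ + γ·diag(Σ).

    Eigenpairs are sorted by descending λ and each eigenvector's sign is
    fixed so its largest-magnitude loading is positive; eigenvectors are
    Σ_γ-orthonormal.
    """
    sigma = np.asarray(sigma, dtype=float)
    ctau = np.asarray(ctau, dtype=float)
    if sigma.shape != ctau.shape or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("Σ and C(τ) must be square and same shape")
    if not (np.all(np.isfinite(sigma)) and np.all(np.isfinite(ctau))):
        raise ValueError("non-finite covariance input")
    if np.allclose(sigma, 0):
        raise ValueError("all-zero covariance matrix")
    d = sigma.shape[0]
    if not 1 <= n_components <= d:
        raise ValueError("n_components out of range")

    sig_reg = _shrink(sigma, shrinkage)
    evals, evecs = scipy.linalg.eigh(0.5 * (ctau + ctau.T), sig_reg)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        k = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    if means is None:
        means = np.zeros(d)
    return TICAModel(
        means=np.asarray(means, dtype=float),
        cov=sigma,
        cov_lagged=ctau,
        lag_frames=int(lag_frames),
        lag_ns=float(lag_ns),
        eigenvalues=evals,
        eigenvectors=evecs,
        n_components=int(n_components),
        kinetic_mapping=bool(kinetic_mapping),
        shrinkage=float(shrinkage),
    )


def fit_tica(
    trajs,
    lag_ns: float,
    n_components: int,
    kinetic_mapping: bool = False,
    shrinkage: float = 1e-8,
) -> TICAModel:
    """Estimate covariances and solve the tICA problem in one call.

    ``lag_ns`` must be an integer multiple of the frame interval.
    """
    trajs = list(trajs)
    dt = trajs[0].dt
    lag_frames = int(round(lag_ns / dt))
    if abs(lag_frames * dt - lag_ns) > 1e-9 * max(1.0, lag_ns) or lag_frames < 1:
        raise ValueError(f"tICA lag {lag_ns} ns is not a positive multiple of dt = {dt} ns")
    means, sigma, ctau = estimate_covariances(trajs, lag_frames)
    return solve_tica(
        sigma, ctau, n_components,
        shrinkage=shrinkage, lag_frames=lag_frames, lag_ns=lag_ns,
        means=means, kinetic_mapping=kinetic_mapping,
    )


def transform(trajs, model: TICAModel) -> list[FeatureTrajectory]:
    """Project mean-free features onto the leading tICs; with kinetic
    mapping, component i is scaled by λ_i."""
    single = isinstance(trajs, FeatureTrajectory)
    if single:
        trajs = [trajs]
    v = model.eigenvectors[:, : model.n_components]
    scale = model.eigenvalues[: model.n_components] if model.kinetic_mapping else 1.0
    out = []
    names = [f"tic{i + 1}" for i in range(model.n_components)]
    for t in trajs:
        if t.values.shape[1] != model.means.shape[0]:
            raise ValueError("feature dimension does not match model")
        proj = (t.values - model.means) @ v * scale
        out.append(FeatureTrajectory(proj, t.dt, list(names)))
    return out[0] if single else out


def timescale_of_component(eigenvalue: float, lag_ns: float) -> float:
    """Relaxation time −τ/ln(λ); NaN for λ ≤ 0, +inf for λ ≥ 1."""
    if eigenvalue <= 0:
        return float("nan")
    if eigenvalue >= 1:
        return float("inf")
    return -lag_ns / np.log(eigenvalue)
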