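"""Empirical response statistics of the power-law code.

Verifies, on sampled ensembles, the structural predictions of the model:
the susceptibility-variance identity ``Sigma = sigma0^2 I + sigma1^2
mu mu^T`` (differential correlations), the eigenvector identity
``Sigma mu = lambda mu``, and the power-law eigenspectrum of the
stimulus-marginalized covariance that motivates the model in the first
place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .code import (
    CodeSpec,
    NeuronSubset,
    ResponseEnsemble,
    sample_responses,
    susceptibility,
    tuning_curve,
)

__all__ = [
    "CovarianceEstimate",
    "ScatterFit",
    "EigenCheck",
    "analytic_covariance",
    "empirical_covariance",
    "susceptibility_variance_scatter",
    "covariance_eigencheck",
    "marginal_eigenspectrum",
    "analytic_marginal_spectrum",
    "spectrum_slope",
]

TWO_PI = 2.0 * math.pi


@dataclass
class CovarianceEstimate:
    """Sample covariance of a response ensemble at a fixed stimulus."""

    matrix: np.ndarray
    n_samples: int
    theta: float
    spec: CodeSpec

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance must be a square matrix")


def analytic_covariance(
    spec: CodeSpec, theta: float, subset: NeuronSubset | None = None
) -> np.ndarray:
    """Small-noise covariance ``sigma0^2 I + sigma1^2 mu mu^T``."""
    mu = susceptibility(spec, theta, subset)
    return spec.sigma0**2 * np.eye(len(mu)) + spec.sigma1**2 * np.outer(mu, mu)


def empirical_covariance(ensemble: ResponseEnsemble) -> CovarianceEstimate:
    """Unbiased sample covariance (divisor ``trials - 1``) of an ensemble."""
    if ensemble.n_trials < 2:
        raise ValueError("need at least 2 trials to estimate a covariance")
    matrix = np.cov(ensemble.responses, rowvar=False, ddof=1)
    return CovarianceEstimate(
        matrix=matrix,
        n_samples=ensemble.n_trials,
        theta=ensemble.theta,
        spec=ensemble.spec,
    )


@dataclass
class ScatterFit:
    """Least-squares fits of covariance elements against susceptibility
    outer-product elements, split into diagonal and off-diagonal groups.

    The model predicts slope ``sigma1^2`` for both groups, intercept
    ``sigma0^2`` on the diagonal and 0 off the diagonal.
    """

    x_diag: np.ndarray
    y_diag: np.ndarray
    x_off: np.ndarray
    y_off: np.ndarray
    slope_diag: float
    intercept_diag: float
    slope_off: float
    intercept_off: float
    n_samples: int
    theta: float
    spec: CodeSpec

    def to_frame(self) -> pd.DataFrame:
        diag = pd.DataFrame({"x": self.x_diag, "y": self.y_diag, "group": "diagonal"})
        off = pd.DataFrame({"x": self.x_off, "y": self.y_off, "group": "off_diagonal"})
        return pd.concat([diag, off], ignore_index=True)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def susceptibility_variance_scatter(
    spec: CodeSpec,
    theta: float,
    n_samples: int,
    seed: int,
    covariance: np.ndarray | None = None,
) -> ScatterFit:
    """Scatter of empirical covariance elements vs ``(mu mu^T)_ij``.

    Samples an ensemble (unless an explicit covariance matrix is given),
    pairs each covariance element with the corresponding element of the
    susceptibility outer product, and fits the diagonal and off-diagonal
    groups separately by ordinary least squares.
    """
    if covariance is None:
        if n_samples < 100:
            raise ValueError("need n_samples >= 100 for a meaningful scatter")
        ensemble = sample_responses(spec, theta, n_samples, seed)
        covariance = empirical_covariance(ensemble).matrix
    mu = susceptibility(spec, theta)
    outer = np.outer(mu, mu)
    diag_mask = np.eye(len(mu), dtype=bool)
    x_diag, y_diag = outer[diag_mask], covariance[diag_mask]
    x_off, y_off = outer[~diag_mask], covariance[~diag_mask]
    slope_diag, intercept_diag = _ols(x_diag, y_diag)
    slope_off, intercept_off = _ols(x_off, y_off)
    return ScatterFit(
        x_diag=x_diag,
        y_diag=y_diag,
        x_off=x_off,
        y_off=y_off,
        slope_diag=slope_diag,
        intercept_diag=intercept_diag,
        slope_off=slope_off,
        intercept_off=intercept_off,
        n_samples=int(n_samples),
        theta=float(theta),
        spec=spec,
    )


@dataclass
class EigenCheck:
    """Residual report for the eigenvector identity ``Sigma mu = lambda mu``."""

    relative_residual: float
    rayleigh_quotient: float


def covariance_eigencheck(
    cov: CovarianceEstimate | np.ndarray, mu: np.ndarray, lam: float
) -> EigenCheck:
    """Check how well ``mu`` is an eigenvector of the covariance.

    Returns the relative residual ``||Sigma mu - lambda mu|| / (lambda
    ||mu||)`` and the Rayleigh quotient ``mu^T Sigma mu / mu^T mu`` (which
    should match ``lambda = sigma0^2 + sigma1^2 H_N(alpha-2)``).
    """
    matrix = cov.matrix if isinstance(cov, CovarianceEstimate) else np.asarray(cov)
    mu = np.asarray(mu, dtype=float)
    if matrix.shape[0] != len(mu):
        raise ValueError("covariance and susceptibility dimensions disagree")
    mu_norm = np.linalg.norm(mu)
    if mu_norm == 0.0:
        raise ValueError("susceptibility vector is zero")
    sigma_mu = matrix @ mu
    residual = float(np.linalg.norm(sigma_mu - lam * mu) / (lam * mu_norm))
    rayleigh = float(mu @ sigma_mu / (mu @ mu))
    return EigenCheck(relative_residual=residual, rayleigh_quotient=rayleigh)


def analytic_marginal_spectrum(spec: CodeSpec) -> np.ndarray:
    """Eigenvalues of the stimulus-marginalized covariance, in closed form.

    For a uniform stimulus the signal covariance is diagonal with paired
    eigenvalues ``n^{-alpha}/2`` (cos and sin neuron of each mode carry
    equal variance); independent neural noise adds ``sigma0^2``.  Returned
    in descending order.
    """
    n = np.arange(1, spec.N + 1, dtype=float)
    pair = n ** (-spec.alpha) / 2.0 + spec.sigma0**2
    return np.sort(np.repeat(pair, 2))[::-1]


def marginal_eigenspectrum(
    spec: CodeSpec,
    n_theta: int,
    trials_per_theta: int,
    seed: int,
    theta_mode: str = "grid",
) -> np.ndarray:
    """Eigenspectrum of the covariance pooled over stimuli.

    Draws responses at ``n_theta`` stimulus angles (a deterministic uniform
    grid by default, or uniform random angles with ``theta_mode='random'``),
    pools all trials, subtracts the grand mean, and returns the eigenvalues
    of the pooled covariance in descending order.  A grid needs
    ``n_theta > 2N`` so that the Fourier modes remain orthogonal under the
    discrete stimulus average.
    """
    if n_theta < 8:
        raise ValueError(f"need n_theta >= 8, got {n_theta}")
    if trials_per_theta < 1:
        raise ValueError("trials_per_theta must be >= 1")
    ss = np.random.SeedSequence(int(seed))
    child_seeds = ss.generate_state(n_theta + 1)
    if theta_mode == "grid":
        thetas = TWO_PI * np.arange(n_theta) / n_theta
    elif theta_mode == "random":
        rng = np.random.Generator(np.random.Philox(key=int(child_seeds[-1])))
        thetas = rng.uniform(0.0, TWO_PI, n_theta)
    else:
        raise ValueError(f"unknown theta_mode {theta_mode!r}")
    blocks = [
        sample_responses(spec, th, trials_per_theta, int(s)).responses
        for th, s in zip(thetas, child_seeds[:n_theta])
    ]
    pooled = np.vstack(blocks)
    pooled -= pooled.mean(axis=0, keepdims=True)
    cov = pooled.T @ pooled / (pooled.shape[0] - 1)
    return np.sort(np.linalg.eigvalsh(cov))[::-1]


def spectrum_slope(
    eigenvalues: np.ndarray,
    sigma0: float = 0.0,
    n_modes: int | None = None,
) -> float:
    """Log-log slope of the signal eigenspectrum against mode rank.

    Pairs consecutive eigenvalues (cos/sin partners of each mode), subtracts
    the neural-noise floor ``sigma0^2``, and fits ``log lambda_n`` against
    ``log n`` by least squares over the first ``n_modes`` modes with a
    positive noise-subtracted value.  For a power-law code the slope is
    ``-alpha``.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if len(ev) % 2 != 0:
        raise ValueError("eigenvalue count must be even (paired modes)")
    per_mode = 0.5 * (ev[0::2] + ev[1::2]) - sigma0**2
    if n_modes is not None:
        per_mode = per_mode[:n_modes]
    ranks = np.arange(1, len(per_mode) + 1, dtype=float)
    keep = per_mode > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 modes above the noise floor")
    slope, _ = np.polyfit(np.log(ranks[keep]), np.log(per_mode[keep]), 1)
    return float(slope)
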