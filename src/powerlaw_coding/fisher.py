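"""Closed-form Fisher information of the power-law code.

For the one-dimensional circular stimulus the Fisher information of the
code with ``N`` modes is

    I(theta) = H_N(alpha - 2) / (sigma0^2 + sigma1^2 H_N(alpha - 2)),

where ``H_N(x) = sum_{n=1}^N n^{-x}`` is the generalized harmonic number.
As N -> infinity, H_N(alpha-2) -> zeta(alpha-2), which diverges for
alpha <= 3; in that regime the information saturates at the input-noise
bound ``1/sigma1^2`` regardless of the neural noise.  For a D-dimensional
input the limit generalizes to

    I_D(alpha) = zeta(alpha - 2/D) / (sigma0^2 D V_D^{2/D}/4
                                      + sigma_i^2 zeta(alpha - 2/D)),

with ``V_D = pi^{D/2} / Gamma(D/2 + 1)`` the unit-D-ball volume, constant at
``1/sigma_i^2`` for alpha <= alpha_c(D) = 1 + 2/D.  The exponent
``alpha_c`` is critical: it is the unique point where the slope of
``I_D(alpha)`` is discontinuous, and it is where the energy-aware objective
``J_D(alpha) = I_D(alpha) - gamma * zeta(alpha)`` attains its maximum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special

from .code import NeuronSubset
from .exceptions import DegenerateModelError, UnsupportedDimensionError

__all__ = [
    "harmonic_number",
    "riemann_zeta",
    "critical_exponent",
    "fisher_finite",
    "fisher_limit",
    "eigenvalue_lambda",
    "energy_aware_performance",
    "subset_fisher",
    "broken_power_fisher",
    "mutual_information_from_fisher",
    "FisherCurve",
    "EnergyCurve",
    "fisher_curve",
    "energy_curve",
    "locate_fisher_kink",
]

TWO_PI = 2.0 * math.pi


def harmonic_number(x: float, N: int) -> float:
    """Generalized harmonic number ``H_N(x) = sum_{n=1}^N n^{-x}``."""
    if int(N) != N or N < 1:
        raise ValueError(f"N must be a positive integer, got {N}")
    return float(np.sum(np.arange(1, int(N) + 1, dtype=float) ** (-float(x))))


def riemann_zeta(x: float) -> float:
    """Riemann zeta ``zeta(x)`` for x > 1; ``inf`` for x <= 1.

    Divergence is reported as a value (``math.inf``), not an error, so that
    callers must handle the sub-critical branch explicitly.
    """
    if x <= 1.0:
        return math.inf
    return float(special.zeta(float(x)))


def _is_infinite_dim(D) -> bool:
    return D is None or (isinstance(D, float) and math.isinf(D)) or D == math.inf


def critical_exponent(D) -> float:
    """Critical eigenspectrum exponent ``alpha_c = 1 + 2/D``.

    ``D = inf`` (or ``None``) gives the limit 1, the decay exponent expected
    for effectively infinite-dimensional inputs such as natural images.
    """
    if _is_infinite_dim(D):
        return 1.0
    if D < 1:
        raise ValueError(f"input dimension must be >= 1, got {D}")
    return 1.0 + 2.0 / float(D)


def fisher_finite(alpha: float, N: int, sigma0: float, sigma1: float) -> float:
    """Fisher information of the finite-N code (D = 1).

    ``H_N(alpha-2) / (sigma0^2 + sigma1^2 H_N(alpha-2))``; independent of
    the stimulus by the rotational symmetry of the receptive fields.
    """
    if sigma0 == 0.0 and sigma1 == 0.0:
        raise DegenerateModelError(
            "noiseless code: the Fisher information is infinite"
        )
    H = harmonic_number(alpha - 2.0, N)
    return H / (sigma0**2 + sigma1**2 * H)


def _ball_volume_factor(D: float) -> float:
    """``D * V_D^{2/D} / 4`` with ``V_D = pi^{D/2}/Gamma(D/2+1)``.

    Computed through log-gamma so it stays finite at large D.
    """
    log_VD = (D / 2.0) * math.log(math.pi) - special.gammaln(D / 2.0 + 1.0)
    return D * math.exp((2.0 / D) * log_VD) / 4.0


def fisher_limit(alpha: float, D, sigma0: float, sigma_i: float) -> float:
    """Large-population Fisher information ``I_D(alpha)``.

    For ``alpha <= alpha_c(D)`` the zeta function diverges and the exact
    analytic limit ``1/sigma_i^2`` is returned (the information plateau);
    above the critical exponent the closed form with ``zeta(alpha - 2/D)``
    applies.  ``D = inf`` uses the dedicated limit with denominator
    ``e*pi*sigma0^2/2 + sigma_i^2 zeta(alpha)``.
    """
    if _is_infinite_dim(D):
        z = riemann_zeta(alpha)
        if math.isinf(z):
            if sigma_i == 0.0:
                raise DegenerateModelError(
                    "sigma_i = 0 with divergent zeta: information unbounded"
                )
            return 1.0 / sigma_i**2
        return z / (math.e * math.pi * sigma0**2 / 2.0 + sigma_i**2 * z)
    if D < 1:
        raise ValueError(f"input dimension must be >= 1, got {D}")
    z = riemann_zeta(alpha - 2.0 / float(D))
    if math.isinf(z):
        if sigma_i == 0.0:
            raise DegenerateModelError(
                "sigma_i = 0 with divergent zeta: information unbounded"
            )
        return 1.0 / sigma_i**2
    return z / (sigma0**2 * _ball_volume_factor(float(D)) + sigma_i**2 * z)


def eigenvalue_lambda(alpha: float, N: int, sigma0: float, sigma1: float) -> float:
    """Eigenvalue of the response covariance along the susceptibility.

    ``lambda = sigma0^2 + sigma1^2 H_N(alpha-2)``: the susceptibility is an
    eigenvector of ``Sigma = sigma0^2 I + sigma1^2 mu mu^T``.
    """
    return sigma0**2 + sigma1**2 * harmonic_number(alpha - 2.0, N)


def energy_aware_performance(
    alpha: float,
    D,
    sigma0: float,
    sigma_i: float,
    gamma: float,
    N: int | None = None,
) -> float:
    """Energy-aware coding objective ``J_D(alpha) = I_D(alpha) - gamma * E``.

    The energy term ``E`` is ``zeta(alpha)`` in the large-population limit
    (``N=None``; requires alpha > 1, else J = -inf) and ``H_N(alpha)`` for a
    finite population.  ``gamma > 0`` is required: lower energy consumption
    is always preferred.
    """
    if gamma <= 0.0:
        raise ValueError(f"regularization weight gamma must be > 0, got {gamma}")
    infinite = N is None or (isinstance(N, float) and math.isinf(N))
    if infinite:
        energy = riemann_zeta(alpha)
        info = fisher_limit(alpha, D, sigma0, sigma_i)
        if math.isinf(energy):
            return -math.inf
    else:
        if not _is_infinite_dim(D) and D != 1:
            raise UnsupportedDimensionError(
                "the finite-N information formula is available for D=1 only"
            )
        energy = harmonic_number(alpha, int(N))
        info = fisher_finite(alpha, int(N), sigma0, sigma_i)
    return info - gamma * energy


def subset_fisher(
    subset: NeuronSubset, alpha: float, sigma0: float, sigma1: float
) -> float:
    """Fisher information of a mode-restricted code.

    Replaces ``H_N`` by the restricted sum ``H_S = sum_{n in S} n^{2-alpha}``
    in the finite-N formula; the theoretical counterpart of the neuron
    ablation experiments.
    """
    if sigma0 == 0.0 and sigma1 == 0.0:
        raise DegenerateModelError("noiseless code: information infinite")
    n = np.asarray(subset.modes, dtype=float)
    H = float(np.sum(n ** (2.0 - alpha)))
    return H / (sigma0**2 + sigma1**2 * H)


def broken_power_fisher(
    alpha1: float,
    alpha2: float,
    n_break: int,
    N: int,
    sigma0: float,
    sigma1: float,
) -> float:
    """Fisher information for a broken power-law amplitude spectrum.

    Modes ``n <= n_break`` decay with exponent ``alpha1`` and the remaining
    modes with ``alpha2``; the amplitude of the second segment carries the
    constant ``c_b = n_break^{(alpha2-alpha1)/2}`` so the spectrum is
    continuous at the break.  Motivated by reanalyses of cortical data in
    which the first ~10 eigenvalues follow a shallow slope (~0.5) and the
    rest a steeper one (~1.2).
    """
    if not 1 <= n_break <= N:
        raise ValueError(f"need 1 <= n_break <= N, got n_break={n_break}, N={N}")
    if sigma0 == 0.0 and sigma1 == 0.0:
        raise DegenerateModelError("noiseless code: information infinite")
    n_low = np.arange(1, n_break + 1, dtype=float)
    n_high = np.arange(n_break + 1, N + 1, dtype=float)
    c_b2 = float(n_break) ** (alpha2 - alpha1)
    H = float(np.sum(n_low ** (2.0 - alpha1)) + c_b2 * np.sum(n_high ** (2.0 - alpha2)))
    return H / (sigma0**2 + sigma1**2 * H)


def mutual_information_from_fisher(
    fisher_value: float,
    prior: Callable[[np.ndarray], np.ndarray] | None = None,
) -> float:
    """Mutual information between stimulus and response in the
    large-population limit.

    ``I(theta; r) = H[p(theta)] - (1/2) E_theta[log(2 pi e / I(theta))]``.
    The Fisher information of this code is stimulus-independent, so the
    average is exact; for a uniform prior the entropy is ``log(2 pi)``.  A
    non-uniform prior is supplied as a density on [0, 2*pi) and its entropy
    is integrated numerically.
    """
    if fisher_value <= 0.0:
        raise ValueError(f"fisher_value must be > 0, got {fisher_value}")
    if prior is None:
        entropy = math.log(TWO_PI)
    else:
        grid = np.linspace(0.0, TWO_PI, 4097)
        p = np.asarray(prior(grid), dtype=float)
        norm = integrate.trapezoid(p, grid)
        if not math.isclose(norm, 1.0, rel_tol=1e-3):
            raise ValueError(f"prior density integrates to {norm:.4f}, not 1")
        with np.errstate(divide="ignore", invalid="ignore"):
            integrand = np.where(p > 0, -p * np.log(p), 0.0)
        entropy = float(integrate.trapezoid(integrand, grid))
    return entropy - 0.5 * math.log(TWO_PI * math.e / fisher_value)


# ---------------------------------------------------------------------------
# Curves over exponent grids


def default_alpha_grid(
    alpha_min: float = 1.05, alpha_max: float = 6.0, step: float = 0.01
) -> np.ndarray:
    """Exponent grid avoiding the zeta pole at alpha = 1."""
    n = int(round((alpha_max - alpha_min) / step))
    return alpha_min + step * np.arange(n + 1)


@dataclass
class FisherCurve:
    """Fisher information evaluated over a grid of exponents."""

    alphas: np.ndarray
    values: np.ndarray
    D: float
    sigma0: float
    sigma_i: float
    N: int | None = None  # None means the large-population limit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alpha": self.alphas, "value": self.values})

    def save(self, path_prefix: str | Path) -> tuple[Path, Path]:
        prefix = Path(path_prefix)
        csv_path, json_path = prefix.with_suffix(".csv"), prefix.with_suffix(".json")
        self.to_frame().to_csv(csv_path, index=False)
        json_path.write_text(json.dumps(self._meta(), indent=2))
        return csv_path, json_path

    def _meta(self) -> dict:
        return {
            "D": None if _is_infinite_dim(self.D) else float(self.D),
            "sigma0": self.sigma0,
            "sigma_i": self.sigma_i,
            "N": self.N,
        }


@dataclass
class EnergyCurve(FisherCurve):
    """Energy-aware performance ``J_D(alpha)`` over a grid of exponents."""

    gamma: float = 1e-3

    def __post_init__(self) -> None:
        if self.gamma <= 0.0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    @property
    def argmax_alpha(self) -> float:
        finite = np.where(np.isfinite(self.values), self.values, -np.inf)
        return float(self.alphas[int(np.argmax(finite))])

    def _meta(self) -> dict:
        meta = super()._meta()
        meta["gamma"] = self.gamma
        return meta


def fisher_curve(
    alphas: Sequence[float] | np.ndarray | None = None,
    D=1,
    sigma0: float = 0.01,
    sigma_i: float = 0.01,
    N: int | None = None,
) -> FisherCurve:
    """Evaluate the Fisher information over an exponent grid."""
    grid = default_alpha_grid() if alphas is None else np.asarray(alphas, dtype=float)
    if N is None:
        vals = np.array([fisher_limit(a, D, sigma0, sigma_i) for a in grid])
    else:
        vals = np.array([fisher_finite(a, N, sigma0, sigma_i) for a in grid])
    return FisherCurve(grid, vals, D=D, sigma0=sigma0, sigma_i=sigma_i, N=N)


def energy_curve(
    alphas: Sequence[float] | np.ndarray | None = None,
    D=1,
    sigma0: float = 0.01,
    sigma_i: float = 0.01,
    gamma: float = 1e-3,
    N: int | None = None,
) -> EnergyCurve:
    """Evaluate the energy-aware objective ``J_D`` over an exponent grid."""
    grid = default_alpha_grid() if alphas is None else np.asarray(alphas, dtype=float)
    vals = np.array(
        [energy_aware_performance(a, D, sigma0, sigma_i, gamma, N) for a in grid]
    )
    return EnergyCurve(grid, vals, D=D, sigma0=sigma0, sigma_i=sigma_i, N=N, gamma=gamma)


def locate_fisher_kink(
    D=1,
    sigma0: float = 0.01,
    sigma_i: float = 0.01,
    alpha_min: float = 2.0,
    alpha_max: float = 4.0,
    step: float = 0.005,
) -> float:
    """Locate the exponent at which the slope of ``I_D(alpha)`` jumps.

    Scans a uniform grid, takes one-sided finite-difference slopes and
    returns the grid point with the largest change of slope — the numerical
    signature of the critical exponent ``alpha_c = 1 + 2/D``.
    """
    grid = default_alpha_grid(alpha_min, alpha_max, step)
    vals = np.array([fisher_limit(a, D, sigma0, sigma_i) for a in grid])
    slopes = np.diff(vals) / step
    jump = np.abs(np.diff(slopes))
    return float(grid[int(np.argmax(jump)) + 1])
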