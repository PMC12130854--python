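"""Power-law population code: the synthetic encoding model.

A population of ``2N`` neurons encodes a circular stimulus ``theta`` through
Fourier receptive fields whose amplitudes decay as a power law in the mode
index ``n``:

    r_{2n-1} = n^{-alpha/2} cos(n (theta + eta)) + xi_{2n-1}
    r_{2n}   = n^{-alpha/2} sin(n (theta + eta)) + xi_{2n}

where ``eta ~ N(0, sigma1^2)`` is input noise shared by the whole population
within a trial and ``xi_i ~ N(0, sigma0^2)`` is independent neural noise per
neuron.  Mode indexing is 1-based: mode ``n`` owns the neuron pair at
(1-based) positions ``2n-1`` (cosine) and ``2n`` (sine).

This module is the study's data generator: every empirical quantity in the
package (covariances, eigenspectra, decoding errors) is measured on samples
drawn from this model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import UnsupportedDimensionError

__all__ = [
    "CodeSpec",
    "NeuronSubset",
    "ResponseEnsemble",
    "RestrictedCode",
    "tuning_curve",
    "susceptibility",
    "sample_responses",
    "population_energy",
    "restrict_code",
    "canonicalize_angle",
]

TWO_PI = 2.0 * math.pi


def canonicalize_angle(theta: float) -> float:
    """Map an angle to the canonical stimulus range [0, 2*pi)."""
    return float(np.mod(theta, TWO_PI))


@dataclass(frozen=True)
class CodeSpec:
    """Parameters of a power-law population code.

    Parameters
    ----------
    N : int
        Number of Fourier modes; the population has ``2N`` neurons.
    alpha : float
        Power-law exponent of the covariance eigenspectrum; receptive-field
        amplitudes scale as ``n**(-alpha/2)``.
    sigma0 : float
        Neural-noise standard deviation (response units), independent per
        neuron.
    sigma1 : float
        Input-noise standard deviation (radians), shared across the
        population within a trial.
    D : int
        Input dimension.  Only the closed-form theory supports ``D > 1``;
        sampling and decoding require ``D == 1``.

    Notes
    -----
    The general model allows an orthogonal rotation of the neuron axes and a
    global amplitude scale; both are fixed (identity, 1) without loss of
    generality and are therefore not parameters.
    """

    N: int
    alpha: float
    sigma0: float
    sigma1: float
    D: int = 1

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise ValueError("noise strengths sigma0, sigma1 must be >= 0")
        if int(self.D) != self.D or self.D < 1:
            raise ValueError(f"D must be a positive integer, got {self.D}")

    @property
    def n_neurons(self) -> int:
        return 2 * self.N

    def to_dict(self) -> dict:
        return {
            "N": int(self.N),
            "alpha": float(self.alpha),
            "sigma0": float(self.sigma0),
            "sigma1": float(self.sigma1),
            "D": int(self.D),
        }


@dataclass(frozen=True)
class NeuronSubset:
    """An ordered set of retained Fourier-mode indices.

    Retaining mode ``n`` keeps both its cosine and sine neuron.  Used for
    the ablation experiments in which encoder neurons are removed from the
    population in ascending or descending order of their mode index.
    """

    modes: tuple[int, ...]
    order_tag: str = "custom"

    def __post_init__(self) -> None:
        modes = tuple(int(m) for m in self.modes)
        if len(modes) == 0:
            raise ValueError("NeuronSubset must retain at least one mode")
        if any(m < 1 for m in modes):
            raise ValueError("mode indices are 1-based and must be >= 1")
        if any(b <= a for a, b in zip(modes, modes[1:])):
            raise ValueError("mode indices must be strictly increasing")
        if self.order_tag not in ("descending_removal", "ascending_removal", "custom"):
            raise ValueError(f"unknown order_tag {self.order_tag!r}")
        object.__setattr__(self, "modes", modes)

    @classmethod
    def full(cls, N: int) -> "NeuronSubset":
        return cls(tuple(range(1, N + 1)), "custom")

    @classmethod
    def descending_removal(cls, N: int, k: int) -> "NeuronSubset":
        """Remove ``k`` modes from the high-frequency end: retain 1..N-k."""
        if not 0 <= k < N:
            raise ValueError(f"need 0 <= k < N, got k={k}, N={N}")
        return cls(tuple(range(1, N - k + 1)), "descending_removal")

    @classmethod
    def ascending_removal(cls, N: int, k: int) -> "NeuronSubset":
        """Remove ``k`` modes from the low-frequency end: retain k+1..N."""
        if not 0 <= k < N:
            raise ValueError(f"need 0 <= k < N, got k={k}, N={N}")
        return cls(tuple(range(k + 1, N + 1)), "ascending_removal")

    def neuron_columns(self) -> np.ndarray:
        """0-based response-vector columns of the retained neurons,
        interleaved (cos, sin) per mode."""
        m = np.asarray(self.modes)
        cols = np.empty(2 * len(m), dtype=int)
        cols[0::2] = 2 * m - 2
        cols[1::2] = 2 * m - 1
        return cols


def _mode_array(spec: CodeSpec, subset: NeuronSubset | None) -> np.ndarray:
    if subset is None:
        return np.arange(1, spec.N + 1, dtype=float)
    modes = np.asarray(subset.modes, dtype=float)
    if modes[-1] > spec.N:
        raise ValueError(
            f"subset retains mode {int(modes[-1])} but the code has only N={spec.N} modes"
        )
    return modes


def _require_d1(spec: CodeSpec) -> None:
    if spec.D != 1:
        raise UnsupportedDimensionError(
            "sampling and tuning-curve evaluation are defined for D=1 only; "
            f"got D={spec.D}"
        )


def _interleave(cos_part: np.ndarray, sin_part: np.ndarray) -> np.ndarray:
    out = np.empty(cos_part.shape[:-1] + (2 * cos_part.shape[-1],), dtype=float)
    out[..., 0::2] = cos_part
    out[..., 1::2] = sin_part
    return out


def tuning_curve(
    spec: CodeSpec, theta: float, subset: NeuronSubset | None = None
) -> np.ndarray:
    """Noise-free mean population response ``m(theta)``.

    Entry ``2n-1`` (1-based) is ``n**(-alpha/2) cos(n theta)`` and entry
    ``2n`` is ``n**(-alpha/2) sin(n theta)`` for each retained mode ``n``.
    """
    _require_d1(spec)
    n = _mode_array(spec, subset)
    amp = n ** (-spec.alpha / 2.0)
    phase = n * theta
    return _interleave(amp * np.cos(phase), amp * np.sin(phase))


def susceptibility(
    spec: CodeSpec, theta: float, subset: NeuronSubset | None = None
) -> np.ndarray:
    """Derivative ``mu = dm/dtheta`` of the mean response.

    Entry ``2n-1`` is ``-n**(1-alpha/2) sin(n theta)``, entry ``2n`` is
    ``n**(1-alpha/2) cos(n theta)``; its squared norm is the generalized
    harmonic number ``H_N(alpha-2)`` for the full code.
    """
    _require_d1(spec)
    n = _mode_array(spec, subset)
    amp = n ** (1.0 - spec.alpha / 2.0)
    phase = n * theta
    return _interleave(-amp * np.sin(phase), amp * np.cos(phase))


def population_energy(spec: CodeSpec, subset: NeuronSubset | None = None) -> float:
    """Mean-square population activity averaged over stimulus and noise.

    Equals ``sum_n n**(-alpha)`` over the retained modes; for the full code
    this converges to the Riemann zeta function ``zeta(alpha)`` as N grows.
    """
    n = _mode_array(spec, subset)
    return float(np.sum(n ** (-spec.alpha)))


@dataclass
class ResponseEnsemble:
    """Trials x 2N matrix of noisy population responses at a fixed stimulus."""

    theta: float
    responses: np.ndarray
    seed: int
    spec: CodeSpec
    subset: NeuronSubset | None = field(default=None)

    def __post_init__(self) -> None:
        self.theta = canonicalize_angle(self.theta)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a trials x neurons matrix")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    def to_frame(self) -> pd.DataFrame:
        trials, n_neurons = self.responses.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(np.arange(trials), n_neurons),
                "neuron_index": np.tile(np.arange(1, n_neurons + 1), trials),
                "value": self.responses.ravel(),
            }
        )

    def save(self, path_prefix: str | Path) -> tuple[Path, Path]:
        """Write `<prefix>.csv` (trial, neuron_index, value) and a JSON
        sidecar `<prefix>.json` with the spec, stimulus and seed."""
        prefix = Path(path_prefix)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        self.to_frame().to_csv(csv_path, index=False)
        meta = {
            "theta": self.theta,
            "seed": int(self.seed),
            "spec": self.spec.to_dict(),
            "subset": list(self.subset.modes) if self.subset is not None else None,
        }
        json_path.write_text(json.dumps(meta, indent=2))
        return csv_path, json_path

    @classmethod
    def load(cls, path_prefix: str | Path) -> "ResponseEnsemble":
        prefix = Path(path_prefix)
        df = pd.read_csv(prefix.with_suffix(".csv"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        trials = df["trial"].nunique()
        responses = df["value"].to_numpy().reshape(trials, -1)
        subset = None
        if meta.get("subset") is not None:
            subset = NeuronSubset(tuple(meta["subset"]))
        return cls(
            theta=meta["theta"],
            responses=responses,
            seed=meta["seed"],
            spec=CodeSpec(**meta["spec"]),
            subset=subset,
        )


def sample_responses(
    spec: CodeSpec,
    theta: float,
    trials: int,
    seed: int,
    subset: NeuronSubset | None = None,
) -> ResponseEnsemble:
    """Draw noisy population responses at a fixed stimulus.

    Each trial draws one input-noise perturbation ``eta ~ N(0, sigma1^2)``
    shared by the whole population, and independent neural noise
    ``xi_i ~ N(0, sigma0^2)`` per neuron.  Uses a counter-based Philox
    stream keyed on ``seed``, so identical arguments give bitwise-identical
    ensembles.
    """
    _require_d1(spec)
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    n = _mode_array(spec, subset)
    amp = n ** (-spec.alpha / 2.0)
    rng = np.random.Generator(np.random.Philox(key=int(seed)))
    eta = spec.sigma1 * rng.standard_normal(trials)
    xi = spec.sigma0 * rng.standard_normal((trials, 2 * len(n)))
    phase = np.outer(theta + eta, n)  # trials x modes
    responses = _interleave(amp * np.cos(phase), amp * np.sin(phase)) + xi
    return ResponseEnsemble(
        theta=theta, responses=responses, seed=int(seed), spec=spec, subset=subset
    )


class RestrictedCode:
    """View of a code restricted to a subset of Fourier modes.

    Delegates to the module-level operations with the subset applied, so the
    retained neuron pairs behave exactly as in the full code.
    """

    def __init__(self, spec: CodeSpec, subset: NeuronSubset):
        _ = _mode_array(spec, subset)  # validates subset against spec
        self.spec = spec
        self.subset = subset

    @property
    def modes(self) -> tuple[int, ...]:
        return self.subset.modes

    @property
    def n_neurons(self) -> int:
        return 2 * len(self.subset.modes)

    def tuning_curve(self, theta: float) -> np.ndarray:
        return tuning_curve(self.spec, theta, self.subset)

    def susceptibility(self, theta: float) -> np.ndarray:
        return susceptibility(self.spec, theta, self.subset)

    def population_energy(self) -> float:
        return population_energy(self.spec, self.subset)

    def sample_responses(self, theta: float, trials: int, seed: int) -> ResponseEnsemble:
        return sample_responses(self.spec, theta, trials, seed, self.subset)


def restrict_code(spec: CodeSpec, subset: NeuronSubset) -> RestrictedCode:
    """Restrict a code to the modes retained by ``subset``."""
    return RestrictedCode(spec, subset)
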