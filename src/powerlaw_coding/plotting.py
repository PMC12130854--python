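"""Plot helpers for the standard result surfaces (all return a Figure)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .fisher import EnergyCurve, FisherCurve
from .response_stats import ScatterFit

__all__ = ["plot_curves", "plot_scatter_fit", "plot_eigenspectrum"]


def plot_curves(curves: list[FisherCurve | EnergyCurve], ax=None):
    """Fisher information (or energy-aware objective) vs exponent, one line
    per input dimension, with the critical exponent marked."""
    from .fisher import critical_exponent

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        label = "D=inf" if not np.isfinite(curve.D) else f"D={curve.D:g}"
        ax.plot(curve.alphas, curve.values, label=label)
        ax.axvline(critical_exponent(curve.D), ls="--", lw=0.8, color="gray")
    ax.set_xlabel(r"power-law exponent $\alpha$")
    ax.set_ylabel("value")
    ax.legend()
    return ax.figure


def plot_scatter_fit(fit: ScatterFit, ax=None):
    """Covariance elements vs susceptibility outer-product elements."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(fit.x_off, fit.y_off, ".", ms=2, alpha=0.4, label="off-diagonal")
    ax.plot(fit.x_diag, fit.y_diag, "o", ms=4, label="diagonal")
    xs = np.linspace(0, max(fit.x_diag.max(), 1e-12), 50)
    s0sq, s1sq = fit.spec.sigma0**2, fit.spec.sigma1**2
    ax.plot(xs, s0sq + s1sq * xs, "k-", lw=1, label=r"$\sigma_0^2+\sigma_1^2 x$")
    ax.plot(xs, s1sq * xs, "k--", lw=1, label=r"$\sigma_1^2 x$")
    ax.set_xlabel(r"$(\mu\mu^\top)_{ij}$")
    ax.set_ylabel(r"$\hat\Sigma_{ij}$")
    ax.legend(fontsize=8)
    return ax.figure


def plot_eigenspectrum(eigenvalues: np.ndarray, sigma0: float = 0.0, ax=None):
    """Marginal covariance eigenspectrum on log-log axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ev = np.sort(np.asarray(eigenvalues))[::-1]
    per_mode = 0.5 * (ev[0::2] + ev[1::2]) - sigma0**2
    ranks = np.arange(1, len(per_mode) + 1)
    keep = per_mode > 0
    ax.loglog(ranks[keep], per_mode[keep], "o-", ms=3)
    ax.set_xlabel("mode rank $n$")
    ax.set_ylabel(r"signal eigenvalue $\lambda_n$")
    return ax.figure
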