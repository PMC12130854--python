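import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TWO_PI = 2.0 * math.pi


def brute_force_log_likelihood(samples, spec, thetas, grid_size=24576, subset=None):
    """Independent trapezoid quadrature of the likelihood integral.

    Evaluates, for each requested theta, the phi-integral of the wrapped
    input-noise Gaussian times the neural-noise profile on its own fine
    grid, without any FFT.  Used as the oracle against the decoder's
    convolution path.
    """
    modes = np.asarray(subset.modes, float) if subset is not None else np.arange(1, spec.N + 1.0)
    amp = modes ** (-spec.alpha / 2.0)
    phi = TWO_PI * np.arange(grid_size) / grid_size
    h = TWO_PI / grid_size
    ph = np.outer(phi, modes)
    basis = np.empty((grid_size, 2 * len(modes)))
    basis[:, 0::2] = amp * np.cos(ph)
    basis[:, 1::2] = amp * np.sin(ph)
    out = np.zeros(len(thetas))
    for s in np.atleast_2d(samples):
        log_g = -np.sum((s[None, :] - basis) ** 2, axis=1) / (2.0 * spec.sigma0**2)
        m = log_g.max()
        g = np.exp(log_g - m)
        for i, theta in enumerate(thetas):
            diff = phi - theta
            kernel = np.zeros(grid_size)
            for w in (-1.0, 0.0, 1.0):
                kernel += np.exp(-0.5 * ((diff + w * TWO_PI) / spec.sigma1) ** 2)
            out[i] += math.log(h * np.sum(kernel * g)) + m
    return out


def exact_covariance_quadrature(spec, theta, n_nodes=201):
    """Exact response covariance by Gauss-Hermite quadrature over the input
    noise, plus the independent neural-noise diagonal.  No linearization,
    no Monte Carlo: the oracle for what sampling the model actually yields.
    """
    from numpy.polynomial.hermite_e import hermegauss

    nodes, weights = hermegauss(n_nodes)
    weights = weights / weights.sum()
    n = np.arange(1, spec.N + 1.0)
    amp = n ** (-spec.alpha / 2.0)
    eta = nodes * spec.sigma1
    ph = np.outer(theta + eta, n)
    F = np.empty((len(eta), 2 * spec.N))
    F[:, 0::2] = amp * np.cos(ph)
    F[:, 1::2] = amp * np.sin(ph)
    mean = weights @ F
    Fc = F - mean
    return (Fc * weights[:, None]).T @ Fc + spec.sigma0**2 * np.eye(2 * spec.N)


@pytest.fixture
def small_spec():
    from powerlaw_coding import CodeSpec

    return CodeSpec(N=10, alpha=2.0, sigma0=0.1, sigma1=0.05)
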