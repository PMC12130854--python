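# powerlaw-coding

Tools for analyzing **power-law neural population codes**: closed-form
Fisher information, maximum-likelihood decoding, and the
energy–information trade-off that singles out the critical eigenspectrum
exponent observed in visual cortex.

## The science

Large-scale recordings show that the eigenspectrum of the stimulus-
marginalized covariance of cortical population activity decays as a power
law, `λ_n ∝ n^(−α)`, with an exponent close to the critical value
`α_c = 1 + 2/D` (D = stimulus dimension) that separates smooth from fractal
neural manifolds. This package implements an analytically tractable model
of such a code for a circular stimulus `θ`: a population of `2N` neurons
with Fourier receptive fields

```
r_{2n−1} = n^(−α/2) cos n(θ + η) + ξ,    r_{2n} = n^(−α/2) sin n(θ + η) + ξ,
```

where `η ~ N(0, σ₁²)` is input noise shared across the population and
`ξ ~ N(0, σ₀²)` is independent neural noise. In the small-noise regime the
response covariance is `Σ = σ₀² I + σ₁² μμᵀ` (a differential-correlation
structure, with `μ = ∂m/∂θ` the susceptibility), and the Fisher information
is

```
I(θ) = H_N(α−2) / (σ₀² + σ₁² H_N(α−2))  →  ζ(α−2) / (σ₀² + σ₁² ζ(α−2)),
```

with `H_N` the generalized harmonic number and `ζ` the Riemann zeta
function. Because `ζ(α−2)` diverges for `α ≤ 3`, the information *plateaus*
at the input-noise bound `1/σ₁²` below the critical exponent — the code
does not degrade even where the manifold is fractal. Adding a metabolic
cost `γ ζ(α)` (the mean-square population activity) gives the energy-aware
objective `J_D(α) = I_D(α) − γ ζ(α)`, which is maximized exactly at
`α = α_c`: the critical power law is the optimal energy-aware code. The
package also provides a maximum-likelihood decoder (exact numerical
integration of the latent-stimulus likelihood) whose inverse error variance
verifies the theory, including under ablation of low- or high-frequency
neurons.

## Worked example

```python
import powerlaw_coding as plc

spec = plc.CodeSpec(N=50, alpha=4.0, sigma0=0.01, sigma1=0.01)

theory = plc.fisher_finite(4.0, 50, 0.01, 0.01)
run = plc.decoding_experiment(spec, M=10, n_trials=1000, seed=123)
print(f"Fisher information (theory): {theory:.1f}")
print(f"1/(M Var) from ML decoding:  {run.inverse_variance_per_obs:.1f}")
print(f"critical exponent, D=1:      {plc.critical_exponent(1):g}")
print(f"J_1 argmax over alpha:       {plc.energy_curve(D=1).argmax_alpha:g}")
```

prints

```
Fisher information (theory): 6190.7
1/(M Var) from ML decoding:  6486.0
critical exponent, D=1:      3
J_1 argmax over alpha:       3
```

The decoder's per-observation inverse error variance (≈6.5·10³ from 1000
Monte-Carlo trials, each decoding M=10 response vectors) agrees with the
closed-form Fisher information within the Monte-Carlo uncertainty (the
relative standard error of a variance at 10³ trials is ≈4.5%), and the
energy-aware objective peaks at the critical exponent `α_c = 3`.

From a shell, the same pipelines are available as a CLI:

```
powerlaw-coding fisher --D 1 --D inf --out results/
powerlaw-coding run config.yaml --seed 1
powerlaw-coding critical --D 2
```

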