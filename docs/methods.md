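# Methods

## Model

A population of `2N` neurons encodes a circular stimulus `θ ∈ [0, 2π)`
through Fourier receptive fields with power-law amplitudes: mode `n`
(1-based) owns a cosine/sine neuron pair with amplitude `n^(−α/2)`. Two
Gaussian noise sources act per trial: an input perturbation
`η ~ N(0, σ₁²)` applied to the stimulus and shared by the whole population,
and independent neural noise `ξ_i ~ N(0, σ₀²)` per neuron. The general
model admits an orthogonal rotation of the neuron axes and a global
amplitude scale; both are fixed to identity and 1 without loss of
generality (the neural noise is isotropic, so the rotation is
unobservable). The simulator (`powerlaw_coding.code`) draws from this model
exactly — no linearization — using a counter-based Philox stream keyed on
the user seed, with draws in a fixed documented order (per-trial `η` first,
then the `ξ` block), so ensembles are bitwise reproducible.

This generator *is* the study's data source; there is no external data.
What it emulates is the power-law covariance eigenspectrum reported for
cortical populations; what it does not emulate are spiking statistics,
skewed rate distributions, receptive-field diversity (e.g. Gabors), or
noise correlations beyond the rank-one differential-correlation structure.
Passing tests therefore validate the theory within this idealized model,
not those aspects of real data.

## Theory

The small-noise linearization `r ≈ m(θ) + μη + ξ`, with `μ = ∂m/∂θ`, gives
the covariance `Σ = σ₀²I + σ₁²μμᵀ` and the eigenvalue identity
`Σμ = λμ`, `λ = σ₀² + σ₁²H_N(α−2)` where `H_N(x) = Σ_{n≤N} n^(−x)`. The
Fisher information follows as

```
I(θ) = H_N(α−2) / (σ₀² + σ₁²H_N(α−2)),
```

θ-independent by rotational symmetry. In the large-population limit
`H_N → ζ`, and for a D-dimensional stimulus

```
I_D(α) = ζ(α−2/D) / (σ₀² · D·V_D^{2/D}/4 + σ_i² ζ(α−2/D)),
V_D = π^{D/2}/Γ(D/2+1),
```

which reduces to the D=1 form (the ball factor is exactly 1) and has a
dedicated `D=∞` branch with denominator `eπσ₀²/2 + σ_i²ζ(α)` (Stirling).
For `α ≤ α_c = 1+2/D` the zeta argument is ≤1 and the series diverges; the
implementation returns the exact analytic limit `1/σ_i²` on that branch
rather than a large truncated sum, so the plateau is represented exactly
and `ζ(x)` for `x ≤ 1` is returned as an explicit `inf` divergence marker
that callers must handle.

Energy-aware performance is `J_D(α) = I_D(α) − γζ(α)` (finite-N variant:
`H_N(α)` as the energy term, D=1 only). `γ > 0` is required; the default
`γ = 10⁻³` is small enough not to overwhelm the information term, and the
optimum's location is insensitive to γ over at least `[10⁻⁵, 10⁻³]`. The
default exponent grid is `[1.05, 6]` in steps of 0.01, starting above the
`ζ` pole at α=1. Consequence: for `D=∞`, where `α_c = 1` sits exactly on
the pole (the energy cost diverges there), the admissible optimum is the
grid's lower edge — the objective is strictly decreasing on the grid, a
delta-function-like peak pressed against α→1⁺.

A broken power-law variant replaces the single spectrum by
`n^(−α₁/2)` up to a break index and `c_b·n^(−α₂/2)` beyond it, with
`c_b = n_break^{(α₂−α₁)/2}` chosen for amplitude continuity at the break —
continuity is the minimal assumption and is isolated in that one constant.
Mutual information is reported via
`I(θ;r) = H[p(θ)] − ½·E[log(2πe/I(θ))]`, exact here because `I` is
θ-independent.

## Decoder

The likelihood of a response `r` is the convolution over the latent
perturbed stimulus `φ` of the input-noise Gaussian with the neural-noise
profile `g_r(φ) = exp[−‖r−m(φ)‖²/(2σ₀²)]`. Numerics:

- uniform circular grid of `G = max(4096, 16·n_max, next_pow2(8·2π/σ₁))`
  points — enough to resolve both the frequency-`n_max` oscillations of
  `g_r` and the narrow (σ₁ ≈ 0.01 rad) kernel at ≥8 points per σ;
- `g_r` evaluated in log space via `‖r−m(φ)‖² = ‖r‖² − 2r·m(φ) + const`
  (one matrix product against a precomputed basis), max-subtracted,
  convolved circularly with a wrapped-Gaussian kernel by FFT; `σ₁ = 0`
  short-circuits to the profile itself (delta kernel);
- convolution values below the FFT roundoff floor (~10⁻¹² of the
  per-sample peak) are clamped there: they are pure noise and can be
  negative, while the peak region that determines the estimate is accurate
  to near machine precision (verified against independent trapezoid
  quadrature to better than 10⁻⁶);
- M observations are treated as independent draws of `(η, ξ)` with a
  factorized likelihood, so `1/(M·Var)` is the quantity comparable to the
  Fisher information; a `shared_input_noise` switch implements the
  alternative convention (one η shared by the M draws), and both
  normalizations `1/Var` and `1/(M·Var)` are always reported;
- the estimate is the grid argmax refined by a three-point quadratic fit
  (circular indexing, offset clipped to half a grid step); a flat
  likelihood raises an estimation-failure error;
- errors are wrapped to `(−π, π]`; trials with `|error| > π/2` are counted
  and reported, never discarded; the variance is over all trials.

Decoding experiments default to 10³ trials (Monte-Carlo relative standard
error of a variance ≈ `sqrt(2/n)` ≈ 4.5%); the experiment pipelines expose
a `--full` flag restoring 10⁵-trial scale. The default stimulus policy
fixes one logged random θ per experiment, valid because the information is
θ-independent.

## Empirical statistics

Covariances use the unbiased (n−1) estimator at a fixed stimulus. The
scatter diagnostic pairs each element of the empirical covariance with the
corresponding element of `μμᵀ` and fits diagonal and off-diagonal groups
separately by ordinary (unweighted) least squares, recovering `σ₁²`
(slopes) and `σ₀²` (diagonal intercept); fits are per-α. The marginal
eigenspectrum pools responses over a deterministic uniform stimulus grid
(`n_theta > 2N` keeps the Fourier modes exactly orthogonal under the
discrete average; a random-θ option exists), subtracts the grand mean, and
diagonalizes the pooled covariance. Slope recovery pairs the cos/sin
eigenvalue partners, subtracts the `σ₀²` noise floor, and fits
`log λ_n` vs `log n` over the leading modes (default window: the first 10,
where the signal dominates the sampling spread of the noise eigenvalues).

## Known limitations

- **The covariance identity is a small-noise result.** Exact sampling of
  the model deviates from `Σ = σ₀²I + σ₁²μμᵀ` once `n·σ₁` is not small for
  the highest retained modes: at `N=100, σ₁=0.01`, mode 100 has `n·σ₁ = 1`
  and the deviation is systematic, not Monte-Carlo. Gauss–Hermite
  quadrature of the exact covariance (no sampling) puts the Rayleigh
  quotient `μᵀΣμ/μᵀμ` at 0.742·λ for α=2, 0.930·λ for α=3 and 0.997·λ for
  α=4, with matching deficits in the scatter slope. The tests assert the
  small-noise predictions as stated and the α ≤ 3 checks at N=100 fail for
  this reason; the identity holds to high accuracy whenever `N·σ₁ ≪ 1`
  (verified separately against the exact-quadrature oracle).
- Sampling and decoding are implemented for D=1 only; higher D enters
  through the closed-form theory. D>1 simulation is refused with an
  explicit error rather than approximated.
- The plateau branch `1/σ_i²` requires `σ_i > 0`; a noiseless code is
  rejected as degenerate (infinite information).
- Fisher theory assumes isotropic neural noise; correlated neural noise and
  stimulus-dependent information are out of scope.
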