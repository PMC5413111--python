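# Methods

This note records the model, its assumptions, the parameter choices and the
numerical conventions used throughout `popinfo`, including the points where
the design was genuinely open and a choice had to be made.

## Model

The encoding stage is the standard tuning-curve-plus-noise model
`x = f(s) + ξ` for a one-dimensional circular stimulus `s ∈ [0, 2π)`, with
`ξ` zero-mean noise of covariance `Σ_ξ(s)`.  The transmission stage is a
feedforward layer `y = g(W·x + ζ) + η`, with a pointwise gain `g`,
pre-nonlinearity noise `ζ` (covariance `Σ_ζ`) and output noise `η`
(covariance `Σ_η`).  Coding efficacy is quantified by linear Fisher
information — the inverse variance of the locally optimal linear stimulus
estimator — in the input layer (`I_x = f′ᵀΣ_ξ⁻¹f′`) and, after
linearization of the gain around the mean drive `h = W·f(s)`, in the output
layer:

    I_y = f′ᵀ [Σ_ξ + (W_effᵀ Σ_eff,η⁻¹ W_eff)⁻¹]⁻¹ f′,
    W_eff = Ḡ′ W,     Σ_eff,η = Ḡ′ Σ_ζ Ḡ′ + δΣ_g + Σ_η,

where `Ḡ′` is the diagonal matrix of average gain slopes
`ḡ′(h_i) = d/dh E[g(h_i + χ_i)]` (with `χ = W·ξ + ζ` the total
pre-nonlinearity noise) and `δΣ_g = Cov[g(h+χ)] − Ḡ′Σ_χḠ′` the excess
covariance the nonlinearity introduces.  `δΣ_g` vanishes for linear gains
and is positive semi-definite for Gaussian `χ` (it equals the covariance of
`g(h+χ) − Ḡ′χ`); the package treats it as an effective noise source and
verifies both properties by Monte Carlo in the tests.  The equivalent
"direct" form `I_y = (W_eff f′)ᵀ[W_eff Σ_ξ W_effᵀ + Σ_eff,η]⁻¹(W_eff f′)`
is implemented separately and is valid for any layer sizes; the two forms
are cross-checked against each other on random instances.

Linear Fisher information coincides with full Fisher information for
exponential-family responses with linear sufficient statistics and is used
here for all layers, including the binary spiking layer, where the output
information is estimated as `μ′ᵀ Cov(y)⁻¹ μ′` from the analytic mean and a
Monte-Carlo covariance.

## Tuning populations

Neurons have Von Mises tuning curves
`f_i(s) = ρ_i + υ_i exp(β_i(cos(s−φ_i) − 1))`, with parameters drawn
independently and uniformly per neuron: baseline `ρ ∈ [0,1]`, amplitude
`υ ∈ [1,51]`, width `β ∈ [1,6]`, preferred stimulus `φ ∈ [0,2π)` (half-open
sampling; immaterial for a continuous distribution).  These ranges give
peak rates up to ~52 rate units and tuning widths typical of
direction-selective sensory neurons.  The stimulus derivative `f′(s)` — the
signal direction — is evaluated analytically; the information formulas are
sensitive to its accuracy, so finite differences exist only as a test
oracle.  Stimuli are radians everywhere; no degrees.

## Covariance constructions and calibration

All constructions start from the Poisson-like base `Σ₀ = diag(f(s))`
(variance equal to the mean, Fano factor exactly 1) and add a rank-1 term:

* **aligned**: `Σ₀ + ε f′f′ᵀ` — weak differential correlations on top of
  Poisson-like variability (default `ε = 10⁻³`; the synergistic variant
  uses `ε = −5×10⁻⁴`);
* **tilted**: `Σ₀ + ε_u u uᵀ` with `|u(s)| = |f′(s)|` and
  `angle(u, f′) = θ_u` (defaults: 1/8 rad for the redundant comparison,
  1/4 rad for the synergistic one).  `ε_u(s)` is solved in closed form —
  the information of a diagonal-plus-rank-1 matrix is a linear-fractional
  function of the strength via Sherman–Morrison — so that the tilted
  population carries exactly the aligned population's information at every
  stimulus.

**Tilt plane.**  The rotation plane of `u` away from `f′` is `n−2`-fold
ambiguous.  The package fixes one auxiliary random vector per experiment,
orthogonalizes it against `f′(s)` at each stimulus, and rotates within that
plane: reproducible, stimulus-continuous, and preserving the angle exactly.
The matched strength `ε_u(s)` is heavy-tailed across population draws: for
roughly a third of tuning draws the matching is near-singular at some
stimulus (the tilted direction barely spans the required information
change) and either fails positive semi-definiteness or produces extreme
strengths.  The generation recipe therefore rejects such draws — see
"Rejection sampling" below.

**Scale normalization.**  For sweeps in `ε_u` at fixed input information,
the whole perturbed matrix is rescaled: `Σ_ξ = γ_u (Σ₀ + ε_u u uᵀ)` with
`γ_u = [f′ᵀΣ₀⁻¹f′ − ε_u (f′ᵀΣ₀⁻¹u)²/(1 + ε_u uᵀΣ₀⁻¹u)] / I_x`.  With the
scale applied to the full matrix, the input information equals the target
exactly for every admissible `(ε_u, u)` — this is asserted to 1e-8 relative
throughout the sweeps.

**Optimal family.**  With a fixed downstream effective covariance
`Σ_y = (W_effᵀΣ_η⁻¹W_eff)⁻¹` and linear gain, the input covariances that
maximize output information at fixed `I_x` form the one-parameter family
`Σ_ξ(α) = (α I_η/I_x) Σ_y + ((1−α)/I_x) f′f′ᵀ`, `I_η = f′ᵀΣ_y⁻¹f′`.
`α = 0` is pure differential correlations (`f′f′ᵀ/I_x`, the only member
independent of the downstream circuit); `α = 1` is the matched covariance
`∝ Σ_y`.  Every PSD member transmits `I_y = I_x/(1 + I_x/I_η)`, verified
numerically to 1e-8 relative spread.  The additional freedom of adding
noise orthogonal to `f′` (which leaves the information untouched) is not
constructed.  Differential correlations also *minimize* information among
trace-constrained covariances (`I_min = |f′|²/C₀`), which the tests verify
against 1000 random trace-matched PSD matrices.

## Spiking layer

The dichotomized-Gaussian model thresholds the Gaussian latent input:
`y_i = 1[x_i + ζ_i ≥ θ_i]`, spike thresholds `θ_i = 0.75(ρ_i + υ_i)` (3/4
of each cell's peak rate), pre-threshold noise iid Gaussian with variance
`σ_ζ²`.  Means are analytic, `μ_i(s) = Φ((f_i(s) − θ_i)/σ_i(s))` with
`σ_i(s)² = Σ_ξ,ii(s) + σ_ζ²`; the covariance has no convenient closed form
and is estimated from Monte-Carlo draws.  Sampling uses the structured form
`x = f + √γ_u·√f⊙z + √(γ_u ε_u)·w·u` (iid normal vector `z`, scalar `w`)
rather than a dense factorization; the two samplers are checked to agree
statistically.

Numerical conventions for the Monte-Carlo information `μ′ᵀCov(y)⁻¹μ′`:

* `μ′(s)` is a central finite difference of the analytic mean with step
  `Δs = 10⁻⁴` rad, re-evaluating the full covariance construction
  (`u(s±Δs)`, `γ_u(s±Δs)`, `ε_u(s±Δs)`) at the shifted stimuli; the mean is
  smooth, and differentiating analytically through the calibration terms
  would be brittle.
* The estimate is restricted to the **sampled support**: cells whose
  observed variance is exactly zero (far-from-threshold cells that never
  fire in the draw budget) are excluded.  Their analytic `μ′` is tiny but
  nonzero, and a diagonal ridge would otherwise convert it into arbitrarily
  large spurious information (`μ′²/ridge`).  The cost is a small downward
  bias: information carried by cells too rare to sample is not counted; it
  shrinks as the draw budget grows.
* Within the support, a relative ridge of `10⁻⁹ × mean(diag)` guards
  against occasional ill-conditioning of the binary covariance.
* The standard error is the spread of the same estimator over 10 disjoint
  batches of the draws.
* Default draw budget `10⁶` per stimulus; the test profile uses `10⁵` with
  30 neurons so the full suite runs in minutes.

Average gain slopes for generic nonlinearities are computed by 101-node
Gauss–Hermite quadrature with the Stein identity
`ḡ′(h) = E[z·g(h+σz)]/σ`, which is valid even for discontinuous gains;
linear and step gains use closed forms (for the step,
`ḡ′ = φ((h−θ)/σ)/σ`).  The quadrature path should only be relied on for
smooth gains.

## Experiments

* **Linear-channel comparison** (redundant and synergistic variants):
  100 neurons, 100 equally spaced stimuli, identity weights, linear gain,
  iid output noise with `σ²` on `{0} ∪ logspace(10⁻³, 10², 20)` (the
  original comparisons plot but do not tabulate their grid; this one covers
  the interesting range).  Output information across the `σ²` grid is
  computed from one eigendecomposition of `Σ_ξ(s)` per stimulus.
  Trial-shuffled information zeroes the off-diagonal entries.
* **Rejection sampling**: tuning draws are repeated until the aligned and
  tilted populations' average correlations agree to `10⁻⁵` (the average
  correlations themselves are at the `10⁻⁴`–`10⁻⁵` scale, so this
  reproduces "matched" at the precision those values are quoted at;
  typical acceptance takes tens of draws).  Draws with infeasible
  per-stimulus matching are rejected outright.  Besides controlling for
  average correlation, this step removes the heavy tail of near-singular
  matchings, stabilizing the ensemble Fano factors at ≈1.015 (aligned) and
  ≈1.03–1.04 (tilted) for the redundant pair and ≈0.99 for the synergistic
  pair, with mean matched strengths of order 10⁻³ (redundant) and −3×10⁻⁴
  (synergistic).
* **Spiking sweeps**: 20 equally spaced stimuli, `ε_u` on
  `logspace(10⁻⁴, 10⁻¹, 8)`, tilt angles `{0, 0.05, 0.1, 0.2}` (noise-free)
  or `{0, 0.1}` with pre-threshold variances `{0, 1, 4, 16}` — the specific
  angle set and noise levels beyond 0.1 rad are this package's choice.  The
  per-stimulus input-information target is the unperturbed value `I₀(s)`.
  Monte-Carlo streams are keyed by (angle, strength, stimulus) but not by
  the noise level, so runs at different `σ_ζ²` share latent draws (common
  random numbers) and the zero-noise sweep of the noisy pipeline reproduces
  the noise-free pipeline bit-for-bit.

## Numerical conventions

* All solves with covariance matrices go through symmetric
  (eigen)factorizations; explicit inverses appear only where the inverse
  matrix itself is the contract (the Sherman–Morrison rank-1 inverse).
* PSD checks symmetrize first and tolerate a minimum eigenvalue down to
  `−10⁻¹⁰ ×` the spectral norm.  Constructors reject violations, naming the
  offending eigenvalue.
* Singular covariances (differential correlations are rank 1) are handled
  by a support-restricted pseudo-inverse, triggered when the relative
  condition number exceeds `10¹²`, with a warning.  If `f′` has a component
  outside the support the information is infinite and an error is raised
  instead — this choice of convention for the exactly singular limit is the
  package's own.
* Randomness: generators are explicit arguments everywhere; experiment
  pipelines derive one stream per stage (population draw, auxiliary tilt
  direction, each Monte-Carlo cell) from the run seed via spawn keys, so
  changing one stage's consumption cannot desynchronize the others and
  every table reproduces bit-for-bit.

## What the synthetic data does and does not show

All inputs are generated internally from the stated parameter
distributions; there is no recorded data anywhere.  The generator emulates
heterogeneous, Poisson-like, weakly correlated populations with
rank-1-structured covariances — the regime in which the robustness theory
is sharp.  It does not emulate non-Gaussian response statistics, refractory
or temporal structure, stimulus-dependent gain changes, or covariance
structure beyond diagonal-plus-rank-1 (and the optimal family).  Passing
tests therefore demonstrate the internal consistency of the framework and
the behavior of these model classes, not properties of any recorded neural
population.

## Known limitations

* The Monte-Carlo information estimator is support-restricted (see above)
  and mildly biased upward by finite-sample covariance estimation; both
  effects shrink with the draw budget.
* The generic smoothed-slope quadrature degrades for discontinuous gains —
  use the dedicated step-gain class there.
* Only single-window binary responses are modeled in the spiking layer; no
  spike trains, no recurrence, no time dependence.
* Shannon mutual information, bias-corrected information estimation from
  finite trial counts, and covariance estimation from data are out of
  scope.
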