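# popinfo

Tools for asking not just *how much* stimulus information a noisy neural
population encodes, but how much of it **survives transmission** through a
noisy, possibly nonlinear, downstream layer.

Sensory information is carried by trial-to-trial-variable population
activity ``x = f(s) + ξ`` (tuning curves ``f``, noise covariance ``Σ_ξ(s)``)
and reaches the next processing stage as ``y = g(W·x + ζ) + η``.  Two
populations with identical tuning curves and identical encoded information
can differ hugely in how robust that information is to the channel's noise;
what matters is the geometry of the noise covariance relative to the signal
direction ``f′(s)``.  `popinfo` implements the covariance structures,
information measures and numerical experiments needed to study this.

## What it computes

* **Linear Fisher information** in the input layer, ``I_x(s) = f′ᵀ Σ_ξ⁻¹ f′``,
  and in the output layer,
  ``I_y(s) = f′ᵀ [Σ_ξ + (W_effᵀ Σ_eff,η⁻¹ W_eff)⁻¹]⁻¹ f′``,
  where ``W_eff`` are the weights scaled by the average gain slope and
  ``Σ_eff,η`` is the effective output noise (including the excess
  covariance ``δΣ_g`` a nonlinearity adds).  Trial-shuffled (correlation-
  removed) information diagnoses redundancy versus synergy.
* **Structured input covariances**: Poisson-like base ``Σ₀ = diag(f)``,
  rank-1 perturbations ``γ_u Σ₀ + ε u uᵀ`` with the direction ``u(s)``
  aligned with or tilted away from ``f′(s)``, pure differential
  correlations ``f′f′ᵀ/I_x``, and the family of robustness-optimal
  covariances ``Σ_ξ(α) = (α I_η/I_x) Σ_y + ((1−α)/I_x) f′f′ᵀ`` — every PSD
  member carries the same input information and transmits the maximal
  output information ``I_x/(1 + I_x/I_η)``.
* **Calibration helpers** that hold information fixed while structure
  varies: `epsilon_match` (solve the rank-1 strength so two populations are
  equally informative) and `gamma_u_normalization` (overall rescaling that
  pins ``I_x`` for any ``(ε_u, u)``).
* **A dichotomized-Gaussian spiking channel** (``y_i = 1[x_i + ζ_i ≥ θ_i]``)
  with analytic means ``μ_i = Φ((f_i − θ_i)/σ_i)`` and Monte-Carlo
  covariance/Fisher estimation for information through an extreme
  spike-generating nonlinearity.
* **Seeded experiment pipelines** reproducing the robustness comparisons:
  linear channels with redundant or synergistic codes, spiking channels
  with and without pre-threshold noise, and a numerical verification of the
  optimal family.  Every pipeline is a pure function of its config + seed.

## Worked example

Build two equally informative 100-neuron populations — rank-1 noise along
``f′(s)`` versus tilted by 1/8 rad — and watch how differently their
information survives added output noise:

```python
import numpy as np
from popinfo import (sample_population, poisson_diagonal, tilted_direction,
                     epsilon_match, rank1_covariance, linear_fisher)

rng = np.random.default_rng(0)
pop = sample_population(100, rng)          # 100 Von Mises tuning curves
s = np.pi / 3                              # one stimulus (radians)
f, fp = pop.rates(s), pop.derivatives(s)

S0 = poisson_diagonal(f)                   # Poisson-like base covariance
aligned = rank1_covariance(S0, 1.0, 1e-3, fp)        # noise along f'(s)
Ix = linear_fisher(fp, aligned)

u = tilted_direction(fp, 1 / 8, rng=rng)   # same length, tilted by 1/8 rad
eps_u = epsilon_match(fp, S0, u, Ix)       # match the input information
tilted = rank1_covariance(S0, 1.0, eps_u, u)

print(f"input information I_x = {Ix:.1f} rad^-2 (both populations)")
print(f"matched tilted strength eps_u = {eps_u:.2e}")
for s2 in (1.0, 10.0, 100.0):
    Iya = linear_fisher(fp, aligned + s2 * np.eye(100))
    Iyt = linear_fisher(fp, tilted + s2 * np.eye(100))
    print(f"sigma^2 = {s2:5.1f}:  I_y aligned = {Iya:6.1f}   tilted = {Iyt:6.1f}")
```

Output:

```
input information I_x = 580.8 rad^-2 (both populations)
matched tilted strength eps_u = 2.06e-03
sigma^2 =   1.0:  I_y aligned =  553.9   tilted =  414.3
sigma^2 =  10.0:  I_y aligned =  427.9   tilted =  306.7
sigma^2 = 100.0:  I_y aligned =  151.6   tilted =  131.4
```

Both populations start from the same 580.8 rad⁻² of encoded information
(the matched strength ``ε_u ≈ 2×10⁻³`` enforces this), yet already at
``σ² = 1`` the population whose noise is concentrated along the signal
direction retains 554 rad⁻² while the slightly tilted one has dropped to
414 — a tilt of 1/8 rad in a 100-dimensional space is enough to make the
code markedly more fragile.

Full experiments run from the shell and write `results.csv`,
`config_resolved.yaml`, `manifest.yaml` and `log.txt`:

```bash
popinfo run fig2 --seed 0 --out runs/fig2          # linear channel, redundant codes
popinfo run fig6 --profile test --seed 0 --out runs/fig6   # spiking channel + input noise
popinfo plot runs/fig2/results.csv --out runs/fig2/robustness.png
```

## Layout

```
src/popinfo/
  tuning.py       Von Mises populations, sampling, CSV (de)serialization
  covariance.py   structured covariances, information matching, optimal family
  fisher.py       linear Fisher information (input/output/shuffled/2-D geometry)
  channel.py      gains, effective weights, delta-Sigma_g, DG spiking, MC Fisher
  experiments.py  seeded pipelines (fig2/fig5/fig6/fig7/family sweeps)
  config.py       YAML configs, result writing, run manifests
  cli.py          `popinfo run` / `popinfo plot`
docs/methods.md   model assumptions, parameter choices, numerical conventions
```
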