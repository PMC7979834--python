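# ddemotifs

Delay-differential-equation (DDE) models of the canonical gene-regulatory
network motifs: direct regulation, cascades, autoregulation, two-input
logic, feedforward loops, two-component feedback and double self-feedback.
The package is for systems biologists and dynamical-systems modelers who
want explicit regulatory delays — rather than chains of intermediate
species — to carry the timescales of a network, together with the analytic
machinery that makes delayed motifs tractable.

## The model

Every regulatory edge is a delayed, signed Hill term.  In dimensionless
units (concentrations in units of the half-maximal input *k*, time in
units of the degradation time 1/β) a node obeys

    dX_i/dT = ε_i + Σ_j η_j / (1 + X_j^{n_j}(T − γ_j)) − X_i(T)

where η is the regulation strength, γ the regulatory delay, ε the leakage
and the *signed* cooperativity n selects the mode: n > 0 represses,
n < 0 activates (with effective cooperativity |n|), n = 0 is constitutive.
One function therefore covers activators and repressors at once, and a
six-parameter dimensional edge (α₀, α, k, β, τ, n) reduces to four
(ε, η, γ, n).

On top of the motif right-hand sides the package provides:

* a bespoke method-of-steps integrator (embedded Runge–Kutta 2(3), cubic
  Hermite dense output, delay-discontinuity breakpoints, ensemble runs);
* closed-form bifurcation analysis of delayed autoregulation — fixed
  points of X(1+Xⁿ) = η, the transcendental characteristic equation
  λ + ηM e^{−γλ} + 1 = 0 solved exactly via Lambert-W branches, the
  saddle-node boundary η = −n(−n−1)^{−(−n−1)/(−n)}, Hopf branches
  γ(ω) = (πk − tan⁻¹ω)/ω, the damped-oscillation (spiral) boundary and
  the period estimate 2(γ+1);
* the analogous eigenmode analysis for two-component loops, where onset of
  oscillation depends on the delays only through their mean and the X–Y
  phase offset only through their difference;
* steady-state logic of two-input summed-Hill regulation: all 14 monotone
  two-input gates arranged on the (sgn(n₁)η₁, sgn(n₂)η₂) chart;
* closed-form step-pulse and Fourier frequency responses of feedforward
  loops, including the universal response envelope I₀/√(1+(2πkf)²);
* the simulation-based phase classifier used to shade phase diagrams
  (ensembles of constant histories, derivative/spectrum/histogram rules);
* chaos diagnostics for double feedback: delay embedding, Wolf
  nearest-neighbor Lyapunov exponents and box-counting dimension.

## Worked example

Delayed negative autoregulation (η = 10, n = 2, γ = 5) oscillates; the
analytics predict it, the simulation confirms it, and the period lands
near the estimate 2(γ+1) = 12:

```python
import numpy as np
from ddemotifs import build_motif, integrate, resample_uniform
from ddemotifs.autoreg import classify_analytic, period_estimate
from ddemotifs.classifier import oscillation_features

print(classify_analytic(eta=10, gamma=5, n=2))   # oscillatory
print(period_estimate(5.0))                      # 12.0

m = build_motif("autoregulation", eta=10, n=2, gamma=5)
traj = integrate(m, [0.3], t_end=240.0)
ts, vs = resample_uniform(traj, 0.3, t_start=60.0)
feat = oscillation_features(vs[:, 0], 0.3, threshold=1.0)
print(round(feat["dominant_period"], 2))         # 12.02
print(round(feat["amplitude"], 2))               # 4.46
```

The classifier labels the point oscillatory from the closed-form Hopf
boundary; the simulated trajectory then shows a relaxation oscillation
whose dominant spectral period (12.02) matches the analytic estimate and
whose amplitude is about 4.5 concentration units.

The same machinery drives a small CLI (`ddemotifs simulate|classify|
bifurcation|logic|ffl|chaos|phase-map <config.yaml>`) whose YAML config
schema is documented in `ddemotifs/cli.py`; registered fixtures
(`fig2` … `fig8`) reproduce the headline scenarios.

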