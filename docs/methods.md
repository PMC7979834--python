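# Methods

This note documents the models, numerical choices and protocols behind
`ddemotifs`, in the package's own words: what is computed, under which
assumptions, and what the shipped tests do and do not establish.

## The unified delayed Hill model

All motifs are built from one regulation primitive,

    dX_i/dT = ε_i + Σ_j η_j / (1 + (K_j X_j)^{n_j}(T − γ_j)) − X_i(T),

with dimensionless strength η ≥ 0, delay γ ≥ 0, leakage ε ≥ 0, input-scale
ratio K > 0 and signed cooperativity n (n > 0 repression, n < 0
activation, n = 0 constitutive).  Removal is first-order and undelayed —
delayed removal can drive concentrations negative and has no biological
counterpart here.  Nondimensionalization measures concentrations in units
of the half-maximal input k and time in units of the degradation time
1/β, so ε = α₀/kβ, η = α/kβ, γ = τβ.

Activator terms are evaluated through the algebraically equivalent form
ε + η(Kx)^{|n|}/(1 + (Kx)^{|n|}) everywhere, so x = 0 is exactly
representable (no division by zero) and the activator limit at zero input
is exactly ε.  The constitutive case n = 0 returns ε + η/2; it is
degenerate with (n ≠ 0, η = 0, ε → ε + η/2).

K defaults to 1 and only matters when two terms share a source (the
feedforward motif); motif builders do not accept K elsewhere.  Relative
degradation rates enter as a per-node `beta_ratio` multiplying the time
derivative, with the reference node pinned to 1, which is how
three-species cascades with unequal β are expressed.

## Cascade reduction

A two-step Hill cascade collapses onto one delayed Hill step by matching
the composite response at input 0, 1 and ∞ plus its slope at 1.  The
resulting effective coefficient h = −(n_X n_Y/2)·2^{|n_Y|}/(2^{|n_Y|}−1)
is negatively proportional to the product of the step cooperativities
(two like-signed steps activate, mixed signs repress), the effective
delay is β_z/β_y plus any intrinsic per-step delays, and leakage vanishes
when the intermediate is an activator.  The approximation's validity
envelope in (η_Y, n_Y) is not characterized analytically; the test suite
reports the sup-norm discrepancy against the full cascade on the
reference parameter set (η_X = 1.5, η_Y = η_Z = 2.17, n = −2,
β_x/β_y = 0.5) and requires it below 10% of the output range rather than
asserting a universal bound.

## DDE integration

The integrator advances a Bogacki–Shampine embedded 2(3) pair by the
method of steps: the step size is capped at the smallest positive delay,
so delayed lookups always land in the already-accepted span (history for
lagged times ≤ 0).  Dense output is per-segment cubic Hermite from the
accepted states and one-sided derivatives.  Derivative discontinuities
propagate from T = 0 and from input kinks; all sums of up to three delays
(deduplicated at 1e-12 relative spacing) are inserted as mesh points.
Zero-delay terms are evaluated from the current stage state.  Defaults
are rtol 1e-6, atol 1e-9.  States are never clipped at zero:
nonnegativity is a theorem for nonnegative histories and parameters, so
the tests assert it (min ≥ −10·atol) instead of enforcing it, and the
bound lim sup X ≤ ε + Ση is asserted the same way.

Ensembles of constant histories integrate in one pass as a
(nodes × members) state with a shared adaptive step controlled by the
worst member; members are bitwise-reproducible functions of the inputs
(no randomness anywhere in the integrator).

Validation: exact piecewise-polynomial solutions of x' = a·x(t−τ), the
ODE limit against a reference solver, equilibrium preservation, and
monotone convergence under tolerance tightening.

## Autoregulation analytics

Fixed points solve X(1+Xⁿ) = η (plus the origin for activators) and are
delay-independent.  Stability comes from the rightmost roots of
λ + ηM e^{−γλ} + 1 = 0 with M(X*) = nX*^{n−1}/(1+X*ⁿ)², computed exactly
as λ = −1 + W_k(−aγe^γ)/γ over Lambert-W branches (an asymptotic branch
expansion takes over when γ + ln(aγ) > 600, where e^γ overflows).  Every
returned root is residual-checked below 1e-9; the Newton-plus-winding-
count scheme one might use instead is unnecessary because the Lambert-W
form enumerates branches completely.

Closed-form boundaries: the saddle-node curve η = −n(−n−1)^{−(−n−1)/(−n)}
(bistability of autoactivation, confined to 1 ≤ η ≤ 2 with the maximum at
−n = 2); Hopf branches γ(ω) = (πk − tan⁻¹ω)/ω with
η(ω) = q(q−1)^{−(n+1)/n}, q = |n|/√(1+ω²), ω ∈ (0, √(n²−1)), of which
k = 1 is the oscillation onset for n > 1; and the spiral (damped-
oscillation) boundary η = q(q−1)^{−(n+1)/n} with q = nγe^{γ+1}.  At the
origin of an activator, M has one-sided limits (divergent for
−1 < n < 0, −1 at n = −1, zero for n < −1), which is what makes the
origin unstable only for weak cooperativity.  Classification ties within
1e-9 of a boundary resolve to the less exotic label (monostable over
spiral over oscillatory).  Boundary formulas refuse ε ≠ 0; fixed-point
finding accepts it (the scan generalizes).

The oscillation period estimate is 2(γ+1): after each delay the state is
pushed across its midpoint and re-equilibrates on the degradation time.

## Two-component loops

With equal degradation rates (unequal rates are rejected), perturbations
about a fixed point split into two modes with characteristic equations
λ ± √(η₁M₁η₂M₂) e^{−λ⟨γ⟩} + 1 = 0, ⟨γ⟩ = (γ₁+γ₂)/2 — the same Lambert-W
machinery applies with a complex coefficient.  The implementation works
with the product η₁M₁·η₂M₂ and explicit mode parity, avoiding square-root
branch ambiguity.  The physical X→Y phase offset of a mode is arg(B/A)
evaluated at its root (the mode-parity π is contained in the ratio's
sign, so no separate correction is applied): synchronous for two
repressors, anti-synchronous for two activators, quarter-period for
mixed loops at equal delays.  Oscillation onset depends on the delays
only through their mean; the offset only through their difference.

Saddle-node and Hopf boundary curves are swept along the constraint
f(X,Y) = F·XⁿʸYⁿˣ/((1+Xⁿʸ)(1+Yⁿˣ)) = 1 by inverting the monotone map
u = Yⁿ/(1+Yⁿ) in closed form.  The delay expressions of the Hopf curve
contain the eigenmode phase, which itself depends on the delay split;
substituting one into the other shows the pair is identically consistent
for any split, so the phase is computed directly from the requested
γ₁ − γ₂ and the consistency asserted (no iteration needed).

Loop classification is computed from first principles — count and
stability of fixed points plus the dominant mode roots — which is
equivalent to "beyond/inside the closed-form curves" but robust for
asymmetric parameters.

## Logic gates

Steady-state output of the two-input summed-Hill motif is thresholded
against 1 (the downstream reporter's half-maximal input after
normalization).  In the ideal saturated-input limit each arm contributes
either 0 or its full η per corner of the truth table, so the gate name
follows from the corner pattern; monotonicity of summation makes XOR and
XNOR unreachable.  The chart depends only on sgn(n₁)η₁ and sgn(n₂)η₂.
TRUE (always on) is emitted only when an explicit finite input scale is
supplied and every corner stays above threshold at it, since the always-
on criterion depends on how far a repressor arm can actually be shut off
(η relative to max(X^{|n|})).  `truth_table` defaults to low = 0.1,
high = 10; `fuzzy_margin` reports how close the nearest decision quantity
came to 1, quantifying the fuzzy-logic caveat near the boundaries.  A
dynamic verification path through a steep reporter (n₃ = −20) is provided
in the fixtures and tests; the classifier itself is purely parametric.

## Feedforward responses

For a square input pulse the output is the closed form
Z(T) = Z_ss + sgn(n₁)η₁Z₁^{n₁}f(T) + sgn(n₂)η₂Z_K^{n₂}f(T−Δγ) with
f(T) = (1−e^{−T})Θ(T) − (1−e^{−(T−w)})Θ(T−w); the pulse width is named
`w` (ω is reserved for angular frequency).  Under sinusoidal input
X = A(1+cos 2πfT) the harmonic magnitudes and phases follow from the
Fourier coefficients a_k of 1/(1+Xⁿ), computed by adaptive quadrature at
relative tolerance 1e-10 with the activator integrand rewritten through
x^{|n|} so the zero-input point is regular; k_max defaults to 16.  The
envelope I₀/√(1+(2πkf)²) is delay- and logic-independent; the response
touches it at frequencies commensurate with 1/Δγ.

One consequence of a_k^{−n} = −a_k^{n} deserves emphasis because prose
descriptions often get it backwards: for a perfectly balanced incoherent
motif (η₁ = η₂, n₁ = −n₂, K = 1) the fundamental vanishes at *integer*
multiples of 1/Δγ (where the interference cosine is +1), and peaks at
half-integer multiples.  Both the magnitude formula and direct DDE
simulation of the motif agree on this (simulated I₁ < 1e-6 at f = 1/Δγ,
I₁ ≈ 0.55 at f = 1/(2Δγ) for η = 0.8, Δγ = 4), so that is what the tests
assert.  The band-pass activation criterion for a unity-threshold
reporter is max_f I₁ > 1 − ⟨I⟩ with ⟨I⟩ the DC term.

## Phase classification by simulation

Autoregulation: 100 constant histories log-spaced on [1e-4, 2η],
integrated to T_end = 100(γ+1).  Stability requires the largest absolute
discrete derivative (first difference of the resampled series over its
spacing) in the last three-quarters below 0.1 for every member.
Spectrum protocol (fixed, since the underlying convention is otherwise
ambiguous): resample the window onto 8192 uniform points, remove the
mean, average the unnormalized rFFT magnitude across members, and count
strict local maxima above amplitude 100 starting at bin 2 — bin 1
borders the zeroed DC bin and would flag any monotone relaxation.
Oscillatory = sustained peak in the last three-quarters; spiral = peak in
the first quarter only; bistable = stable with a multi-peaked histogram
of final values (20 equal-width bins over the observed range, a peak
being a bin strictly above both neighbors holding > 2% of the ensemble —
basins of genuine second states can be small under the prescribed IC
spread, so the floor only guards against stragglers; a range narrower
than 1% of the state scale counts as one state).  Loops use equal and
apposing (X, Y) arrangements spanning 0 to max(η₁, η₂), with bistable
points annotated correlated vs anti-correlated by splitting each
member's final state at the midpoint of the observed range (cutoff floor
0.05).  The protocol is deterministic end to end.

On a boundary-excluded (η, γ) grid (points whose analytic label is not
constant under ±0.2 perturbations are dropped), simulated labels match
the closed-form boundaries at 100% on the shipped grid; the acceptance
test requires ≥ 98%.  The test grid uses 2.0-spacing over (0.2, 10]² for
n ∈ {−3, −2, 2, 3} — a reduced resolution chosen to keep the suite's
ensemble-integration time in minutes; the agreement rate was insensitive
to refining the grid in spot checks.

## Chaos diagnostics

Scalar series are delay-embedded as (X(T), X(T−10), X(T−20)).  For the
double-feedback protocol the orbit convention is the delay-oscillator
period estimate 2(γ_max+1) (= 24 for the reference parameters), the
series is resampled at ~55 points per orbit with the 10-unit embedding
delay an exact multiple of the sampling interval, and the first
max(20% of the run, 10(γ₁+γ₂)) is discarded as transient.

Wolf exponent: track a fiducial point and a neighbor whose separation
starts inside a scale band (0.1%–10% of the attractor diameter by
default), accumulate log₂ of the separation growth per evolution
interval, and renormalize onto a fresh neighbor — preferring one aligned
with the current separation direction within 0.3π — whenever the band is
left or the neighbor runs off the end of the series.  Re-anchoring after
*every* interval (an alternative reading of the classic algorithm)
overestimates the Lorenz benchmark two-fold and is available behind a
flag but off by default.  The estimate is the mean ± sd of the running
exponent over the last 50 iterations.  On a Lorenz-system embedding the
default protocol lands in 1.3–2.0 bits/time against the true 1.31: the
method's known upward bias at short horizons (nearest-neighbor stretch
exceeds the global exponent until orientations average out), which is why
the shipped test asserts an order-of-magnitude band rather than the
exact value.

Box-counting dimension: normalize the cloud to the unit cube, count
occupied dyadic boxes at side 2^{−j}, drop saturated levels (count
> 90% of the points), and regress log₂N on j over the *finest*
contiguous half (≥ 4 levels) of what remains, reporting the slope with
its 95% CI.  The coarsest levels (a handful of boxes) carry no scaling
statistics and systematically steepen the slope, so "half the linear
domain" is read as the fine half.

For the double-feedback protocol specifically, the evolution interval is
fixed at about half an orbit (30 samples).  The calibration target is
internal: a direct twin-trajectory experiment (two constant histories
10⁻⁸ apart integrated side by side) measures this attractor's divergence
rate at ≈ 0.0035 bits per unit time, and the Wolf estimate converges
onto that rate as the horizon grows (0.006–0.010 at sub-orbit horizons,
0.0043 ± 0.0004 at the half-orbit setting), mirroring the bias-vs-
horizon behavior on the Lorenz benchmark.

Verdicts: chaotic requires the exponent positive at 2σ; quasiperiodic
requires |mean| ≤ 2σ with a dimension CI containing ≈ 2; decayed and
plain periodic signals fall out as fixed/periodic.

## Study conditions and their sensitivity

The chaotic reference point (η₁ = 15, η₂ = 1, n₁ = 11, n₂ = −3, γ₁ = 1,
γ₂ = 11, constant history 0.5) sits in a parameter region where windows
of complex dynamics alternate with simple oscillation as γ₂ varies; the
bifurcation-scan protocol (collect distinct local maxima per γ₂ after
transients) exhibits ≥ 2 regime switches over γ₂ ∈ [2, 14].

Dynamics in such windows are sensitive to integration accuracy, and here
decisively so: at this package's default tolerances (rtol 1e-6) every
probed constant history settles onto a *regular* attractor — twin
trajectories separated by 10⁻⁸ remain within a stationary band,
amplified ~12× but never growing, for 9000 time units — whereas at the
default accuracy of the classic DDE solvers this protocol emulates
(relative tolerance 1e-3) the same parameters produce a strange
attractor with exponential twin divergence at ≈ 0.0035 bits per unit
time and box dimension ≈ 1.87.  The chaos protocol therefore pins
rtol 1e-3 / atol 1e-6 in `double_feedback_series` as part of its study
conditions; all other protocols keep the tight defaults.  Consumers
should treat the chaotic attractor as a property of the model *under
that integration contract*, and should not expect digit-level agreement
of the exponent across integrators.

## What the synthetic tests do not show

All inputs are generated by the package itself (constant histories,
square pulses, sinusoids, registered parameter sets).  The models omit
intrinsic noise, stochastic or state-dependent delays, non-constant
histories, saturating degradation and spatial coupling; passing tests
demonstrate internal consistency of the analytics, the integrator and
the classifiers under the stated model class, not agreement of that
model class with any particular experimental system.  The quasiperiodic
verdict path is exercised with a synthetic two-frequency torus series,
as a suitable dual-negative-feedback parameter set is not part of the
registered fixtures.
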