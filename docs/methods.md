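# Methods

## Model and assumptions

The package implements the reduction of a quasi-steady nutrient-diffusion
model of a nonnecrotic spherical tumor to one scalar delay differential
equation in the cubed radius x = R³:

    dx/dt = s · [ 3 σ∞ f(x(t−τ)) − γ(t) x(t) ],
    f(x)  = x p(x^{1/3}),   p(u) = (u coth u − 1)/u²,
    γ(t)  = σ̃ + λ(t),      λ(t+ω) = λ(t) ≥ 0.

Assumptions inherited from the derivation: the nutrient field equilibrates
instantly relative to growth (so the radial profile is the closed form
σ∞ (R/sinh R)(sinh r/r) with the consumption coefficient rescaled to 1);
proliferation is proportional to the nutrient concentration a time τ ago
(the mitotic delay); natural and therapy-induced cell loss are volumetric
with rates σ̃ and λ(t).  The proliferation constant s multiplies the whole
field and is 1 after the conventional time rescaling; it is kept as an
explicit factor because the rescaling is a pure change of time unit — all
thresholds (which compare rates against σ∞ − σ̃) are independent of s, and
the integral-identity check is stated for s = 1 and refuses other values
rather than silently mis-scaling.

## Parameters

| parameter | meaning | units | default |
|---|---|---|---|
| σ∞ (`sigma_inf`) | external nutrient concentration | dimensionless, > 0 | required |
| σ̃ (`sigma_tilde`) | natural apoptosis rate | 1/time, ≥ 0 | 0 |
| τ (`tau`) | mitotic delay | time, ≥ 0 | 0 |
| s | proliferation time constant | 1/time | 1 |
| Γ (`gamma_diff`) | nutrient consumption coefficient | — | 1 (rescaled away) |
| λ(t), ω | therapy rate and its period | 1/time, time | schedule-specific |

Constructors accept any admissible values; the analysis routines branch on
the standing viability assumption σ∞ > σ̃ instead of enforcing it, because
the σ∞ < σ̃ case is itself a meaningful regime (extinction without
therapy).

## Numerical kernels

p suffers catastrophic cancellation near 0 (u coth u − 1 ~ u²/3).  Below
u = 0.2 it is evaluated by its Maclaurin series through the u¹⁰ term
(truncation < 10⁻¹⁵ there); above, directly via u/tanh(u).  The two
branches agree to ~10⁻¹⁴ relative in a band around the switch, and the
whole kernel is within 2.4·10⁻¹⁵ of 50-digit arithmetic on a log grid over
[10⁻⁸, 10³] (measured by the acceptance script).  For u ≥ 19, tanh(u) = 1
in double precision and the formula degrades gracefully to (u−1)/u²; p′
switches to its asymptotic −1/u² + 2/u³ there to keep sinh out of the
overflow range.  p(0) = 1/3 is defined by continuity rather than raising at
a removable singularity.  Note that in double precision p(u) rounds to
exactly 1/3 for u ≲ 3·10⁻⁸ (the deficit u²/45 falls below eps/3), so the
strict bound p < 1/3 saturates there.  The nutrient profile is computed as
σ∞ e^{r−R} q(r)/q(R) with q(t) = (1 − e^{−2t})/(2t) — an exact rewriting
that cannot overflow however large the radius.

## Integrator

Method of steps with the classical fixed-step RK4: on each segment
[kτ, (k+1)τ] the delayed state is a known function (the previous segment's
dense output, or the exact initial history), so the segment is an ordinary
non-autonomous ODE.  Node values and node derivatives define a cubic-Hermite
dense output, from which the next segment reads x(t−τ); since the Hermite
error is O(h⁴), the scheme stays 4th order end to end (observed order 4.05
under step halving).  Fixed steps rather than adaptive ones keep segment
boundaries — where derivative discontinuities inherited from t = 0 live —
exactly on the grid.  Default dt = τ/100; dt > τ/4 is reduced with a
warning record.

Pulsed (piecewise-constant) schedules go beyond the continuity assumed by
the underlying theory and are supported as an extension: step grids are
aligned to the schedule's breakpoints, stage rates and node derivatives are
evaluated one-sidedly from inside each step (an inward bias of 10⁻⁹·h,
exact at jumps and far below truncation error for smooth schedules), and
the dense output is assembled cell by cell from the two one-sided
derivatives so no interpolation cell ever spans a discontinuity.

Degenerate and guarded cases: τ = 0 collapses to a plain ODE handled by the
same stepper (cross-checked against scipy's adaptive RK at 10⁻⁸); a step
that lands in [−10⁻¹², 0) is clipped to 0, further below raises; a zero
history is exactly preserved (f(0) = 0).  The radius-form integrator is a
deliberate second route for cross-checking (R³ agrees with x to ~10⁻¹⁰
relative); it is singular at R = 0, so runs reaching R = 10⁻⁶ are truncated
with an extinction flag — the x form is authoritative near extinction.

Correctness is audited against the equivalent Volterra identity
x(t) = x(0)e^{−∫γ} + 3σ∞∫ e^{∫γ−∫γ} f(x(ξ−τ))dξ, evaluated by adaptive
quadrature on the dense output: the canonical constant-therapy run at
dt = 0.01 has residual ~2·10⁻¹¹ over 200 time units.  The quadrature is
seeded with the integrand's kink locations (multiples of τ and schedule
breakpoints) and truncated to the last 45/γ_min time units, where the
discarded tail is below 10⁻¹⁸ of scale.

## Equilibria and classification

p is strictly decreasing, so p(u) = c is solved by a doubling bracket plus
Brent's method (xtol 10⁻¹⁴); x_s = u³.  Stationarity residuals are ≤ 10⁻¹⁰
by construction.  The classifier returns one of four regimes with the
inequality certificate attached: extinct-untreated (σ∞ < σ̃), extinct
(λ_min ≥ σ∞ − σ̃), persistent-with-periodic-orbit (λ_max < σ∞ − σ̃), and
indeterminate (the genuine gap in the theory; a flag marks schedules with
λ̄ < σ∞ − σ̃, where the conjecture predicts an orbit).  Indeterminate is an
explicit outcome rather than a forced binary answer because the canonical
gap case (σ̃ = 3, λ = 1.5 + cos t) sits exactly there while simulation
still finds an orbit.

"Eventually trapped in the envelope [x₁/2, 3x₂/2]" is operationalized as:
the sampled range over the last 20% of a horizon t_end = max(50τ, 50ω)
lies inside the envelope, with the horizon doubled (at most twice) on
failure — the theory guarantees a trapping time T but does not quantify it.

## Periodic-orbit location

Two independent routes, agreeing to ~2·10⁻⁷ on the canonical persistent
preset (tolerated to 10⁻⁴, the grid-limited level):

1. **Integral operator.**  (A x)(t) = 3σ∞ ∫ₜ^{t+ω} G(t,s) f(x(s−τ)) ds with
   the periodic Green's kernel G, discretized on N = 1024 uniform nodes per
   period with composite Simpson.  The delayed lookup uses the periodic
   cubic-spline extension of the path — a cubic rather than linear
   interpolant because the O(Δ²) error of linear interpolation (~10⁻³ at
   this N on orbit scales of a few hundred) would dominate the cross-route
   agreement check, while the spline's O(Δ⁴) error does not.  G is
   evaluated as exp(∫ₜˢγ − ω(σ̃+λ̄))/(1−κ), whose exponent is ≤ 0 — stable
   for arbitrarily strong therapy (κ = e^{−ω(σ̃+λ̄)} can be ~10⁻¹³ and
   smaller).  Fixed points are sought by Picard iteration from the constant
   upper persistence state x₂; the existence theory (fixed-point index on
   the cone {x ≥ κ sup x}) is non-constructive, so non-convergence is
   reported as a failure object, never treated as refuting existence; an
   iteration that collapses below 10⁻⁸ reports extinction.

2. **Period map.**  Simulate 50 forcing periods (doubling to at most 400),
   then compare the last two periods in sup norm on the period grid;
   mismatch ≤ 10⁻⁶ yields the final period as the orbit, a vanished last
   period yields an extinction outcome.

The tolerance hierarchy — operator residual 10⁻¹⁰, period-map residual
10⁻⁶, cross-route 10⁻⁴ — reflects each route's dominant discretization
error (quadrature, integration, grid).  A located orbit fed back to the
integrator as its own initial history reproduces itself over five further
periods to ~10⁻⁸ (tolerated to 10⁻⁵).

## Scenario generator

`random_scenario` draws σ∞ ∈ [1,10], σ̃ ∈ [0,σ∞), a sinusoidal schedule
(mean ∈ [0.05,5], amplitude ≤ mean so the rate stays nonnegative, period
∈ [2,10], random phase), τ ∈ [0.1,2] and x₀ ∈ (0,100], rejection-sampling
the schedule until the requested regime's inequality holds; it is fully
determined by its seed.  These ranges bracket the canonical presets (all of
which use σ∞ = 5, τ = 1, ω = 2π) by roughly an order of magnitude in each
direction, which is the regime the reduction itself is plausible in.  The
generator emulates *model* diversity, not data: there is no measurement
noise, no parameter uncertainty, and no biological calibration — passing
tests show the advertised dynamical trichotomy holds across the parameter
box, not that any real tumor follows the model.

## Problem sizes

Defaults used by the test suite and the acceptance script: dt = 0.01 with
τ = 1 (100 steps per delay interval), horizons of 200 time units for
limit checks (≈32 forcing periods), N = 1024 period-grid nodes, 20 random
persistent scenarios for the confinement sweep, and a 160-point log grid
for the kernel audit.  These sizes put every numerical check two or more
orders of magnitude inside its tolerance; halving dt or doubling N moves
the measured residuals by the expected 4th-order factors and nothing else.

## Known limitations

- Figure-level reproduction is qualitative (limits, confinement, orbit
  existence); no trajectory-level reference values exist to compare
  against.
- Orbit *uniqueness* and existence under λ̄ < σ∞ − σ̃ are conjectures:
  probed by multi-history convergence (pairwise ≤ 10⁻⁴, observed ~10⁻⁸),
  never asserted as invariants.
- Schedules that touch zero (λ_min = 0) fall outside the strict-positivity
  hypothesis of the existence theory; they are admitted and flagged
  (`strictly_positive`), and the orbit machinery empirically still works
  on them, but no guarantee is claimed.
- No local (characteristic-equation) stability analysis of x_s and no
  Floquet analysis of orbits: the underlying theory argues via comparison
  and fixed-point index, not spectra, and the package follows it.
- State-dependent delays, stiff/implicit stepping, and pharmacokinetic
  dose-to-λ(t) translation are out of scope.
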