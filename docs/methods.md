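# Methods

## Model

The package handles the scalar nonautonomous delay differential equation

    x'(t) = -α(t) x(t) + Σ_{i=1}^m β_i(t) x(t-τ_i(t)) e^{-γ_i(t) x(t-τ_i(t))},  t ≥ t0,

with continuous coefficients, α, β_i ≥ 0, γ_i > 0, and delays
0 ≤ τ_i(t) ≤ τ (τ = `tau_max`). Initial data are continuous histories
φ ≥ 0 on [t0-τ, t0] with φ(t0) > 0. For such data the solution is unique,
strictly positive, and global: the production term is nonnegative, so on
any interval where x > 0 the state is bounded below by a decaying
exponential and above by the variation-of-constants bound

    x(t) ≤ x(t0) + ∫_{t0}^{t} Σ_i β_i(s)/(e γ_i(s)) ds,                    (†)

using that u ↦ u e^{-g u} never exceeds 1/(e g). Positivity and global
existence hold with **no** lower bound on α — but boundedness does not:
when α(t) → 0, production can outrun mortality and positive solutions may
grow without bound (the shipped `eq9` model does exactly this).

## Convergence machinery

Write A(t) = ∫_{t0}^{t} α(s) ds for the cumulative mortality, and define

- **(A1)** m_α := sup_{t ≥ t0, i} ∫_{t-τ_i(t)}^{t} α(s) ds < ∞,
- **(A2)** A(t) → ∞,
- **(A3)** σ := limsup_{t→∞} (1/α(t)) Σ_i β_i(t) < 1.

### Ultimate bound δ

Since β_i x e^{-γ_i x} ≤ β_i/(e γ_i), the state obeys
x'(t) ≤ -α(t) (x(t) - q(t)) with q(t) = (1/α(t)) Σ_i β_i(t)/(e γ_i(t)).
Past any T with sup_{t≥T} q(t) =: δ finite, comparison gives

    x(t) ≤ δ + (x(T) - δ) e^{-(A(t)-A(T))},

so limsup x ≤ δ under (A2), and x(t) ≤ δ + |φ| e^{-A(t)} pointwise from t0
whenever the margin already holds at t0. `ultimate_bound` takes T as the
first probe time after which the (A3) ratio stays within 1e-3 of σ, and
computes δ = sup_{t≥T} q(t) on the probe grid with a local refinement of
the maximizer (`delta_formula` isolates the expression). Note the
pointwise bound, not δ alone, is what a trajectory with |φ| > δ satisfies
during its transient; tests check both the pointwise inequality and the
eventual bound on the trajectory tail.

### Decay rate λ* and envelope

Bounding the production term linearly (β_i x e^{-γ_i x} ≤ β_i x) and
passing to the weighted variable y(t) = x(t) e^{λ(A(t)-A(T*))}, the
delayed term picks up the factor e^{λ(A(t)-A(t-τ_i(t)))} ≤ e^{λ m_α} by
(A1). A maximum-principle argument then shows y can never cross its
history supremum provided

    H(λ) = λ - 1 + σ e^{λ m_α} < 0 at the crossing,

and the best certified rate is the unique positive root λ* of H(λ) = 0
(H(0) = σ-1 < 0, H' > 0, H → ∞). Using σ equal to the limsup itself is
admissible by a limiting argument λ ↑ λ*, so no artificial margin is
inserted into H. The envelope returned by `decay_rate` is

    x(t) ≤ M e^{-λ* A(t)},   M = (|φ| + ∫_{t0}^{T*} Σ_i β_i/(e γ_i) ds) e^{λ* A(T*)},

where T* is the onset of the (A3) margin (probe scan, tolerance 1e-3) and
the transient integral comes from (†). When the margin holds from t0 —
true for every shipped and generated model with a constant ratio — the
prefactor collapses to M = |φ|, making the bound tight at t = t0.

### Classical rate and its failure

For constant (or boundedly varying, with declared bounds α⁻ and β_i⁺)
coefficients, `constant_rate` solves

    η - α⁻ + (Σ_i β_i⁺) e^{η τ} = 0.

Dividing by α shows η = λ* α exactly in the constant case; the package
tests this consistency pointwise to 1e-9 relative. Conversely, when
A(t)/t → 0 (e.g. α ~ 1/(1+t), so A grows logarithmically) no constant
η > 0 can dominate the generalized envelope eventually;
`classical_rate_gap` probes r(t) = A(t)/(t-t0) on a log-spaced grid up to
t = 1e4 and reports that a classical rate exists only when r stays
bounded below (declared uniform positivity of α short-circuits the
probe).

## Numerical integration

- **Method of steps, RK4, uniform grid.** Default step
  h = min(0.01, max(min positive delay / 10, τ/100)); the floor matters
  because delays that sweep through zero must not drive h to zero — short
  delays are handled structurally, not by refinement.
- **Dense output** is cubic Hermite through (value, slope) pairs; the
  slope at a node is the right-hand side there, so no extra storage or
  stage retention is needed, and the interpolant matches RK4's one-step
  order. History queries below t0 evaluate φ directly.
- **Sub-step and vanishing delays** make the RK4 stages implicit. The
  step is computed by fixed-point sweeps over a provisional Hermite
  extension of the current cell (first guess: linear extension), repeated
  until the endpoint moves less than 1e-12 relative (at most 8 sweeps;
  delays longer than the step converge on the first sweep).
- **Statuses, not exceptions.** Crossing `blowup_threshold` (default
  1e12) truncates with `blowup_detected` — legitimate model behaviour.
  Dropping below `-positivity_tol` (default 0) yields `positivity_lost`,
  which only a solver failure can produce since exact solutions are
  positive.
- **Euler oracle.** A deliberately naive first-order integrator with
  linear-interpolation history, kept free of the Hermite and implicit
  machinery so it can serve as an independent cross-check; agreement at
  h = 1e-4 within 1e-2·(1 + max x) is asserted on random models.

## Quadrature and probes

A(t) is computed by adaptive quadrature (`scipy.integrate.quad`,
epsabs 1e-12) memoized on a sorted breakpoint list, so envelope
evaluation along a trajectory costs one incremental panel per grid point.
m_α is the grid supremum (601 points, locally polished) of
A(t) - A(t-τ_i(t)); a supremum attained at the probe end while still
climbing is reported as (A1) failing. Divergence of ∫α (A2) is probed by
comparing consecutive dyadic window integrals I₁ = A(H/2)-A(H/4) and
I₂ = A(H)-A(H/2): a tail α ~ t^{-p} gives I₂/I₁ = 2^{1-p}, so the probe
declares divergence when I₂ ≥ 0.95·I₁ — it cannot distinguish p slightly
above 1 from p = 1, which is exactly why declared metadata takes
precedence everywhere: limsup values and integral divergence are not
finitely decidable, the probes are best-effort and say so via
`source="numeric_probe"`, and a declaration/probe disagreement is
attached as a warning rather than silently resolved.

## Root solving

`solve_increasing_root` implements the contract the characteristic
equations satisfy (f(0⁺) < 0, strictly increasing, f → ∞): bracket by
doubling (≤ 60 times), bisect until both the bracket width and the
residual at the returned point are ≤ tol (1e-12 internally for λ* and η,
so the 1e-10 residual guarantee holds with slack), then verify uniqueness
by a 1000-point sign scan over the enclosing decade. An independent
multi-stage dense sign scan is used as the oracle in tests; the shipped
solver never calls it.

## Synthetic model family

`generate_synthetic_model` draws from the family α(t) = a/(1+t)^p,
β_i = c_i α, γ_i(t) = γ_min(1 + w_i sin² t), τ(t) = base + amp·sin t,
with a random positive piecewise-linear history (8 knots, values in
[0.2, 2]); all randomness flows through one seeded generator and output
is bit-reproducible. The family was chosen because its asymptotics are
known by construction and can be declared as metadata: the mortality
integral diverges iff p ≤ 1, α is never uniformly positive, and the
production/mortality ratio is constantly Σc_i — so Σc < 1 gives models
satisfying (A1)–(A3) with σ known exactly, and Σc ≥ 1 gives admissible
models where the convergence machinery must refuse to run. It emulates
the structural features the analysis cares about (fading mortality,
oscillating bounded delays, saturating production) and nothing else: real
populations have seasonality in β, demographic noise, and measurement
error, none of which are modelled, so passing tests certify the
*mathematics* of the envelope machinery, not fidelity to field data.

## Problem sizes

The default verification runs use: 200 synthetic models over
[t0, t0 + 50τ] at h = 0.01 for the positivity sweep; 20 models × 3
histories at horizon 30 for the envelope sweep; 5 models at horizon 5
for the RK4/Euler-oracle comparison (the oracle runs at h = 1e-4); 10
constant models for the classical/generalized consistency check; horizons
40 and 50 for the eq9 and eq21 pipelines. These sizes make the whole
suite run in well under a minute while leaving each property's failure
modes (positivity loss, envelope violation, order degradation) plenty of
room to manifest.

## Known limitations

- All asymptotic verdicts from numeric probes are finite-horizon
  heuristics; declarations exist precisely because the user may know the
  analytics. `classify_long_run`'s "unbounded_growth" label is explicit
  evidence, not proof.
- The envelope certifies decay toward the zero equilibrium only; positive
  equilibria, periodic solutions and oscillation theory are out of scope.
- Scalar state only; no diffusion, impulses, or stochastic forcing.
- `constant_rate` with declared bounds for time-varying coefficients uses
  the conservative uniform delay bound τ; per-term delay bounds would
  sharpen η but are not implemented.
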