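# nicholson-dde

Simulation and stability analysis for the **nonautonomous Nicholson
blowflies equation** — the scalar delay differential equation

```
x'(t) = -α(t) x(t) + Σᵢ βᵢ(t) x(t - τᵢ(t)) exp(-γᵢ(t) x(t - τᵢ(t))),   t ≥ t₀,
```

with `m ≥ 1` delayed Ricker-type production terms. `x(t)` is an adult
population, `α(t)` the per-capita mortality rate, `βᵢ(t)` egg-production
coefficients, `1/γᵢ(t)` the population scale at which recruitment
saturates, and `τᵢ(t)` bounded, time-varying maturation delays. Admissible
initial data are continuous nonnegative histories `φ` on `[t₀-τ, t₀]` with
`φ(t₀) > 0`, which yield a unique, strictly positive solution.

The package is aimed at the regime most classical stability theory
excludes: **mortality that is not uniformly positive** (for instance
`α(t) = 2/(2+t)`, which decays to zero). Three checkable assumptions
drive the analysis:

- **(A1)** the mortality integral over any delay window is bounded:
  `∫_{t-τᵢ(t)}^{t} α(s) ds ≤ m_α`;
- **(A2)** total mortality diverges: `∫^∞ α(s) ds = ∞`;
- **(A3)** production is asymptotically dominated by mortality:
  `σ := limsup_{t→∞} Σᵢ βᵢ(t)/α(t) < 1`.

Under (A1)–(A3) every positive solution obeys a **generalized exponential
envelope**

```
x(t) ≤ M · exp(-λ* · A(t)),        A(t) = ∫_{t₀}^{t} α(s) ds,
```

where the decay rate `λ*` is the unique positive root of the scalar
characteristic equation

```
H(λ) = λ - 1 + σ · e^{λ m_α} = 0.
```

When `A(t)` grows sublinearly (`A(t)/t → 0`) no classical bound
`M e^{-ηt}` with constant `η > 0` exists — the generalized envelope is then
the sharpest exponential statement available. When `α` is constant the
envelope reduces exactly to the classical rate `η = λ* α`.

## What the package does

| Layer | Contents |
|---|---|
| `nicholson.model` | model/history types, validation, shipped example models (`eq9`, `eq21`), restricted-expression config files, seeded synthetic-model generator |
| `nicholson.integrate` | method-of-steps RK4 with cubic-Hermite dense output, sub-step (vanishing) delay handling, blow-up/positivity statuses, brute-force Euler oracle |
| `nicholson.analysis` | cumulative mortality `A(t)`, (A1)–(A3) checks, ultimate bound `δ`, root solver, `λ*` and the envelope, classical constant rate `η` |
| `nicholson.verify` | envelope verification on simulated trajectories, long-run behaviour classification, classical-rate existence probe |
| `nicholson.cli` | `nicholson simulate / analyze / verify / reproduce` |

Two example models ship as config files:

- **eq9** — `α(t) = γ(t) = 1/(1+t)`, `β = 1`, `τ = 1`: mortality and
  saturation both fade; positive solutions exist globally but grow without
  bound.
- **eq21** — two delays `0.5(1+sin t)`, `0.5(1+cos t)` that repeatedly
  touch zero, `α(t) = 2/(2+t)`, constant production/mortality ratio `1/2`:
  (A1)–(A3) hold, solutions converge to zero inside the generalized
  envelope, and no classical rate exists.

## Worked example

```
$ nicholson analyze --fixture eq21 --out out
lambda_star = 0.271500220433; wrote out/analysis.json
```

`out/analysis.json` reports `m_alpha = 1.3862943611` (= 2 ln 2, the
delay-window mortality integral at its worst, t = 0 with τ = 1),
`sigma = 0.5`, `delta = 0.1839397206` (= 1/(2e), the eventual absorbing
level), and `lambda_star = 0.2715002204`, the root of
`λ - 1 + 0.5·4^λ = 0`. The envelope is therefore

```
x(t) ≤ |φ| · (2/(2+t))^{2·0.2715} ,
```

an algebraic decay in `t` — exponential only in the stretched time `A(t)`.

```
$ nicholson simulate --fixture eq21 --horizon 20 --out out
status: completed; wrote out/trajectory.csv
$ nicholson verify --trajectory out/trajectory.csv --analysis out/analysis.json \
      --fixture eq21 --out out
holds=True max_ratio=1
```

`max_ratio` is the supremum of `x(t)/envelope(t)` over the simulated
grid; 1 means the bound is tight exactly at `t₀` (where `x = |φ|`) and
respected everywhere after. The two shipped examples run end to end with

```
$ nicholson reproduce fig1 --out out    # eq9:  classification = unbounded_growth
$ nicholson reproduce fig2 --out out    # eq21: envelope holds=True,
                                        #       classical_rate_exists=False
```

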