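"""Model data types for the nonautonomous Nicholson blowflies equation.

The scalar delay differential equation handled throughout this package is

    x'(t) = -alpha(t) x(t)
            + sum_i beta_i(t) x(t - tau_i(t)) exp(-gamma_i(t) x(t - tau_i(t)))

for t >= t0, with m >= 1 delayed Ricker-type production terms.  alpha is the
per-capita mortality rate (1/time), beta_i the egg production rate
coefficients, 1/gamma_i the population scale at which production saturates,
and tau_i(t) bounded time-varying maturation delays with
0 <= tau_i(t) <= tau_max.  Admissible initial data are continuous
nonnegative histories phi on [t0 - tau_max, t0] with phi(t0) > 0; such data
yield a unique positive solution.

Nothing here assumes alpha is uniformly positive: the whole point of the
analysis layer is that alpha(t) may decay to zero (e.g. like 1/(1+t)), in
which case solutions may converge to zero at a *generalized* exponential
rate governed by the running integral of alpha rather than by t itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .expressions import compile_expression

__all__ = [
    "ModelError",
    "AsymptoticMeta",
    "TimeFunction",
    "NicholsonModel",
    "InitialHistory",
    "Violation",
    "ValidationReport",
    "validate_model",
    "rhs",
    "make_paper_fixture",
    "available_fixtures",
    "load_model_config",
    "generate_synthetic_model",
]


class ModelError(ValueError):
    """Raised for structurally invalid model definitions."""


@dataclass
class AsymptoticMeta:
    """Declared asymptotic facts about a time function.

    Uniform positivity, divergence of the integral, and limsup values are
    not decidable from finitely many samples, so the user (or a fixture)
    may declare them.  Numeric probes report their own estimate and warn on
    disagreement, but never silently override a declaration.
    """

    is_uniformly_positive: bool | None = None
    positivity_bound: float | None = None
    integral_diverges: bool | None = None
    declared_limsup: float | None = None
    declared_liminf: float | None = None


class TimeFunction:
    """A scalar function of time with optional declared asymptotics."""

    def __init__(
        self,
        fn: Callable[[float], float],
        label: str = "f",
        meta: AsymptoticMeta | None = None,
    ):
        self._fn = fn
        self.label = label
        self.meta = meta or AsymptoticMeta()

    def __call__(self, t: float) -> float:
        return float(self._fn(t))

    @classmethod
    def from_expression(
        cls, expr: str, var: str = "t", label: str | None = None,
        meta: AsymptoticMeta | None = None,
    ) -> "TimeFunction":
        return cls(compile_expression(expr, var=var), label=label or expr, meta=meta)

    @classmethod
    def constant(cls, value: float, label: str | None = None) -> "TimeFunction":
        value = float(value)
        meta = AsymptoticMeta(
            is_uniformly_positive=value > 0,
            positivity_bound=value if value > 0 else None,
            integral_diverges=value > 0,
            declared_limsup=value,
            declared_liminf=value,
        )
        return cls(lambda t: value, label=label or f"{value}", meta=meta)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"TimeFunction({self.label!r})"


@dataclass(eq=False)
class NicholsonModel:
    """Full right-hand-side specification of the delayed blowflies equation.

    ``meta`` may carry model-level declarations used by the analysis layer:

    - ``ratio_limsup``: limsup as t -> infinity of sum(beta_i(t)) / alpha(t),
      the production/mortality ratio whose value below 1 drives convergence;
    - ``ratio_is_constant``: True when that ratio is constant in t;
    - ``m_alpha``: declared bound on the delay-window mortality integral
      sup_t int_{t - tau_i(t)}^{t} alpha(s) ds;
    - ``alpha_lower`` / ``alpha_upper`` / ``beta_upper``: constant bounds for
      the classical (constant-rate) corollary when coefficients vary.
    """

    alpha: TimeFunction
    betas: list[TimeFunction]
    gammas: list[TimeFunction]
    taus: list[TimeFunction]
    tau_max: float
    t0: float = 0.0
    label: str = "model"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.betas) == len(self.gammas) == len(self.taus)):
            raise ModelError("betas, gammas and taus must have equal length")
        if len(self.betas) < 1:
            raise ModelError("at least one delayed production term is required")
        if not (self.tau_max > 0):
            raise ModelError("tau_max must be positive")

    @property
    def m(self) -> int:
        """Number of delayed production terms."""
        return len(self.betas)


class InitialHistory:
    """Admissible initial datum: continuous phi >= 0 on [t0-tau_max, t0], phi(t0) > 0.

    The history is stored in absolute time, so ``phi(s)`` is queried with the
    same clock as the solution; this avoids sign errors when delays vary.
    """

    def __init__(
        self,
        t0: float,
        phi: Callable[[float], float],
        tau_max: float,
        label: str = "phi",
    ):
        self.t0 = float(t0)
        self.tau_max = float(tau_max)
        self._phi = phi
        self.label = label

    def __call__(self, s: float) -> float:
        lo = self.t0 - self.tau_max
        # tolerate round-off at the window edges
        if s < lo - 1e-12 or s > self.t0 + 1e-12:
            raise ModelError(
                f"history queried at {s} outside [{lo}, {self.t0}]"
            )
        return float(self._phi(min(max(s, lo), self.t0)))

    def sup_norm(self, n: int = 2001) -> float:
        """Supremum of phi over the history window, by dense sampling."""
        grid = np.linspace(self.t0 - self.tau_max, self.t0, n)
        return float(max(self(float(s)) for s in grid))

    @classmethod
    def from_expression(
        cls, expr: str, t0: float, tau_max: float, var: str = "s"
    ) -> "InitialHistory":
        return cls(t0, compile_expression(expr, var=var), tau_max, label=expr)


@dataclass
class Violation:
    condition: str
    time: float
    observed: float
    message: str


@dataclass
class ValidationReport:
    ok: bool
    violations: list[Violation]

    def first(self) -> Violation | None:
        return self.violations[0] if self.violations else None


def _finite(value: float) -> bool:
    return math.isfinite(value)


def validate_model(
    model: NicholsonModel,
    history: InitialHistory | None = None,
    probe_grid: Sequence[float] | None = None,
    horizon: float = 10.0,
    n_probe: int = 2001,
) -> ValidationReport:
    """Sampled check of the standing sign/boundedness assumptions.

    Continuity of user functions cannot be proven from code; all conditions
    are probed on a grid covering [t0 - tau_max, t0 + horizon] (default 2001
    points) with a finite-difference jump heuristic for the history.  Probes
    record at most one violation per condition per probe point; non-finite
    values become violations, not exceptions.
    """
    t0, tau = model.t0, model.tau_max
    if probe_grid is None:
        probe_grid = np.linspace(t0 - tau, t0 + horizon, n_probe)
    probe_grid = np.asarray(probe_grid, dtype=float)
    if probe_grid.size == 0:
        raise ModelError("probe grid must be nonempty")

    violations: list[Violation] = []

    def check_fn(fn: TimeFunction, name: str, t: float, lower: float | None,
                 strict: bool, upper: float | None = None) -> None:
        try:
            v = fn(t)
        except Exception as exc:  # evaluation failure is a violation
            violations.append(Violation(name, t, math.nan, f"{name}: {exc}"))
            return
        if not _finite(v):
            violations.append(Violation(name, t, v, f"{name} non-finite at t={t}"))
            return
        if lower is not None:
            if (strict and v <= lower) or (not strict and v < lower):
                op = ">" if strict else ">="
                violations.append(
                    Violation(name, t, v, f"{name} must be {op} {lower}")
                )
        if upper is not None and v > upper + 1e-12:
            violations.append(
                Violation(name, t, v, f"{name} must be <= {upper}")
            )

    # coefficients enter the right-hand side only at t >= t0 (delayed
    # arguments read the *state*, not the coefficients, below t0), so sign
    # and finiteness conditions are probed from t0 on
    for t in probe_grid:
        t = float(t)
        if t >= t0:
            check_fn(model.alpha, "alpha", t, 0.0, strict=False)
            for i in range(model.m):
                check_fn(model.betas[i], f"beta[{i}]", t, 0.0, strict=False)
                check_fn(model.gammas[i], f"gamma[{i}]", t, 0.0, strict=True)
                check_fn(model.taus[i], f"tau[{i}]", t, 0.0, strict=False,
                         upper=model.tau_max)

    if history is not None:
        if abs(history.t0 - t0) > 1e-12 or abs(history.tau_max - tau) > 1e-9:
            violations.append(
                Violation("history", t0, history.t0,
                          "history window does not match model (t0, tau_max)")
            )
        hist_grid = probe_grid[(probe_grid >= t0 - tau - 1e-12) & (probe_grid <= t0 + 1e-12)]
        if hist_grid.size < 2:
            hist_grid = np.linspace(t0 - tau, t0, 101)
        vals = []
        for s in hist_grid:
            try:
                v = history(float(s))
            except Exception as exc:
                violations.append(Violation("phi", float(s), math.nan, f"phi: {exc}"))
                v = math.nan
            vals.append(v)
            if _finite(v):
                if v < 0:
                    violations.append(
                        Violation("phi", float(s), v, "phi must be nonnegative")
                    )
            else:
                violations.append(
                    Violation("phi", float(s), v, f"phi non-finite at s={s}")
                )
        v0 = history(t0)
        if not (_finite(v0) and v0 > 0):
            violations.append(Violation("phi(t0)", t0, v0, "phi(t0) must be positive"))
        # jump heuristic: a single-step change comparable to the full range
        # of phi indicates a discontinuity at the probe resolution
        arr = np.asarray(vals)
        finite = arr[np.isfinite(arr)]
        if finite.size >= 2:
            scale = float(finite.max() - finite.min()) + 1e-12
            diffs = np.abs(np.diff(arr))
            bad = np.where(diffs > 0.25 * scale + 1e-9)[0]
            for k in bad[:3]:
                violations.append(
                    Violation("phi continuity", float(hist_grid[k]), float(diffs[k]),
                              "phi jump exceeds continuity heuristic")
                )

    # uniform positivity declarations are spot-checked
    for fn, name in [(model.alpha, "alpha")] + [
        (model.betas[i], f"beta[{i}]") for i in range(model.m)
    ]:
        if fn.meta.is_uniformly_positive and fn.meta.positivity_bound is not None:
            bound = fn.meta.positivity_bound
            for t in probe_grid[probe_grid >= t0]:
                v = fn(float(t))
                if v < bound - 1e-12:
                    violations.append(
                        Violation(f"{name} positivity declaration", float(t), v,
                                  f"declared uniform lower bound {bound} violated")
                    )
                    break

    return ValidationReport(ok=not violations, violations=violations)


def rhs(model: NicholsonModel, t: float, x_now: float,
        x_delayed: Sequence[float]) -> float:
    """Right-hand side -alpha x + sum beta_i x_d_i exp(-gamma_i x_d_i).

    ``x_delayed[i]`` must be the solution value at ``t - tau_i(t)``.
    Raises on a non-finite coefficient, naming it; the zero state is an
    exact equilibrium (rhs(t, 0, [0]*m) == 0 identically).
    """
    a = model.alpha(t)
    if not _finite(a):
        raise ModelError(f"alpha non-finite at t={t}")
    total = -a * x_now
    for i in range(model.m):
        b = model.betas[i](t)
        g = model.gammas[i](t)
        if not _finite(b):
            raise ModelError(f"beta[{i}] non-finite at t={t}")
        if not _finite(g):
            raise ModelError(f"gamma[{i}] non-finite at t={t}")
        xd = x_delayed[i]
        total += b * xd * math.exp(-g * xd)
    return total


# ---------------------------------------------------------------------------
# config files and shipped fixtures
# ---------------------------------------------------------------------------

def _meta_from_dict(d: dict) -> AsymptoticMeta:
    return AsymptoticMeta(
        is_uniformly_positive=d.get("is_uniformly_positive"),
        positivity_bound=d.get("positivity_bound"),
        integral_diverges=d.get("integral_diverges"),
        declared_limsup=d.get("declared_limsup"),
        declared_liminf=d.get("declared_liminf"),
    )


def load_model_config(source) -> tuple[NicholsonModel, InitialHistory]:
    """Build a model and history from a TOML file path or a parsed dict.

    Expected keys: ``t0``, ``tau_max``, ``alpha`` (expression in t),
    ``beta``/``gamma``/``tau`` (lists of expressions in t), ``phi``
    (expression in s on [t0-tau_max, t0]), optional ``label`` and ``meta``
    table (with optional per-coefficient sub-tables ``meta.alpha`` etc.).
    """
    if isinstance(source, dict):
        cfg = source
    else:
        import tomllib

        with open(source, "rb") as fh:
            cfg = tomllib.load(fh)

    try:
        t0 = float(cfg.get("t0", 0.0))
        tau_max = float(cfg["tau_max"])
        meta_block = dict(cfg.get("meta", {}))
        alpha_meta = _meta_from_dict(meta_block.pop("alpha", {}))
        alpha = TimeFunction.from_expression(cfg["alpha"], "t", meta=alpha_meta)
        betas = [TimeFunction.from_expression(e, "t") for e in cfg["beta"]]
        gammas = [TimeFunction.from_expression(e, "t") for e in cfg["gamma"]]
        taus = [TimeFunction.from_expression(e, "t") for e in cfg["tau"]]
        phi_expr = cfg["phi"]
    except KeyError as exc:
        raise ModelError(f"model config missing key {exc}") from None

    if "m" in cfg and int(cfg["m"]) != len(betas):
        raise ModelError("declared m does not match the number of beta terms")

    model = NicholsonModel(
        alpha=alpha, betas=betas, gammas=gammas, taus=taus,
        tau_max=tau_max, t0=t0, label=str(cfg.get("label", "model")),
        meta=meta_block,
    )
    history = InitialHistory.from_expression(phi_expr, t0=t0, tau_max=tau_max)
    return model, history


_FIXTURES = ("eq9", "eq21")


def available_fixtures() -> tuple[str, ...]:
    return _FIXTURES


def make_paper_fixture(name: str) -> tuple[NicholsonModel, InitialHistory]:
    """Load one of the shipped example models.

    ``"eq9"`` — a single-delay model whose mortality and saturation
    coefficients decay to zero; positive solutions exist globally but grow
    without bound, illustrating that dropping uniform positivity of alpha
    also forfeits boundedness.

    ``"eq21"`` — a two-delay model with time-varying (occasionally
    vanishing) delays whose production/mortality ratio is constantly 1/2;
    the convergence assumptions hold and every positive solution obeys the
    generalized envelope, while no classical exponential rate exists.
    """
    if name not in _FIXTURES:
        raise ModelError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(_FIXTURES)}"
        )
    from importlib import resources

    path = resources.files("nicholson") / "fixtures" / f"{name}.toml"
    with resources.as_file(path) as p:
        return load_model_config(p)


# ---------------------------------------------------------------------------
# synthetic model family
# ---------------------------------------------------------------------------

def generate_synthetic_model(
    p: float = 1.0,
    c: Sequence[float] = (0.5,),
    gamma_min: float = 1.0,
    delay_base: float = 0.5,
    delay_amp: float = 0.3,
    a: float = 1.0,
    seed: int = 0,
) -> tuple[NicholsonModel, InitialHistory]:
    """Seeded generator for the test family alpha(t) = a/(1+t)^p, beta_i = c_i alpha.

    The family is built so its asymptotics are known by construction and can
    be declared as metadata: for 0 < p <= 1 the mortality integral diverges
    while alpha itself decays to zero (not uniformly positive), and the
    production/mortality ratio is constantly sum(c).  Delays are
    tau(t) = delay_base + delay_amp*sin(t), bounded away from the pole of
    alpha at t = -1; gamma_i(t) >= gamma_min.  The initial history is a
    random positive piecewise-linear function; identical seeds give
    bit-identical models and histories.
    """
    if not (0 < p <= 1):
        raise ModelError("p must lie in (0, 1]")
    c = [float(ci) for ci in c]
    if not c or any(ci < 0 for ci in c):
        raise ModelError("c must be a nonempty list of nonnegative reals")
    if not (gamma_min > 0):
        raise ModelError("gamma_min must be positive")
    if not (0 <= abs(delay_amp) < delay_base):
        raise ModelError("need |delay_amp| < delay_base")
    tau_max = delay_base + abs(delay_amp)
    if tau_max >= 1.0:
        raise ModelError("delay_base + |delay_amp| must be < 1 for this family")
    if not (a > 0):
        raise ModelError("a must be positive")

    rng = np.random.default_rng(seed)

    def alpha_fn(t: float, _a=a, _p=p) -> float:
        return _a / (1.0 + t) ** _p

    alpha = TimeFunction(
        alpha_fn,
        label=f"{a}/(1+t)^{p}",
        meta=AsymptoticMeta(
            is_uniformly_positive=False,
            integral_diverges=bool(p <= 1),
            declared_limsup=0.0,
            declared_liminf=0.0,
        ),
    )
    betas, gammas, taus = [], [], []
    for i, ci in enumerate(c):
        betas.append(TimeFunction(
            lambda t, _c=ci, _a=a, _p=p: _c * _a / (1.0 + t) ** _p,
            label=f"{ci}*alpha",
        ))
        wobble = float(rng.uniform(0.0, 1.0))
        gammas.append(TimeFunction(
            lambda t, _g=gamma_min, _w=wobble: _g * (1.0 + _w * math.sin(t) ** 2),
            label=f"gamma[{i}]>= {gamma_min}",
        ))
        taus.append(TimeFunction(
            lambda t, _b=delay_base, _amp=delay_amp: _b + _amp * math.sin(t),
            label=f"{delay_base}+{delay_amp}*sin(t)",
        ))

    model = NicholsonModel(
        alpha=alpha, betas=betas, gammas=gammas, taus=taus,
        tau_max=tau_max, t0=0.0,
        label=f"synthetic(p={p}, c={c}, seed={seed})",
        meta={
            "ratio_limsup": float(sum(c)),
            "ratio_is_constant": True,
        },
    )

    # random positive piecewise-linear history on [-tau_max, 0]
    n_knots = 8
    knots = np.linspace(-tau_max, 0.0, n_knots)
    vals = rng.uniform(0.2, 2.0, size=n_knots)

    def phi(s: float, _k=knots, _v=vals) -> float:
        return float(np.interp(s, _k, _v))

    history = InitialHistory(0.0, phi, tau_max, label=f"piecewise-linear(seed={seed})")
    return model, history
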