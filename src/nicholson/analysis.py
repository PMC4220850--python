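"""Asymptotic analysis: assumptions, ultimate bound, and the decay rate.

For the nonautonomous blowflies equation the convergence machinery rests on
three assumptions about the per-capita mortality rate alpha and the
production coefficients beta_i:

(A1)  the mortality integral over any delay window is bounded: there is
      m_alpha > 0 with  int_{t - tau_i(t)}^{t} alpha(s) ds <= m_alpha;
(A2)  the total mortality diverges:  int_{t0}^{infinity} alpha(s) ds = oo;
(A3)  production is asymptotically dominated by mortality:
      sigma := limsup_{t->oo} (1/alpha(t)) sum_i beta_i(t) < 1.

Under (A1)-(A3) every positive solution obeys a *generalized* exponential
envelope

      x(t) <= M exp(-lambda_star * A(t)),    A(t) = int_{t0}^{t} alpha(s) ds,

where lambda_star is the unique positive root of the scalar equation

      H(lambda) = lambda - 1 + sigma * exp(lambda * m_alpha) = 0.

H(0) = sigma - 1 < 0, H is strictly increasing and H -> oo, so the root
exists and is unique.  When alpha is constant the exponent reduces to the
classical constant rate eta = lambda_star * alpha; when A(t) grows
sublinearly (e.g. alpha ~ 1/(1+t)) no classical rate exists at all, which
is exactly the regime this analysis is for.

Asymptotic facts (limsup values, integral divergence) are not decidable
from finite samples, so every check resolves in two stages: declared
metadata wins when present; otherwise a numeric probe over a finite horizon
supplies a best-effort answer and the report records that its source was a
probe.  Probe and declaration are compared and disagreement is surfaced as
a warning, never silently resolved.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .model import ModelError, NicholsonModel

__all__ = [
    "AnalysisError",
    "AssumptionError",
    "RootFindError",
    "CumulativeAlpha",
    "cumulative_alpha",
    "AssumptionReport",
    "check_assumptions",
    "UltimateBound",
    "delta_formula",
    "ultimate_bound",
    "transient_envelope",
    "solve_increasing_root",
    "DecayEstimate",
    "prefactor_formula",
    "decay_rate",
    "constant_rate",
]


class AnalysisError(ValueError):
    pass


class AssumptionError(AnalysisError):
    """A required assumption is not established."""


class RootFindError(AnalysisError):
    pass


# ---------------------------------------------------------------------------
# cumulative mortality A(t)
# ---------------------------------------------------------------------------

class CumulativeAlpha:
    """Memoized running integral A(t) = int_{t0}^{t} alpha(s) ds.

    Evaluations are cached on a sorted breakpoint list, so walking along an
    increasing trajectory grid costs one small adaptive-quadrature panel per
    step.  t below t0 (down to t0 - tau_max) yields negative values, which
    the delay-window integrals of (A1) rely on.
    """

    def __init__(self, model: NicholsonModel, epsabs: float = 1e-12):
        self.model = model
        self.epsabs = epsabs
        self._ts = [model.t0]
        self._as = [0.0]

    def __call__(self, t: float) -> float:
        t = float(t)
        lo = self.model.t0 - self.model.tau_max
        if t < lo - 1e-9:
            raise AnalysisError(f"A(t) requested at t={t} below {lo}")
        i = bisect_left(self._ts, t)
        if i < len(self._ts) and abs(self._ts[i] - t) <= 1e-14 * (1 + abs(t)):
            return self._as[i]
        # integrate from the nearest cached breakpoint
        if i == 0:
            base_t, base_a = self._ts[0], self._as[0]
        elif i == len(self._ts):
            base_t, base_a = self._ts[-1], self._as[-1]
        else:
            if abs(self._ts[i] - t) < abs(t - self._ts[i - 1]):
                base_t, base_a = self._ts[i], self._as[i]
            else:
                base_t, base_a = self._ts[i - 1], self._as[i - 1]
        val, err = quad(self.model.alpha, base_t, t,
                        epsabs=self.epsabs, epsrel=1e-10, limit=200)
        if err > max(1e-7, 1e-6 * abs(val)):
            raise AnalysisError(
                f"quadrature did not converge on [{base_t}, {t}] (err={err:g})"
            )
        a = base_a + val
        j = bisect_left(self._ts, t)
        self._ts.insert(j, t)
        self._as.insert(j, a)
        return a


_CUM_CACHE: dict[int, tuple[NicholsonModel, CumulativeAlpha]] = {}


def cumulative_alpha(model: NicholsonModel, t: float) -> float:
    """A(t) for this model, with a per-model memoized breakpoint cache."""
    entry = _CUM_CACHE.get(id(model))
    if entry is None or entry[0] is not model:
        entry = (model, CumulativeAlpha(model))
        _CUM_CACHE[id(model)] = entry
    return entry[1](t)


# ---------------------------------------------------------------------------
# assumption report
# ---------------------------------------------------------------------------

@dataclass
class A1Result:
    holds: bool | None
    m_alpha: float | None


@dataclass
class A2Result:
    holds: bool | None


@dataclass
class A3Result:
    holds: bool | None
    limsup_value: float | None


@dataclass
class AssumptionReport:
    a1: A1Result
    a2: A2Result
    a3: A3Result
    source: str                      # "declared" | "numeric_probe" | "mixed"
    probe_horizon: float
    warnings: list[str] = field(default_factory=list)

    @property
    def all_hold(self) -> bool:
        return bool(self.a1.holds and self.a2.holds and self.a3.holds)


def _delay_window_integral(model: NicholsonModel, A: CumulativeAlpha,
                           i: int, t: float) -> float:
    """int_{t - tau_i(t)}^{t} alpha(s) ds; +inf when the window integral
    diverges (e.g. alpha singular at the history edge)."""
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            v = A(t) - A(t - model.taus[i](t))
    except (AnalysisError, ZeroDivisionError, OverflowError):
        return math.inf
    return v if math.isfinite(v) else math.inf


def _probe_m_alpha(model: NicholsonModel, A: CumulativeAlpha,
                   horizon: float, n: int = 601) -> tuple[float | None, float]:
    """Numeric sup of the delay-window mortality integral, polished locally.

    Returns (m_alpha or None if the sup looks unbounded, argmax time).
    """
    t0 = model.t0
    grid = np.linspace(t0, t0 + horizon, n)
    best_v, best_t = -math.inf, t0
    half_max = -math.inf
    for i in range(model.m):
        vals = np.array([_delay_window_integral(model, A, i, float(t)) for t in grid])
        if not np.all(np.isfinite(vals)):
            return None, float(grid[int(np.argmax(~np.isfinite(vals)))])
        k = int(np.argmax(vals))
        if vals[k] > best_v:
            best_v, best_t = float(vals[k]), float(grid[k])
        half_max = max(half_max, float(vals[: n // 2].max()))
        # growth screen: sup attained at the far end and still climbing
        if k >= n - 2 and vals[-1] > 1.05 * max(vals[: n // 2].max(), 1e-12):
            return None, float(grid[k])
    # polish the grid maximum
    spacing = horizon / (n - 1)
    for i in range(model.m):
        res = minimize_scalar(
            lambda t: -_delay_window_integral(model, A, i, t),
            bounds=(max(t0, best_t - spacing), min(t0 + horizon, best_t + spacing)),
            method="bounded", options={"xatol": 1e-10},
        )
        best_v = max(best_v, float(-res.fun))
    return best_v, best_t


def _probe_a2(model: NicholsonModel, A: CumulativeAlpha, horizon: float) -> bool:
    """Dyadic-window divergence heuristic.

    For a tail alpha ~ t^-p the window integrals over [H/4, H/2] and
    [H/2, H] scale by 2^(1-p), so a ratio >= 0.95 indicates p <= 1 (the
    divergent regime) at the resolution a finite probe can offer.
    """
    t0 = model.t0
    i1 = A(t0 + horizon / 2) - A(t0 + horizon / 4)
    i2 = A(t0 + horizon) - A(t0 + horizon / 2)
    if i2 <= 1e-10:
        return False
    return i2 >= 0.95 * i1


def _ratio(model: NicholsonModel, t: float) -> float:
    a = model.alpha(t)
    s = sum(b(t) for b in model.betas)
    if a <= 0:
        return math.inf if s > 0 else 0.0
    return s / a


def _probe_a3(model: NicholsonModel, horizon: float, n: int = 801) -> float:
    t0 = model.t0
    grid = np.linspace(t0 + horizon / 2, t0 + horizon, n)
    return float(max(_ratio(model, float(t)) for t in grid))


def check_assumptions(model: NicholsonModel, probe_horizon: float = 60.0
                      ) -> AssumptionReport:
    """Evaluate (A1)-(A3), preferring declared metadata over numeric probes."""
    if not (probe_horizon > 0):
        raise AnalysisError("probe_horizon must be positive")
    A = CumulativeAlpha(model)
    warnings: list[str] = []
    sources: list[str] = []

    # (A1)
    declared_m = model.meta.get("m_alpha")
    probe_m, _ = _probe_m_alpha(model, A, probe_horizon)
    if declared_m is not None:
        a1 = A1Result(holds=True, m_alpha=float(declared_m))
        sources.append("declared")
        if probe_m is not None and probe_m > float(declared_m) * (1 + 1e-6):
            warnings.append(
                f"A1 probe found window integral {probe_m:.6g} above the "
                f"declared m_alpha {declared_m:.6g}"
            )
    elif probe_m is None:
        a1 = A1Result(holds=False, m_alpha=None)
        sources.append("numeric_probe")
    else:
        a1 = A1Result(holds=True, m_alpha=probe_m)
        sources.append("numeric_probe")

    # (A2)
    declared_div = model.alpha.meta.integral_diverges
    probe_div = _probe_a2(model, A, probe_horizon)
    if declared_div is not None:
        a2 = A2Result(holds=bool(declared_div))
        sources.append("declared")
        if probe_div != bool(declared_div):
            warnings.append(
                f"A2 probe suggests integral_diverges={probe_div}, "
                f"declaration says {declared_div}"
            )
    else:
        a2 = A2Result(holds=probe_div)
        sources.append("numeric_probe")

    # (A3)
    declared_ratio = model.meta.get("ratio_limsup")
    if declared_ratio is not None:
        val = float(declared_ratio)
        a3 = A3Result(holds=val < 1.0, limsup_value=val)
        sources.append("declared")
        probe_val = _probe_a3(model, probe_horizon)
        if probe_val > val * (1 + 1e-6) + 1e-9:
            warnings.append(
                f"A3 probe found ratio {probe_val:.6g} above declared "
                f"limsup {val:.6g}"
            )
    else:
        val = _probe_a3(model, probe_horizon)
        a3 = A3Result(holds=val < 1.0, limsup_value=val)
        sources.append("numeric_probe")

    source = ("declared" if all(s == "declared" for s in sources)
              else "numeric_probe" if all(s == "numeric_probe" for s in sources)
              else "mixed")
    return AssumptionReport(a1=a1, a2=a2, a3=a3, source=source,
                            probe_horizon=probe_horizon, warnings=warnings)


# ---------------------------------------------------------------------------
# ultimate bound (eventual absorbing level)
# ---------------------------------------------------------------------------

@dataclass
class UltimateBound:
    delta: float
    onset_time: float                # first time the (A3) margin holds for good
    sigma: float


def delta_formula(sup_weighted_ratio: float) -> float:
    """delta = sup_{t >= T} (1/alpha(t)) sum_i beta_i(t) / (e * gamma_i(t)).

    The production term u -> beta u e^{-gamma u} never exceeds
    beta/(e*gamma), so x' <= -alpha(t) (x - q(t)) with q the weighted ratio
    above; past T any solution decays toward the level sup q, giving
    limsup x <= delta (and x(t) <= delta + |phi| e^{-A(t)} when the margin
    holds from t0).
    """
    return sup_weighted_ratio


def _margin_onset(model: NicholsonModel, sigma: float, horizon: float,
                  n: int = 1025, margin: float = 1e-3) -> float:
    """First probe time after which the ratio stays <= sigma + margin."""
    t0 = model.t0
    grid = np.linspace(t0, t0 + horizon, n)
    vals = np.array([_ratio(model, float(t)) for t in grid])
    ok = vals <= sigma + margin
    # suffix scan: onset is the first index from which all later probes hold
    idx = None
    good = True
    for k in range(n - 1, -1, -1):
        good = good and bool(ok[k])
        if good:
            idx = k
    if idx is None:
        raise AnalysisError(
            "the (A3) margin inequality never holds on the probe horizon"
        )
    return float(grid[idx])


def _weighted_ratio(model: NicholsonModel, t: float) -> float:
    a = model.alpha(t)
    s = sum(b(t) / g(t) for b, g in zip(model.betas, model.gammas))
    if a <= 0:
        return math.inf if s > 0 else 0.0
    return s / (math.e * a)


def ultimate_bound(model: NicholsonModel, report: AssumptionReport,
                   probe_horizon: float = 60.0, n: int = 1025) -> UltimateBound:
    """Eventual absorbing level delta for all positive solutions."""
    if report.a3.holds is not True:
        raise AssumptionError("A3 required for the ultimate bound")
    sigma = float(report.a3.limsup_value)
    T = _margin_onset(model, sigma, probe_horizon, n)
    t0 = model.t0
    grid = np.linspace(T, t0 + probe_horizon, n)
    vals = np.array([_weighted_ratio(model, float(t)) for t in grid])
    k = int(np.argmax(vals))
    best = float(vals[k])
    spacing = (grid[-1] - grid[0]) / (n - 1)
    res = minimize_scalar(
        lambda t: -_weighted_ratio(model, t),
        bounds=(max(T, grid[k] - spacing), min(grid[-1], grid[k] + spacing)),
        method="bounded", options={"xatol": 1e-10},
    )
    best = max(best, float(-res.fun))
    if not math.isfinite(best):
        raise AnalysisError("weighted production/mortality ratio is unbounded")
    return UltimateBound(delta=delta_formula(best), onset_time=T, sigma=sigma)


def transient_envelope(model: NicholsonModel, bound: UltimateBound,
                       history_norm: float) -> Callable[[float], float]:
    """Pointwise bound delta + |phi| e^{-(A(t)-A(T))}, valid for t >= T."""
    A = CumulativeAlpha(model)
    AT = A(bound.onset_time)

    def env(t: float) -> float:
        return bound.delta + history_norm * math.exp(-(A(t) - AT))

    return env


# ---------------------------------------------------------------------------
# scalar root solving
# ---------------------------------------------------------------------------

def solve_increasing_root(f: Callable[[float], float],
                          bracket_hint: float = 1.0,
                          tol: float = 1e-10) -> float:
    """Unique positive root of a continuous strictly increasing f.

    Requires f(0+) < 0 and f -> +oo (caller-asserted; spot-checked).  The
    bracket is found by doubling from ``bracket_hint`` and refined by
    bisection until both |f| <= tol and the bracket width <= tol;
    uniqueness is then verified by a 1000-point sign scan over the decade
    containing the root.
    """
    if not (bracket_hint > 0):
        raise RootFindError("bracket_hint must be positive")
    eps = 1e-12
    f_eps = f(eps)
    if f_eps >= 0:
        raise RootFindError("no positive root: f(0+) >= 0")
    hi = bracket_hint
    doublings = 0
    while f(hi) < 0:
        hi *= 2.0
        doublings += 1
        if doublings > 60:
            raise RootFindError("no positive root found after 60 doublings")
    lo = eps if doublings == 0 else hi / 2.0
    flo = f(lo)
    if flo > 0:
        lo = eps
    root = 0.5 * (lo + hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm < 0:
            lo = mid
        else:
            hi = mid
        if (hi - lo) <= tol and abs(fm) <= tol:
            root = mid          # the point whose residual was verified
            break
    # uniqueness: exactly one sign change across the enclosing decade
    decade_lo = 10.0 ** math.floor(math.log10(root))
    decade_hi = 10.0 * decade_lo
    scan = np.linspace(decade_lo, decade_hi, 1000)
    signs = np.sign([f(float(s)) for s in scan])
    changes = int(np.sum(np.abs(np.diff(np.where(signs == 0, 1, signs))) > 1))
    if changes > 1:
        raise RootFindError("multiple sign changes: function is not monotone")
    return root


# ---------------------------------------------------------------------------
# decay rate and envelope
# ---------------------------------------------------------------------------

@dataclass
class DecayEstimate:
    """lambda_star, prefactor M, onset T*, and the envelope M e^{-lambda* A(t)}."""

    lambda_star: float
    prefactor: float
    onset_time: float
    sigma: float
    m_alpha: float
    residual: float
    cumulative: CumulativeAlpha

    def envelope(self, t: float) -> float:
        return self.prefactor * math.exp(-self.lambda_star * self.cumulative(t))

    def characteristic(self, lam: float) -> float:
        return lam - 1.0 + self.sigma * math.exp(lam * self.m_alpha)


def prefactor_formula(history_norm: float, transient_integral: float,
                      lambda_star: float, a_at_onset: float) -> float:
    """M = (|phi| + int_{t0}^{T*} sum_i beta_i/(e gamma_i) ds) e^{lambda* A(T*)}.

    The integral bounds the transient growth on [t0, T*] via the integral
    representation of the solution; the exponential factor lifts the
    envelope so that it dominates that transient before the decay argument
    takes over at T*.  When the margin inequality holds from t0 the onset
    is t0 and M collapses to the history supremum |phi|.
    """
    return (history_norm + transient_integral) * math.exp(lambda_star * a_at_onset)


def decay_rate(model: NicholsonModel, report: AssumptionReport,
               history_norm: float, probe_horizon: float = 60.0) -> DecayEstimate:
    """Generalized exponential decay estimate for all positive solutions."""
    if not report.all_hold:
        missing = [name for name, r in
                   (("A1", report.a1), ("A2", report.a2), ("A3", report.a3))
                   if r.holds is not True]
        raise AssumptionError(f"assumptions not established: {', '.join(missing)}")
    if not (history_norm > 0):
        raise AnalysisError("history_norm must be positive")
    sigma = float(report.a3.limsup_value)
    m_alpha = float(report.a1.m_alpha)
    t_star = _margin_onset(model, sigma, probe_horizon)

    def H(lam: float) -> float:
        return lam - 1.0 + sigma * math.exp(lam * m_alpha)

    lambda_star = solve_increasing_root(H, bracket_hint=0.5, tol=1e-12)
    residual = abs(H(lambda_star))
    if residual > 1e-10:
        raise RootFindError(f"characteristic residual {residual:g} above 1e-10")

    A = CumulativeAlpha(model)
    a_onset = A(t_star)
    if t_star > model.t0 + 1e-12:
        val, _ = quad(
            lambda s: sum(b(s) / (math.e * g(s))
                          for b, g in zip(model.betas, model.gammas)),
            model.t0, t_star, epsabs=1e-12, epsrel=1e-10, limit=200,
        )
        transient = float(val)
    else:
        transient = 0.0
    M = prefactor_formula(history_norm, transient, lambda_star, a_onset)
    return DecayEstimate(
        lambda_star=lambda_star, prefactor=M, onset_time=t_star,
        sigma=sigma, m_alpha=m_alpha, residual=residual, cumulative=A,
    )


def constant_rate(model: NicholsonModel, probe_horizon: float = 10.0) -> float:
    """Classical exponential rate eta for (effectively) constant coefficients.

    eta is the unique positive root of

        eta - alpha_lower + (sum_i beta_i_upper) e^{eta tau_max} = 0,

    the constant-coefficient specialization of the generalized equation
    (divide H by alpha: with sigma = sum beta/alpha and
    m_alpha = alpha tau_max, eta = lambda_star * alpha exactly).  For
    time-varying coefficients the caller must declare constant bounds
    ``alpha_lower`` and ``beta_upper`` in ``model.meta``.
    """
    grid = np.linspace(model.t0, model.t0 + probe_horizon, 17)

    def const_val(fn) -> float | None:
        vals = [fn(float(t)) for t in grid]
        mean = sum(vals) / len(vals)
        if max(vals) - min(vals) <= 1e-9 * (1 + abs(mean)):
            return float(mean)
        return None

    alpha_lower = const_val(model.alpha)
    beta_uppers = [const_val(b) for b in model.betas]
    if alpha_lower is None or any(b is None for b in beta_uppers):
        alpha_lower = model.meta.get("alpha_lower")
        beta_meta = model.meta.get("beta_upper")
        if alpha_lower is None or beta_meta is None:
            raise AnalysisError(
                "constant_rate needs constant coefficients or declared "
                "alpha_lower/beta_upper bounds in model.meta"
            )
        beta_uppers = [float(b) for b in beta_meta]
    beta_sum = float(sum(beta_uppers))
    tau = model.tau_max

    def f(eta: float) -> float:
        return eta - float(alpha_lower) + beta_sum * math.exp(eta * tau)

    return solve_increasing_root(f, bracket_hint=0.5 * float(alpha_lower) or 0.5,
                                 tol=1e-12)
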