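"""Method-of-steps integration of the delayed blowflies equation.

The solver advances on a uniform grid with classical RK4 and reads delayed
states from a piecewise cubic Hermite interpolant built from stored
(value, slope) pairs — the slope at each node is the right-hand side there,
so the dense output matches the one-step order without storing stage
values.  Delayed arguments falling inside the initial history window are
evaluated from phi directly.

When a delay is shorter than the current step (including tau_i(t) = 0) the
stage equations become implicit; they are resolved by fixed-point sweeps
over the provisional Hermite extension of the current cell (typically two
sweeps; convergence tolerance 1e-12) rather than by shrinking the step, so
the grid stays uniform and runs are deterministic.

Blow-up is a *status*, not an exception: with vanishing mortality the model
legitimately produces unbounded positive solutions, and reporting that is
part of the job.  A negative excursion below ``positivity_tol``, by
contrast, can only be solver error — exact solutions with admissible data
are strictly positive — and aborts the run with ``"positivity_lost"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    InitialHistory,
    ModelError,
    NicholsonModel,
    rhs,
    validate_model,
)

__all__ = [
    "SolverConfig",
    "Trajectory",
    "default_step",
    "simulate",
    "euler_oracle",
    "eval_dense",
]


class AdmissibilityError(ModelError):
    """Initial data or model failed validation before integration."""


@dataclass
class SolverConfig:
    step: float | None = None          # base step h; None -> default_step(model)
    method: str = "rk4"                # "rk4" | "euler"
    horizon: float = 20.0              # integration length past t0
    blowup_threshold: float = 1e12
    positivity_tol: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("rk4", "euler"):
            raise ModelError(f"unknown method {self.method!r}")
        if self.step is not None and not (0 < self.step <= self.horizon):
            raise ModelError("need 0 < step <= horizon")
        if not (self.blowup_threshold > 0):
            raise ModelError("blowup_threshold must be positive")
        if self.positivity_tol < 0:
            raise ModelError("positivity_tol must be nonnegative")


def default_step(model: NicholsonModel, horizon: float, n_probe: int = 512) -> float:
    """h = min(0.01, smallest positive delay / 10), probed over the horizon.

    Delays that sweep through zero do not shrink the step — sub-step delays
    are resolved by the implicit stage sweeps, not by refinement — so the
    probed minimum is floored at tau_max/100.
    """
    grid = np.linspace(model.t0, model.t0 + horizon, n_probe)
    min_pos = math.inf
    for tau in model.taus:
        for t in grid:
            v = tau(float(t))
            if v > 1e-9:
                min_pos = min(min_pos, v)
    if not math.isfinite(min_pos):
        return 0.01
    h = min(0.01, max(min_pos / 10.0, model.tau_max / 100.0))
    return max(h, 1e-6)


@dataclass
class Trajectory:
    """Dense numerical solution, with the sampled history segment prepended.

    ``times`` is strictly increasing and uniform past ``t0``; ``derivs``
    holds the right-hand-side slope at each solution node (NaN on the
    history segment, where phi itself is the dense representation).
    """

    times: np.ndarray
    values: np.ndarray
    derivs: np.ndarray
    status: str                       # completed | blowup_detected | positivity_lost
    model: NicholsonModel
    history: InitialHistory
    t0_index: int                     # index of the node at t0
    step: float
    meta: dict = field(default_factory=dict)

    @property
    def t0(self) -> float:
        return float(self.times[self.t0_index])

    def solution_times(self) -> np.ndarray:
        return self.times[self.t0_index:]

    def solution_values(self) -> np.ndarray:
        return self.values[self.t0_index:]

    def __call__(self, t: float) -> float:
        return eval_dense(self, t)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "x": self.values, "dxdt": self.derivs})

    def to_csv(self, path, metadata_path=None) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if metadata_path is not None:
            meta = {
                "model": self.model.label,
                "status": self.status,
                "t0": self.t0,
                "step": self.step,
                "tau_max": self.model.tau_max,
                **self.meta,
            }
            Path(metadata_path).write_text(json.dumps(meta, indent=2))


def _hermite(theta: float, h: float, x0: float, f0: float,
             x1: float, f1: float) -> float:
    t2 = theta * theta
    t3 = t2 * theta
    return ((2 * t3 - 3 * t2 + 1) * x0
            + (t3 - 2 * t2 + theta) * h * f0
            + (-2 * t3 + 3 * t2) * x1
            + (t3 - t2) * h * f1)


def _validate_or_raise(model: NicholsonModel, history: InitialHistory,
                       horizon: float) -> None:
    report = validate_model(model, history, horizon=min(horizon, 10.0), n_probe=801)
    if not report.ok:
        first = report.first()
        raise AdmissibilityError(
            f"model/history failed validation: {first.message} "
            f"(condition {first.condition} at t={first.time})"
        )


def simulate(model: NicholsonModel, history: InitialHistory,
             config: SolverConfig) -> Trajectory:
    """Integrate the model forward from its admissible history."""
    _validate_or_raise(model, history, config.horizon)
    h = config.step if config.step is not None else default_step(model, config.horizon)
    t0, tau = model.t0, model.tau_max
    n_steps = int(round(config.horizon / h))
    if n_steps < 1:
        raise ModelError("horizon shorter than one step")

    alpha, betas, gammas, taus = model.alpha, model.betas, model.gammas, model.taus
    m = model.m

    xs = np.empty(n_steps + 1)
    fs = np.empty(n_steps + 1)
    xs[0] = history(t0)

    # provisional endpoint of the current cell, used when a delayed argument
    # lands inside the step being computed
    prov = {"n": 0, "x1": xs[0], "f1": 0.0}

    def x_at(tt: float, n: int) -> float:
        if tt <= t0:
            return history(tt)
        k = int((tt - t0) / h)
        if k >= n:                      # inside the provisional cell
            theta = (tt - (t0 + n * h)) / h
            return _hermite(theta, h, xs[n], fs[n], prov["x1"], prov["f1"])
        theta = (tt - (t0 + k * h)) / h
        return _hermite(theta, h, xs[k], fs[k], xs[k + 1], fs[k + 1])

    def f_at(tt: float, x_now: float, n: int) -> float:
        xd = [0.0] * m
        for i in range(m):
            d = taus[i](tt)
            xd[i] = x_at(tt - d, n)
        a = alpha(tt)
        if not math.isfinite(a):
            raise ModelError(f"alpha non-finite at t={tt}")
        total = -a * x_now
        for i in range(m):
            b = betas[i](tt)
            g = gammas[i](tt)
            if not (math.isfinite(b) and math.isfinite(g)):
                raise ModelError(f"coefficient non-finite at t={tt}")
            total += b * xd[i] * math.exp(-g * xd[i])
        return total

    fs[0] = f_at(t0, xs[0], 0)
    status = "completed"
    last = n_steps

    for n in range(n_steps):
        tn = t0 + n * h
        xn, fn = xs[n], fs[n]
        # fixed-point sweeps over the provisional cell; for delays longer
        # than the step the first sweep is already exact
        prov["n"], prov["x1"], prov["f1"] = n, xn + h * fn, fn
        x_new = prov["x1"]
        for _ in range(8):
            k1 = f_at(tn, xn, n)
            k2 = f_at(tn + 0.5 * h, xn + 0.5 * h * k1, n)
            k3 = f_at(tn + 0.5 * h, xn + 0.5 * h * k2, n)
            k4 = f_at(tn + h, xn + h * k3, n)
            x_prev = x_new
            x_new = xn + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            prov["x1"] = x_new
            prov["f1"] = f_at(tn + h, x_new, n)
            if abs(x_new - x_prev) <= 1e-12 * (1.0 + abs(x_new)):
                break
        xs[n + 1] = x_new
        fs[n + 1] = prov["f1"]
        if not math.isfinite(x_new) or x_new > config.blowup_threshold:
            status, last = "blowup_detected", n + 1
            break
        if x_new < -config.positivity_tol:
            status, last = "positivity_lost", n + 1
            break

    return _assemble(model, history, xs[: last + 1], fs[: last + 1], h, status,
                     {"method": "rk4", "horizon": config.horizon})


def euler_oracle(model: NicholsonModel, history: InitialHistory,
                 h: float, horizon: float,
                 blowup_threshold: float = 1e12,
                 positivity_tol: float = 0.0) -> Trajectory:
    """Explicit Euler with linear-interpolation history lookup.

    Intentionally naive: first order, no Hermite machinery, no implicit
    stage handling.  Serves as an independent cross-check for the RK4 path.
    """
    _validate_or_raise(model, history, horizon)
    if not (0 < h <= horizon):
        raise ModelError("need 0 < h <= horizon")
    t0 = model.t0
    m = model.m
    n_steps = int(round(horizon / h))
    xs = np.empty(n_steps + 1)
    fs = np.empty(n_steps + 1)
    xs[0] = history(t0)

    def x_at(tt: float, n: int) -> float:
        if tt <= t0:
            return history(tt)
        k = min(int((tt - t0) / h), n - 1) if n > 0 else 0
        theta = (tt - (t0 + k * h)) / h
        return xs[k] * (1 - theta) + xs[k + 1] * theta if n > 0 else xs[0]

    status = "completed"
    last = n_steps
    for n in range(n_steps):
        tn = t0 + n * h
        xd = [x_at(tn - model.taus[i](tn), n) for i in range(m)]
        fs[n] = rhs(model, tn, xs[n], xd)
        xs[n + 1] = xs[n] + h * fs[n]
        if not math.isfinite(xs[n + 1]) or xs[n + 1] > blowup_threshold:
            status, last = "blowup_detected", n + 1
            break
        if xs[n + 1] < -positivity_tol:
            status, last = "positivity_lost", n + 1
            break
    if last == n_steps:
        tn = t0 + n_steps * h
        xd = [x_at(tn - model.taus[i](tn), n_steps) for i in range(m)]
        fs[n_steps] = rhs(model, tn, xs[n_steps], xd)

    return _assemble(model, history, xs[: last + 1], fs[: last + 1], h, status,
                     {"method": "euler", "horizon": horizon})


def _assemble(model, history, xs, fs, h, status, meta) -> Trajectory:
    t0, tau = model.t0, model.tau_max
    n_hist = max(int(math.ceil(tau / h)), 2)
    hist_times = np.linspace(t0 - tau, t0, n_hist + 1)[:-1]
    hist_vals = np.array([history(float(s)) for s in hist_times])
    sol_times = t0 + h * np.arange(len(xs))
    times = np.concatenate([hist_times, sol_times])
    values = np.concatenate([hist_vals, xs])
    derivs = np.concatenate([np.full(n_hist, np.nan), fs])
    return Trajectory(
        times=times, values=values, derivs=derivs, status=status,
        model=model, history=history, t0_index=n_hist, step=h, meta=meta,
    )


def eval_dense(traj: Trajectory, t: float) -> float:
    """Dense-output value at t: phi on the history segment, cubic Hermite
    (linear for Euler trajectories) on solution cells; exact at grid points."""
    if t < traj.times[0] - 1e-12 or t > traj.times[-1] + 1e-12:
        raise ModelError(
            f"t={t} outside covered range [{traj.times[0]}, {traj.times[-1]}]"
        )
    t0 = traj.t0
    if t <= t0:
        return traj.history(t)
    h = traj.step
    n_cells = len(traj.times) - 1 - traj.t0_index
    k = min(int((t - t0) / h), n_cells - 1)
    i = traj.t0_index + k
    theta = (t - traj.times[i]) / h
    if traj.meta.get("method") == "euler":
        return float(traj.values[i] * (1 - theta) + traj.values[i + 1] * theta)
    return float(_hermite(theta, h, traj.values[i], traj.derivs[i],
                          traj.values[i + 1], traj.derivs[i + 1]))
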