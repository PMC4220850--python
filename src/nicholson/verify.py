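"""Trajectory-versus-envelope verification and long-run classification.

These diagnostics turn the two headline behaviours of the model into
computed quantities: a trajectory either outruns every bound (vanishing
mortality with production winning — unbounded growth), or it settles under
the generalized envelope M e^{-lambda* A(t)} even though no classical rate
M e^{-eta t} exists.  All labels are finite-horizon evidence, not proofs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .analysis import AnalysisError, CumulativeAlpha, DecayEstimate
from .integrate import Trajectory
from .model import NicholsonModel

__all__ = [
    "VerificationReport",
    "BehaviourLabel",
    "verify_envelope",
    "classify_long_run",
    "classical_rate_gap",
]


@dataclass
class VerificationReport:
    holds: bool
    max_ratio: float
    argmax_time: float
    checked_range: tuple[float, float]
    tolerance: float


@dataclass
class BehaviourLabel:
    label: str          # converging_to_zero | bounded | unbounded_growth | undetermined
    final_value: float
    max_value: float
    tail_slope: float


def verify_envelope(traj: Trajectory, estimate: DecayEstimate,
                    t_lo: float | None = None,
                    tolerance: float = 1e-3) -> VerificationReport:
    """sup over the trajectory's own grid of x(t) / envelope(t) on [t_lo, end].

    The comparison deliberately reuses the trajectory grid instead of a
    fresh one, so no interpolation bias enters the ratio.  An envelope
    underflow to zero against positive x reports ratio = +inf.
    """
    if traj.status != "completed":
        raise AnalysisError(f"trajectory status is {traj.status!r}, not completed")
    if t_lo is None:
        t_lo = max(estimate.onset_time, traj.t0)
    if t_lo < estimate.onset_time - 1e-12:
        raise AnalysisError("t_lo must be at or after the envelope onset time")
    times = traj.solution_times()
    values = traj.solution_values()
    mask = times >= t_lo - 1e-12
    times, values = times[mask], values[mask]
    if times.size == 0:
        raise AnalysisError("no trajectory points at or after t_lo")
    max_ratio, arg = -math.inf, float(times[0])
    for t, x in zip(times, values):
        env = estimate.envelope(float(t))
        r = math.inf if (env <= 0.0 and x > 0.0) else float(x) / env
        if r > max_ratio:
            max_ratio, arg = r, float(t)
    return VerificationReport(
        holds=max_ratio <= 1.0 + tolerance,
        max_ratio=max_ratio,
        argmax_time=arg,
        checked_range=(float(times[0]), float(times[-1])),
        tolerance=tolerance,
    )


def classify_long_run(traj: Trajectory, growth_factor: float = 10.0,
                      conv_tol: float = 1e-4,
                      slope_tol: float = 1e-2) -> BehaviourLabel:
    """Heuristic long-run label from a finite-horizon trajectory.

    The tail slope is the least-squares line through (t, log x) over the
    last 25% of the solution grid.  "unbounded_growth" requires either a
    blow-up status or exceeding ``growth_factor`` times the history
    supremum with a positive tail slope; a finite simulation can only
    evidence, never prove, unboundedness.
    """
    times = traj.solution_times()
    values = traj.solution_values()
    if times.size < 100:
        raise AnalysisError("trajectory too short to classify (need >= 100 points)")
    sup_phi = traj.history.sup_norm()
    final_value = float(values[-1])
    max_value = float(values.max())

    k = max(2, times.size // 4)
    tt, xx = times[-k:], np.maximum(values[-k:], 1e-300)
    slope = float(np.polyfit(tt, np.log(xx), 1)[0])

    if traj.status == "blowup_detected" or (
        max_value >= growth_factor * sup_phi and slope > 0
    ):
        label = "unbounded_growth"
    elif final_value <= conv_tol * sup_phi and slope < 0:
        label = "converging_to_zero"
    elif max_value < growth_factor * sup_phi and abs(slope) <= slope_tol:
        label = "bounded"
    else:
        label = "undetermined"
    return BehaviourLabel(label=label, final_value=final_value,
                          max_value=max_value, tail_slope=slope)


def classical_rate_gap(model: NicholsonModel, horizon: float = 1e4,
                       n: int = 33) -> dict:
    """Does a classical rate M e^{-eta t} make sense for this model?

    Computes r(t) = A(t)/(t - t0) on a log-spaced grid.  A classical
    exponential estimate requires r bounded below by a positive constant;
    when r -> 0 (sublinear cumulative mortality, e.g. alpha ~ 1/(1+t)) the
    generalized envelope e^{-lambda* A(t)} eventually sits above every
    e^{-eta t}, so no classical rate exists.
    """
    declared = model.alpha.meta.is_uniformly_positive
    A = CumulativeAlpha(model)
    t0 = model.t0
    ts = t0 + np.logspace(0, math.log10(horizon), n)
    r = np.array([A(float(t)) / (float(t) - t0) for t in ts])
    tail = r[n // 2:]
    liminf_ratio = float(tail.min())
    if declared is True:
        exists = True
    else:
        # vanishing trend: the tail keeps shrinking and has lost most of its
        # starting level by the end of the probe range
        shrinking = bool(tail[-1] <= 0.5 * tail[0]) and bool(
            np.all(np.diff(tail) <= 1e-12)
        )
        exists = not shrinking
        if declared is False and exists:
            # declared non-uniformly-positive alpha can still have A(t)/t
            # bounded below (e.g. sin^2 patterns); keep the probe's answer
            pass
    return {
        "classical_rate_exists": exists,
        "liminf_ratio": liminf_ratio,
        "checked_horizon": float(horizon),
    }
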