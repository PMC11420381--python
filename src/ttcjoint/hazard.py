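"""Subject-level hazard with trajectory-linked association terms.

The event sub-model is a proportional-hazards model with a piecewise-constant
baseline hazard and a linear predictor that can include the current value of
the subject's TTC trajectory, its running average, and baseline covariates:

    h(t) = h0(t) * exp(phi'w + a_curr * m(t) + a_avg * avg_m(t))

Cumulative hazards are integrated by Gauss-Legendre quadrature within the
pieces on which the integrand is smooth (baseline knots and dose-change
points split the axis); event times are sampled by inverse-transform, i.e.
root-finding on the cumulative hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .trajectory import Trajectory

__all__ = ["HazardSpec", "hazard", "cumulative_hazard", "sample_event_time"]


@dataclass
class HazardSpec:
    """Piecewise-constant baseline plus association/covariate log-linear terms.

    knots
        Interior breakpoints (months) of the baseline hazard; ``log_rates``
        has one entry more than ``knots`` (last piece extends to infinity).
    lin_pred
        Baseline-covariate contribution phi'w (constant in time).
    alpha_current, alpha_average
        Log-hazard per TTC unit of the trajectory's current value / running
        average.
    """

    knots: np.ndarray = field(default_factory=lambda: np.zeros(0))
    log_rates: np.ndarray = field(default_factory=lambda: np.zeros(1))
    lin_pred: float = 0.0
    alpha_current: float = 0.0
    alpha_average: float = 0.0

    def __post_init__(self) -> None:
        self.knots = np.atleast_1d(np.asarray(self.knots, dtype=float)) if np.size(self.knots) else np.zeros(0)
        self.log_rates = np.atleast_1d(np.asarray(self.log_rates, dtype=float))
        if len(self.log_rates) != len(self.knots) + 1:
            raise ValueError("need len(log_rates) == len(knots) + 1")
        if np.any(np.diff(self.knots) <= 0) or np.any(self.knots <= 0):
            raise ValueError("knots must be positive and strictly increasing")

    def piece_index(self, t) -> np.ndarray:
        return np.searchsorted(self.knots, np.asarray(t, dtype=float), side="left")

    def log_baseline(self, t):
        out = self.log_rates[self.piece_index(t)]
        return out if np.ndim(out) else float(out)


def hazard(t, traj: Trajectory, spec: HazardSpec):
    """Hazard rate (per month) at time(s) ``t > 0``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    eta = spec.lin_pred
    if spec.alpha_current != 0.0:
        eta = eta + spec.alpha_current * traj(t_arr)
    if spec.alpha_average != 0.0:
        eta = eta + spec.alpha_average * traj.average(t_arr)
    out = np.exp(spec.log_rates[spec.piece_index(t_arr)] + eta)
    return out if out.ndim else float(out)


# 7-node Gauss-Legendre on [-1, 1]
_GL_X, _GL_W = np.polynomial.legendre.leggauss(7)


def _breakpoints(t: float, traj: Trajectory, spec: HazardSpec) -> np.ndarray:
    pts = np.concatenate(([0.0, t], spec.knots[spec.knots < t], traj.change_points()))
    pts = pts[pts <= t]
    return np.unique(pts)


def cumulative_hazard(t: float, traj: Trajectory, spec: HazardSpec, n_nodes: int = 7) -> float:
    """int_0^t h(s) ds by per-segment Gauss-Legendre quadrature.

    Segments are delimited by baseline knots and trajectory change points, so
    the integrand is smooth (exp of a linear-plus-smooth function) on each.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0
    if n_nodes == 7:
        gx, gw = _GL_X, _GL_W
    else:
        gx, gw = np.polynomial.legendre.leggauss(n_nodes)
    bp = _breakpoints(t, traj, spec)
    lo, hi = bp[:-1], bp[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    nodes = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    weights = (half[:, None] * gw[None, :]).ravel()
    return float(np.sum(weights * hazard(nodes, traj, spec)))


def sample_event_time(traj: Trajectory, spec: HazardSpec, u: float,
                      t_max: float, tol: float = 1e-8) -> float | None:
    """Inverse-transform event-time draw: solve H(T) = -log(u).

    Returns ``None`` when the cumulative hazard never reaches the target
    within ``t_max`` (no finite event time in the search window).  ``u`` is a
    uniform(0, 1) draw; ``u -> 1`` gives ``T -> 0``.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must be in (0, 1)")
    target = -np.log(u)
    if cumulative_hazard(t_max, traj, spec) < target:
        return None
    f = lambda t: cumulative_hazard(t, traj, spec) - target
    return float(optimize.brentq(f, 0.0, t_max, xtol=tol))
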