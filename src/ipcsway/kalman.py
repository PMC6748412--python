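"""Delayed, switching Kalman filter and the -2 log-likelihood objective.

The likelihood of an observed sway series is computed by the prediction
error decomposition of a continuous-discrete Kalman filter whose
prediction step carries a delayed input term.  Lagged states are linearly
interpolated from the ring of past corrected means; before the first
observation they come from a quadratic backward extrapolation with a free
coefficient.  When consecutive lagged states straddle the activation
boundary, the prediction is split in two at the interpolated crossing so
that the active and inactive dynamics each act for the right share of the
sampling interval.  The delayed covariance is approximated by the current
corrected covariance.

Two implementations coexist: the step-wise Python operations
(:func:`predict`, :func:`correct`) used for inspection and testing, and
the numba fast path behind :func:`minus2_loglik` used by the optimizer.
The test suite asserts their agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import (PhasePoint, TransitionKind, detect_transition)
from .model import (IPCParameters, ModelVariant, PhysicalConstants,
                    StateSpaceModel, TrialNuisance, build_model, discretize,
                    _alpha_clamped)
from .simulate import Trajectory

__all__ = [
    "GaussianState",
    "DelayBuffer",
    "FilterResult",
    "FilterDivergence",
    "lagged_state",
    "extrapolate_initial",
    "predict",
    "correct",
    "minus2_loglik",
    "multi_trial_minus2ll",
    "DIVERGED",
    "DEFAULT_P0",
]

DIVERGED = _kernels.DIVERGED

#: default diagonal of the initial state covariance.  A diffuse start
#: lets the first two observations lock position and velocity without
#: forcing the fitted initial values to match the data to within the
#: (possibly tiny) measurement noise; the initial values then matter
#: only through the lagged pre-history, which is their actual role.
#: Set to 0.0 to make the initial state deterministic at (x0, xdot0).
DEFAULT_P0 = 1e6


class FilterDivergence(RuntimeError):
    """Innovation variance collapsed or the state blew up."""


@dataclass
class GaussianState:
    """Filtered state: mean (position, velocity) and 2x2 covariance."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)

    def symmetrized(self) -> "GaussianState":
        return GaussianState(self.mean, 0.5 * (self.cov + self.cov.T))


class DelayBuffer:
    """Chronological ring of corrected (posterior) state means.

    Entry ``i`` is the corrected mean at time ``t0 + i*dt``.  Lag lookups
    beyond the newest entry clamp to it; lags reaching before ``t0`` are
    the caller's responsibility (see :func:`extrapolate_initial`).
    """

    def __init__(self) -> None:
        self._means: list[np.ndarray] = []

    def append(self, mean: np.ndarray) -> None:
        self._means.append(np.asarray(mean, dtype=float).reshape(2))

    def __len__(self) -> int:
        return len(self._means)

    def __getitem__(self, i: int) -> np.ndarray:
        if not self._means:
            raise IndexError("empty delay buffer")
        return self._means[min(max(i, 0), len(self._means) - 1)]


def lagged_state(buffer: DelayBuffer, i: int, lam: float,
                 compat: bool = False) -> np.ndarray:
    """State at ``lam`` sampling steps before buffer index ``i``.

    Default mode returns the standard linear interpolant between the two
    bracketing entries,

    ``x[i - floor(lam)] + (x[i - ceil(lam)] - x[i - floor(lam)]) * frac``,

    with ``frac = lam - floor(lam)``.  ``compat=True`` instead applies the
    sign ``+ (x[i - floor(lam)] - x[i - ceil(lam)]) * frac``, which
    extrapolates away from the older sample; it is kept as a
    compatibility mode only (both coincide at integer ``lam``, and at
    ``lam = 0`` the entry itself is returned).
    """
    if len(buffer) == 0:
        raise IndexError("empty delay buffer")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    kf = math.floor(lam)
    frac = lam - kf
    a = buffer[i - kf]
    if frac == 0.0:
        return a.copy()
    b = buffer[i - math.ceil(lam)]
    if compat:
        return a + (a - b) * frac
    return a + (b - a) * frac


def extrapolate_initial(nuisance: TrialNuisance, t: float,
                        tau: float) -> np.ndarray:
    """Quadratic backward extrapolation of the lagged state for t <= tau.

    position = x0 + xdot0*(t - tau) + xddot0*(t - tau)^2 and
    velocity = xdot0 + 2*xddot0*(t - tau).  The quadratic coefficient is a
    fitted parameter, not a literal acceleration (no 1/2 factor).
    """
    d = t - tau
    return np.array([
        nuisance.x0 + nuisance.xdot0 * d + nuisance.xddot0 * d * d,
        nuisance.xdot0 + 2.0 * nuisance.xddot0 * d,
    ])


def _linear_step(state: GaussianState, disc, lag: np.ndarray | None
                 ) -> GaussianState:
    """One zero-order-hold prediction with optional delayed input."""
    Ad, Td, Qd = disc.Ad, disc.Atau_d, disc.Qd
    mean = Ad @ state.mean
    cov = Ad @ state.cov @ Ad.T + Qd
    if lag is not None:
        mean = mean + Td @ lag
        cov = cov + Td @ state.cov @ Td.T
    return GaussianState(mean, 0.5 * (cov + cov.T))


def predict(state: GaussianState, lag_start: np.ndarray,
            lag_end: np.ndarray, model: StateSpaceModel,
            dt: float) -> GaussianState:
    """Predict the state one sampling interval ahead.

    ``lag_start`` / ``lag_end`` are the lagged states at the two ends of
    the interval (u and v, velocities s-scaled).  Without a traversal the
    step is a single zero-order hold: active steps feed the interval-END
    lag through the delayed input matrix, inactive steps drop it.  A
    traversal splits the step at the interpolated crossing: switching OFF
    runs active-with-input-u over dt-, then passive over dt+; switching ON
    runs passive over dt-, then active-with-input-crossing over dt+.  The
    delayed covariance is approximated by the current corrected one
    throughout.
    """
    if model.variant is ModelVariant.SDE:
        return _linear_step(state, discretize(model, False, dt), None)
    u = PhasePoint(float(lag_start[0]), float(model.s * lag_start[1]))
    v = PhasePoint(float(lag_end[0]), float(model.s * lag_end[1]))
    if model.variant is ModelVariant.SDDE:
        return _linear_step(state, discretize(model, True, dt),
                            np.asarray(lag_end, dtype=float))
    ev = detect_transition(u, v, model.alpha, model.r, dt)
    if ev.kind is TransitionKind.NONE:
        from .geometry import is_active
        if is_active(v, model.alpha, model.r):
            return _linear_step(state, discretize(model, True, dt),
                                np.asarray(lag_end, dtype=float))
        return _linear_step(state, discretize(model, False, dt), None)
    crossing = np.array([ev.crossing.pos, ev.crossing.vel_scaled / model.s])
    if ev.kind is TransitionKind.OFF:
        if ev.dt_minus > 0:
            state = _linear_step(
                state, discretize(model, True, ev.dt_minus),
                np.asarray(lag_start, dtype=float))
        if ev.dt_plus > 0:
            state = _linear_step(
                state, discretize(model, False, ev.dt_plus), None)
        return state
    # switching ON
    if ev.dt_minus > 0:
        state = _linear_step(state, discretize(model, False, ev.dt_minus),
                             None)
    if ev.dt_plus > 0:
        state = _linear_step(state, discretize(model, True, ev.dt_plus),
                             crossing)
    return state


def correct(state: GaussianState, y: float, model: StateSpaceModel,
            mu: float = 0.0) -> tuple[GaussianState, float]:
    """Standard scalar measurement update.

    Returns the posterior state and the increment to -2 log L:
    ``ln(2 pi S) + e^2 / S`` with innovation ``e = y - (H mean + mu)`` and
    ``S = H cov H' + R``.
    """
    H = model.H
    S = float((H @ state.cov @ H.T)[0, 0]) + float(model.R[0, 0])
    if S <= 0 or not np.isfinite(S):
        raise FilterDivergence(f"non-positive innovation variance S={S}")
    e = float(y) - float((H @ state.mean)[0]) - mu
    gain = (state.cov @ H.T / S).reshape(2)
    mean = state.mean + gain * e
    cov = state.cov - np.outer(gain, H @ state.cov)
    cov = 0.5 * (cov + cov.T)
    return GaussianState(mean, cov), math.log(2.0 * math.pi * S) + e * e / S


@dataclass
class FilterResult:
    """Outcome of one filtering pass."""

    minus2ll: float
    innovations: np.ndarray
    filtered_means: np.ndarray  # (n, 2) corrected means
    n_traversals: int
    diverged: bool = False


def _kernel_args(params: IPCParameters, constants: PhysicalConstants,
                 variant: ModelVariant):
    c = constants.mgh / constants.inertia
    return (c * (1.0 - params.K), -params.B / constants.inertia,
            -c * params.P, -params.D / constants.inertia,
            params.sigma_w ** 2, params.eps,
            _alpha_clamped(params.a), False, params.r, params.tau)


def filter_series(series: Trajectory, params: IPCParameters,
                  nuisance: TrialNuisance,
                  constants: PhysicalConstants = PhysicalConstants(),
                  variant: ModelVariant = ModelVariant.ISDDE,
                  compat: bool = False,
                  p0: float = DEFAULT_P0) -> FilterResult:
    """Run the fast filtering pass and keep innovations / states."""
    y = np.ascontiguousarray(series.values, dtype=float)
    n = y.size
    innov = np.empty(n)
    fp = np.empty(n)
    fv = np.empty(n)
    m2, ntrav = _kernels.filter_minus2ll(
        y, series.dt, *_kernel_args(params, constants, variant),
        nuisance.x0, nuisance.xdot0, nuisance.xddot0, nuisance.mu,
        int(variant), compat, p0, innov, fp, fv)
    return FilterResult(minus2ll=m2, innovations=innov,
                        filtered_means=np.column_stack([fp, fv]),
                        n_traversals=ntrav, diverged=(m2 >= DIVERGED))


def minus2_loglik(series: Trajectory, params: IPCParameters,
                  nuisance: TrialNuisance,
                  constants: PhysicalConstants = PhysicalConstants(),
                  variant: ModelVariant = ModelVariant.ISDDE,
                  compat: bool = False,
                  p0: float = DEFAULT_P0) -> float:
    """-2 log-likelihood of one series under one parameter vector.

    A diverged pass returns the large finite penalty :data:`DIVERGED`
    rather than raising, so derivative-free optimizers can keep ranking
    candidates.
    """
    y = np.ascontiguousarray(series.values, dtype=float)
    n = y.size
    scratch = np.empty(n)
    fp = np.empty(n)
    fv = np.empty(n)
    m2, _ = _kernels.filter_minus2ll(
        y, series.dt, *_kernel_args(params, constants, variant),
        nuisance.x0, nuisance.xdot0, nuisance.xddot0, nuisance.mu,
        int(variant), compat, p0, scratch, fp, fv)
    return m2


def multi_trial_minus2ll(trials: list[tuple[Trajectory, TrialNuisance]],
                         shared: IPCParameters,
                         constants: PhysicalConstants = PhysicalConstants(),
                         variant: ModelVariant = ModelVariant.ISDDE,
                         compat: bool = False,
                         p0: float = DEFAULT_P0) -> float:
    """Sum of per-trial -2 log-likelihoods with shared structural
    parameters and per-trial nuisance parameters."""
    if not trials:
        raise ValueError("at least one trial is required")
    dts = {round(t.dt, 12) for t, _ in trials}
    if len(dts) > 1:
        raise ValueError(f"trials have mismatched sampling rates: {dts}")
    return sum(minus2_loglik(t, shared, nu, constants, variant, compat,
                             p0)
               for t, nu in trials)
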