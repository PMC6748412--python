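"""Structural model of intermittent postural control (IPC).

The standing body is a single-link inverted pendulum pivoting at the ankle.
Tilt angle :math:`\\theta` obeys

.. math::

    I\\ddot\\theta = mgh(1-K)\\theta - B\\dot\\theta
                   - mghP\\,\\theta_{t-\\tau} - D\\dot\\theta_{t-\\tau}
                   + \\sigma w_t,

where the delayed (active) terms are present only when the lagged phase
point satisfies the intermittent activation conditions (see
:mod:`ipcsway.geometry`).  This module holds the parameter containers, the
three nested model variants, the continuous state-space matrices, and their
exact zero-order-hold discretization.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PhysicalConstants",
    "IPCParameters",
    "TrialNuisance",
    "ModelVariant",
    "StateSpaceModel",
    "DiscretizedModel",
    "SingularSwitchingLine",
    "alpha_from_a",
    "build_model",
    "discretize",
]

#: seconds constant used to express velocities in radians on the phase plane
SECONDS_CONSTANT = 1.0

#: clamp applied to `a` at its singular endpoints when building models
_A_CLAMP = 1e-9


class SingularSwitchingLine(ValueError):
    """Raised when the switching line is vertical (a = 0 or a = 1)."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Anthropometric constants of the pendulum.

    Parameters
    ----------
    mass : float
        Body mass ``m`` in kg.
    com_height : float
        Distance ``h`` of the center of mass from the ankle, in m.  For a
        subject of standing height ``H`` the usual convention is
        ``h = 0.51 H`` (see :func:`ipcsway.io.preprocess`).
    gravity : float
        ``g`` in m/s^2.
    inertia : float, optional
        Rotational inertia ``I`` in kg m^2.  Defaults to the point-mass
        value ``m h^2``, which reduces every ``mgh/I`` ratio to ``g/h``.
    """

    mass: float = 60.0
    com_height: float = 1.0
    gravity: float = 9.81
    inertia: float | None = None

    def __post_init__(self) -> None:
        if self.inertia is None:
            object.__setattr__(self, "inertia",
                               self.mass * self.com_height ** 2)
        for name in ("mass", "com_height", "gravity", "inertia"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def mgh(self) -> float:
        """Gravitational toppling-torque coefficient ``m g h`` (N m/rad)."""
        return self.mass * self.gravity * self.com_height


@dataclass(frozen=True)
class IPCParameters:
    """The estimable structural parameters.

    ``K`` and ``P`` are fractions of the gravitational toppling torque
    ``mgh``; ``B`` and ``D`` are torque-per-velocity coefficients
    (N m s/rad); ``a`` is the fraction of the phase plane (outside the
    insensitivity radius ``r``) over which active feedback is on; ``tau``
    is the neural feedback delay in seconds; ``sigma_w`` is the
    acceleration-level white-noise intensity; ``eps`` is the measurement
    error VARIANCE in squared observation units (a sensor SD of 0.01
    corresponds to eps = 1e-4).
    """

    K: float
    B: float
    P: float
    D: float
    a: float
    r: float
    tau: float
    sigma_w: float
    eps: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must lie in [0, 1], got {self.a}")
        for name in ("r", "tau", "sigma_w", "eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "IPCParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class TrialNuisance:
    """Per-trial free parameters.

    ``x0`` / ``xdot0`` are the initial tilt and velocity; ``xddot0`` is the
    quadratic coefficient of the backward extrapolation of the lagged
    pre-history (only meaningful for delayed variants, and not a literal
    acceleration); ``mu`` is the sway origin offset in observation units.
    """

    x0: float = 0.0
    xdot0: float = 0.0
    xddot0: float = 0.0
    mu: float = 0.0


class ModelVariant(enum.IntEnum):
    """Nested model family, in descending order of complexity.

    ISDDE: full intermittent stochastic delay differential equation.
    SDDE:  delayed feedback always active (no switching).
    SDE:   instantaneous PID terms only (no delay machinery).
    """

    ISDDE = 0
    SDDE = 1
    SDE = 2

    @property
    def has_delay(self) -> bool:
        return self is not ModelVariant.SDE

    @property
    def has_switching(self) -> bool:
        return self is ModelVariant.ISDDE


def alpha_from_a(a: float) -> float:
    """Slope of the switching line from the active-fraction parameter.

    The switching line passes through the phase-plane origin at angle
    ``pi/2 - a*pi`` from the position axis, so its slope is
    ``alpha = cos(a*pi)/sin(a*pi)``; the active region then covers exactly
    the fraction ``a`` of the plane outside the insensitivity radius.
    Monotone decreasing on (0, 1), with ``alpha_from_a(0.25) == 1`` and
    ``alpha_from_a(0.5) == 0`` (horizontal line).

    Raises
    ------
    SingularSwitchingLine
        For a = 0 or a = 1, where the line is vertical and the active
        region degenerates to nothing / everything.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a must lie in [0, 1], got {a}")
    s = math.sin(a * math.pi)
    if a in (0.0, 1.0) or s == 0.0:
        raise SingularSwitchingLine(
            f"a = {a} gives a vertical switching line; the active fraction "
            "is degenerate (0% or 100%)")
    return math.cos(a * math.pi) / s


def _alpha_clamped(a: float) -> float:
    """`alpha_from_a` with the singular endpoints nudged inward.

    Used when building models so that optimizer proposals at exactly
    a = 0 or a = 1 behave as never / always active rather than erroring.
    """
    a = min(max(a, _A_CLAMP), 1.0 - _A_CLAMP)
    return alpha_from_a(a)


@dataclass(frozen=True)
class StateSpaceModel:
    """Continuous-time state-space form of one variant.

    ``A`` drives the passive dynamics, ``A_tau`` the delayed active
    feedback (zero for the SDE variant), ``Q = diag(0, sigma_w^2)`` is the
    process-noise intensity, ``H = [1, 0]`` observes position, and
    ``R = [eps]`` is the measurement-noise variance.
    """

    A: np.ndarray
    A_tau: np.ndarray
    Q: np.ndarray
    H: np.ndarray
    R: np.ndarray
    alpha: float
    r: float
    tau: float
    variant: ModelVariant
    s: float = SECONDS_CONSTANT


@dataclass(frozen=True)
class DiscretizedModel:
    """Zero-order-hold discretization of a :class:`StateSpaceModel`."""

    Ad: np.ndarray
    Atau_d: np.ndarray
    Qd: np.ndarray
    dt: float


def build_model(params: IPCParameters, constants: PhysicalConstants,
                variant: ModelVariant = ModelVariant.ISDDE) -> StateSpaceModel:
    """Assemble the continuous matrices for one parameter vector.

    ``A = [[0, 1], [mgh(1-K)/I, -B/I]]`` and
    ``A_tau = [[0, 0], [-mghP/I, -D/I]]`` (zeroed for the SDE variant).
    """
    c = constants.mgh / constants.inertia
    A = np.array([[0.0, 1.0],
                  [c * (1.0 - params.K), -params.B / constants.inertia]])
    if variant.has_delay:
        A_tau = np.array([[0.0, 0.0],
                          [-c * params.P, -params.D / constants.inertia]])
    else:
        A_tau = np.zeros((2, 2))
    Q = np.array([[0.0, 0.0], [0.0, params.sigma_w ** 2]])
    return StateSpaceModel(
        A=A, A_tau=A_tau, Q=Q,
        H=np.array([[1.0, 0.0]]), R=np.array([[params.eps]]),
        alpha=_alpha_clamped(params.a), r=params.r, tau=params.tau,
        variant=variant)


def discretize(model: StateSpaceModel, active: bool,
               dt: float) -> DiscretizedModel:
    """Discretize over a sampling interval ``dt``.

    ``Ad = expm(A dt)``; the delayed input matrix is obtained without
    inverting ``A`` from the block exponential
    ``expm([[A, I], [0, 0]] dt) = [[Ad, J], [0, I]]`` as
    ``Atau_d = J @ A_tau`` (so the singular K = 1 case is legal); ``Qd``
    comes from the standard Van Loan matrix-fraction construction.  With
    ``active=False`` the delayed input is switched off (``Atau_d = 0``).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    A, Q = model.A, model.Q
    blk = np.zeros((4, 4))
    blk[:2, :2] = A * dt
    blk[:2, 2:] = np.eye(2) * dt
    E = expm(blk)
    Ad = E[:2, :2]
    J = E[:2, 2:]
    if active and model.variant.has_delay:
        Atau_d = J @ model.A_tau
    else:
        Atau_d = np.zeros((2, 2))
    VL = np.zeros((4, 4))
    VL[:2, :2] = -A * dt
    VL[:2, 2:] = Q * dt
    VL[2:, 2:] = A.T * dt
    F = expm(VL)
    Qd = F[2:, 2:].T @ F[:2, 2:]
    Qd = 0.5 * (Qd + Qd.T)
    return DiscretizedModel(Ad=Ad, Atau_d=Atau_d, Qd=Qd, dt=dt)
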