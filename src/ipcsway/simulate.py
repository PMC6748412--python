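"""Trajectory generation for the intermittent postural control model.

The stochastic delay differential equation is integrated by Euler-Maruyama
at a fine step (1e-5 s by default), with activation re-evaluated every fine
step from the buffered lagged state, then downsampled by decimation to the
observation rate.  The pre-history before one delay interval holds the
initial state constant.  Measurement noise and the sway-origin offset are
added separately by :func:`observe`, mirroring the observation equation of
the filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from . import _kernels
from .model import (IPCParameters, PhysicalConstants, _alpha_clamped)

__all__ = [
    "Trajectory",
    "ParameterPreset",
    "DivergenceError",
    "simulate",
    "downsample",
    "observe",
    "presets",
    "get_preset",
    "DEFAULT_FINE_DT",
]

DEFAULT_FINE_DT = 1e-5


class DivergenceError(RuntimeError):
    """The integration blew up (unstable parameterization)."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"simulated state diverged at t = {time:.5f} s")


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled series: the common currency of the package."""

    values: np.ndarray
    dt: float
    t0: float = 0.0
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a trajectory needs at least two samples")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)


@dataclass(frozen=True)
class ParameterPreset:
    name: str
    params: IPCParameters


# The six data-generating parameter sets used by the simulation studies.
# Columns: K, B, P, D, a, r, tau, sigma_w, eps.
_PRESET_TABLE = (
    ("Asai et al.",            0.80,   4.00, 0.25,  10.00, 0.62, 0.40, 0.20, 0.20, 1e-4),
    ("Low Noise",              0.80,   4.00, 0.25,  10.00, 0.62, 0.40, 0.20, 0.05, 1e-4),
    ("High Noise",             0.80,   4.00, 0.25,  10.00, 0.62, 0.40, 0.20, 1.00, 1e-4),
    ("Passive Control",        0.95,   4.00, 0.15,  10.00, 0.50, 0.70, 0.20, 0.20, 1e-4),
    ("Active Control",         0.75,   4.00, 0.70, 120.00, 0.80, 0.20, 0.20, 0.20, 1e-4),
    ("Rambling and Trembling", 0.98, 500.00, 0.20, -50.00, 0.45, 0.05, 0.20, 2.00, 1e-4),
)


def presets() -> tuple[ParameterPreset, ...]:
    """The six named data-generating parameter sets."""
    return tuple(
        ParameterPreset(row[0], IPCParameters(*row[1:]))
        for row in _PRESET_TABLE)


def get_preset(name: str) -> ParameterPreset:
    """Look up a preset by (case- and punctuation-insensitive) name."""
    def norm(s: str) -> str:
        return "".join(ch for ch in s.lower() if ch.isalnum())
    for p in presets():
        if norm(p.name) == norm(name) or norm(p.name).startswith(norm(name)):
            return p
    raise KeyError(f"unknown preset {name!r}; choose from "
                   f"{[p.name for p in presets()]}")


def simulate(params: IPCParameters,
             constants: PhysicalConstants = PhysicalConstants(),
             duration: float = 60.0,
             fine_dt: float = DEFAULT_FINE_DT,
             x0: float = 0.0,
             xdot0: float = 0.0,
             seed: int | np.random.Generator | None = None,
             noiseless: bool = False) -> Trajectory:
    """Integrate the model and return the fine-step tilt-angle series.

    The returned trajectory is in state units (radians) and noiseless in
    the *measurement* sense; pass it through :func:`downsample` and
    :func:`observe` to obtain observation-rate data.  ``noiseless=True``
    zeroes the process-noise term as well (deterministic trajectory).

    Raises
    ------
    DivergenceError
        If the state exceeds 1e8, naming the time of blow-up.
    """
    if duration <= 0 or fine_dt <= 0:
        raise ValueError("duration and fine_dt must be positive")
    n = int(round(duration / fine_dt))
    if noiseless or params.sigma_w == 0.0:
        noise = np.zeros(n)
    else:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        noise = rng.standard_normal(n)
    c = constants.mgh / constants.inertia
    pos = np.empty(n + 1)
    vel = np.empty(n + 1)
    code = _kernels.simulate_kernel(
        noise, fine_dt,
        c * (1.0 - params.K), -params.B / constants.inertia,
        -c * params.P, -params.D / constants.inertia,
        0.0 if noiseless else params.sigma_w,
        _alpha_clamped(params.a), False, params.r,
        int(round(params.tau / fine_dt)), x0, xdot0, pos, vel)
    if code >= 0:
        raise DivergenceError(code * fine_dt)
    meta = {"fine_dt": fine_dt, "x0": x0, "xdot0": xdot0,
            "noiseless": bool(noiseless),
            "seed": seed if isinstance(seed, (int, type(None))) else None}
    return Trajectory(values=pos, dt=fine_dt, meta=meta)


def downsample(traj: Trajectory, target_hz: float) -> Trajectory:
    """Decimate to ``target_hz`` by keeping every k-th sample from index 0.

    No averaging or anti-aliasing is applied: the statistical structure of
    the driving Wiener noise is self-similar under decimation.  The target
    interval must be an integer multiple of the source interval.
    """
    interval = 1.0 / target_hz
    ratio = interval / traj.dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6 * k:
        raise ValueError(
            f"target interval {interval} is not an integer multiple of "
            f"dt = {traj.dt}")
    if k == 1:
        return traj
    meta = dict(traj.meta)
    meta["downsample_factor"] = k
    return Trajectory(values=traj.values[::k].copy(), dt=traj.dt * k,
                      t0=traj.t0, meta=meta)


def observe(traj: Trajectory, eps: float, mu: float = 0.0,
            seed: int | np.random.Generator | None = None) -> Trajectory:
    """Add the sway-origin offset and Gaussian measurement noise.

    ``y_i = x_i + mu + sqrt(eps) * N(0, 1)`` with ``eps`` the measurement
    error variance, independent per sample.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    y = traj.values + mu
    if eps > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        y = y + math.sqrt(eps) * rng.standard_normal(y.size)
    meta = dict(traj.meta)
    meta.update({"eps": eps, "mu": mu})
    return Trajectory(values=y, dt=traj.dt, t0=traj.t0, meta=meta)
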