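"""Reading, writing and preprocessing of sway series.

Series are exchanged as delimited text with a time column and a position
column (the layout of public posturography releases such as the "Human
Balance" center-of-mass files: a header row plus tab- or comma-delimited
kinematic columns).  Readers validate uniform sampling; writers round-trip
simulator output bit-equal through the text representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trajectory

__all__ = [
    "SeriesFile",
    "RunConfig",
    "read_series",
    "write_series",
    "preprocess",
    "COM_HEIGHT_RATIO",
]

#: approximate ratio of the center-of-mass height to total standing height
COM_HEIGHT_RATIO = 0.51

#: tolerated jitter of timestamps around uniform sampling, in seconds
_JITTER_TOL = 1e-6


@dataclass(frozen=True)
class SeriesFile:
    """How to pull one uniformly sampled series out of a text file."""

    path: str | Path
    delimiter: str | None = None     # None = sniff (comma / tab / space)
    time_column: str | int | None = 0
    value_column: str | int = 1
    rate_hz: float | None = None     # required when time_column is None
    units: str = "unknown"


def _pick(df: pd.DataFrame, col: str | int, what: str) -> np.ndarray:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise ValueError(f"{what} column index {col} out of range "
                             f"({df.shape[1]} columns)")
        series = df.iloc[:, col]
    else:
        if col not in df.columns:
            raise ValueError(f"{what} column {col!r} not found; available: "
                             f"{list(df.columns)}")
        series = df[col]
    values = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        # +2: 1-based line numbers plus the header row
        raise ValueError(
            f"non-numeric {what} values at line(s) {(bad[:5] + 2).tolist()}")
    return values


def read_series(spec: SeriesFile | str | Path) -> Trajectory:
    """Read a delimited text file into a :class:`Trajectory`.

    The sampling interval is inferred from the time column (which must be
    uniform to within 1e-6 s) or taken from ``rate_hz``.
    """
    if not isinstance(spec, SeriesFile):
        spec = SeriesFile(path=spec)
    path = Path(spec.path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = spec.delimiter
    if sep is None:
        head = path.open().readline()
        sep = "," if "," in head else ("\t" if "\t" in head else r"\s+")
    if len(sep) == 1:
        # exact float parsing so simulator output round-trips bit-equal
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    else:
        df = pd.read_csv(path, sep=sep, engine="python")
    values = _pick(df, spec.value_column, "value")
    if spec.time_column is None:
        if not spec.rate_hz:
            raise ValueError("rate_hz is required when no time column is "
                             "given")
        dt = 1.0 / spec.rate_hz
        t0 = 0.0
    else:
        t = _pick(df, spec.time_column, "time")
        steps = np.diff(t)
        if steps.size == 0:
            raise ValueError("series has fewer than two rows")
        dt = float(np.median(steps))
        if dt <= 0 or np.any(np.abs(steps - dt) > _JITTER_TOL):
            raise ValueError(
                "time column is not uniformly sampled (jitter beyond "
                f"{_JITTER_TOL} s); use rate_hz with time_column=None to "
                "override")
        t0 = float(t[0])
    return Trajectory(values=values, dt=dt, t0=t0,
                      meta={"path": str(path), "units": spec.units})


def write_series(traj: Trajectory, path: str | Path,
                 delimiter: str = ",") -> Path:
    """Write (time, value) rows as delimited text; full double precision
    so that read_series round-trips simulator output bit-equal."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"time{delimiter}value\n")
        for t, v in zip(traj.times, traj.values):
            fh.write(f"{float(t)!r}{delimiter}{float(v)!r}\n")
    return path


def preprocess(traj: Trajectory, trim_head: int = 0, trim_tail: int = 0
               ) -> Trajectory:
    """Trim transient samples from both ends of a series.

    The first and last seconds of experimental trials often contain
    initiation/termination movements; trimming is by sample count, not
    seconds.
    """
    if trim_head < 0 or trim_tail < 0:
        raise ValueError("trim counts must be non-negative")
    n = len(traj)
    if n - trim_head - trim_tail < 2:
        raise ValueError(
            f"trimming {trim_head}+{trim_tail} samples leaves fewer than "
            f"two of {n}")
    stop = n - trim_tail if trim_tail else n
    return Trajectory(values=traj.values[trim_head:stop].copy(),
                      dt=traj.dt, t0=traj.t0 + trim_head * traj.dt,
                      meta=dict(traj.meta))


def com_height_from_stature(height_m: float) -> float:
    """Pendulum length h from standing height via h = 0.51 * height."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return COM_HEIGHT_RATIO * height_m


@dataclass
class RunConfig:
    """Serializable description of one analysis run."""

    mass: float = 60.0
    height: float | None = None      # standing height in m (h = 0.51 * it)
    com_height: float = 1.0          # used when height is None
    variant: str = "ISDDE"
    context: str = "simulation"
    bounds: dict = field(default_factory=dict)
    de_iterations: int = 15000
    trim_head: int = 0
    trim_tail: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))
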