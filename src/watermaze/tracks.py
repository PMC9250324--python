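"""Reading, validation, and preprocessing of raw swim tracks.

A :class:`Trajectory` is one trial's time-stamped 2-D track in pool-centered
centimeters, plus trial metadata.  Preprocessing goes position -> uniform
resampling -> moving-average smoothing -> heading/turn extraction; the
heading series is the substrate for trajectory-change detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import PoolConfig, OutsidePoolError

__all__ = [
    "Trajectory",
    "HeadingSeries",
    "TrackFormatError",
    "DIALECTS",
    "read_track",
    "resample",
    "smooth",
    "headings",
]

log = logging.getLogger(__name__)

TRIAL_TYPES = ("pretraining", "acquisition", "probe")


class TrackFormatError(ValueError):
    """A track file cannot be loaded as a valid trajectory."""


@dataclass
class Trajectory:
    """An ordered time/position track for a single swim trial.

    ``t`` is seconds from trial start, ``x``/``y`` pool-centered cm.
    Time must be strictly increasing with at least two samples.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    animal_id: str = "animal"
    group: Optional[str] = None  # "young" | "aged"
    day: int = 0
    trial_index: int = 0
    trial_type: str = "acquisition"
    trial_duration: float = 90.0
    start_octant: Optional[int] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite values in trajectory")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"trial_type must be one of {TRIAL_TYPES}")
        if self.t[-1] - self.t[0] > self.trial_duration + 1.0:
            raise ValueError(
                f"track spans {self.t[-1] - self.t[0]:.1f} s, longer than the "
                f"{self.trial_duration:.0f} s trial duration"
            )

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def path_length(self) -> float:
        """Total polyline length in cm."""
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))

    def validate_in_pool(self, cfg: PoolConfig) -> None:
        r = np.hypot(self.x, self.y)
        if np.any(r > cfg.pool_radius + cfg.wall_tolerance):
            raise OutsidePoolError(
                f"trajectory leaves the pool by up to "
                f"{float(np.max(r)) - cfg.pool_radius:.1f} cm (tolerance {cfg.wall_tolerance:.1f})"
            )

    def sliced(self, stop: int) -> "Trajectory":
        """Copy containing samples ``[0, stop)``."""
        return replace(self, t=self.t[:stop].copy(), x=self.x[:stop].copy(), y=self.y[:stop].copy())


@dataclass
class HeadingSeries:
    """Per-step bearings and signed turns of a preprocessed trajectory.

    ``bearing[i]`` is the compass bearing (deg) of step i; ``turn[j]`` the
    signed heading change, positive clockwise, wrapped to (-180, 180], at the
    vertex between steps j and j+1.  ``point_t``/``point_index`` give the
    time stamp and original sample index of each retained vertex, so event
    spans can be mapped back onto the trajectory; vertex j sits at retained
    point j+1.
    """

    bearing: np.ndarray  # (m,) deg
    turn: np.ndarray  # (m-1,) deg, positive clockwise
    displacement: np.ndarray  # (m,) cm per step
    t_mid: np.ndarray  # (m,) step midpoint time
    x_mid: np.ndarray  # (m,)
    y_mid: np.ndarray  # (m,)
    point_t: np.ndarray  # (m+1,) times of retained points
    point_index: np.ndarray  # (m+1,) indices of retained points

    @property
    def n_steps(self) -> int:
        return self.bearing.size

    def total_abs_turn(self) -> float:
        return float(np.sum(np.abs(self.turn)))


# ---------------------------------------------------------------------------
# file reading

#: Known track-file dialects.  Each maps logical columns to acceptable
#: header names (case-insensitive) and declares the factor converting file
#: length units to cm.  The "anymaze-export" dialect is a column map + meter
#: conversion only; nothing proprietary is parsed.
DIALECTS = {
    "generic": {
        "t": ("t", "time"),
        "x": ("x",),
        "y": ("y",),
        "length_to_cm": 1.0,
    },
    "anymaze-export": {
        "t": ("time",),
        "x": ("centre position x", "center position x"),
        "y": ("centre position y", "center position y"),
        "length_to_cm": 100.0,  # exports positions in meters
    },
}


def _resolve_column(df: pd.DataFrame, names) -> str:
    lower = {c.strip().lower(): c for c in df.columns}
    for name in names:
        if name in lower:
            return lower[name]
    raise TrackFormatError(f"none of the columns {names} present (have {list(df.columns)})")


def read_track(
    path,
    dialect: str = "generic",
    meta: Optional[dict] = None,
    cfg: Optional[PoolConfig] = None,
    max_gap: float = 1.0,
) -> Trajectory:
    """Read one trial's track file into a validated :class:`Trajectory`.

    Non-finite rows are dropped (and counted in the log); a load fails if
    columns are missing, more than 10% of rows are dropped, time is
    non-monotone after cleaning, or a dropped stretch leaves a gap longer
    than ``max_gap`` seconds (occlusion gaps are interpolated across at the
    resampling stage; longer gaps invalidate latency and void the trial).
    """
    if dialect not in DIALECTS:
        raise TrackFormatError(f"unknown dialect {dialect!r}; know {sorted(DIALECTS)}")
    spec = DIALECTS[dialect]
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise TrackFormatError(f"cannot parse {path}: {exc}") from exc
    cols = {k: _resolve_column(df, spec[k]) for k in ("t", "x", "y")}
    raw = df[[cols["t"], cols["x"], cols["y"]]].apply(pd.to_numeric, errors="coerce").to_numpy()
    keep = np.all(np.isfinite(raw), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("%s: dropped %d non-finite row(s) of %d", path, n_dropped, len(raw))
    if len(raw) and n_dropped > 0.1 * len(raw):
        raise TrackFormatError(f"{path}: {n_dropped}/{len(raw)} rows dropped (>10%)")
    raw = raw[keep]
    if raw.shape[0] < 2:
        raise TrackFormatError(f"{path}: fewer than 2 usable samples")
    t = raw[:, 0]
    if np.any(np.diff(t) <= 0):
        raise TrackFormatError(f"{path}: time not strictly increasing after cleaning")
    if np.any(np.diff(t) > max_gap):
        raise TrackFormatError(f"{path}: gap longer than {max_gap:.1f} s after cleaning")
    scale = spec["length_to_cm"]
    traj = Trajectory(t=t - t[0], x=raw[:, 1] * scale, y=raw[:, 2] * scale, **(meta or {}))
    if cfg is not None:
        traj.validate_in_pool(cfg)
    return traj


# ---------------------------------------------------------------------------
# preprocessing

def resample(traj: Trajectory, dt: float) -> Trajectory:
    """Linearly interpolate onto a uniform time grid preserving both endpoints.

    The grid has ``round(span / dt)`` intervals so the effective step equals
    the requested ``dt`` up to endpoint rounding; resampling an
    already-resampled track at the same ``dt`` is the identity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = traj.duration
    if dt > span:
        raise ValueError(f"dt {dt} exceeds trajectory span {span:.3f} s")
    n = max(1, int(round(span / dt)))
    grid = np.linspace(traj.t[0], traj.t[-1], n + 1)
    return replace(
        traj,
        t=grid,
        x=np.interp(grid, traj.t, traj.x),
        y=np.interp(grid, traj.t, traj.y),
    )


def _reflect_pad(a: np.ndarray, k: int) -> np.ndarray:
    """Odd (point-symmetric) reflection about both endpoints.

    Continues a straight line exactly, so smoothing never bends a straight
    track at its ends.
    """
    left = 2 * a[0] - a[k:0:-1]
    right = 2 * a[-1] - a[-2 : -k - 2 : -1]
    return np.concatenate([left, a, right])


def smooth(traj: Trajectory, window: int) -> Trajectory:
    """Centered moving average of x and y; time stamps unchanged.

    ``window`` must be odd and no larger than the number of points;
    ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > traj.n:
        raise ValueError(f"window {window} exceeds {traj.n} points")
    if window == 1:
        return replace(traj, t=traj.t.copy(), x=traj.x.copy(), y=traj.y.copy())
    k = window // 2
    kernel = np.full(window, 1.0 / window)
    xs = np.convolve(_reflect_pad(traj.x, k), kernel, mode="valid")
    ys = np.convolve(_reflect_pad(traj.y, k), kernel, mode="valid")
    return replace(traj, t=traj.t.copy(), x=xs, y=ys)


def headings(traj: Trajectory, min_step: float = 1.0) -> HeadingSeries:
    """Extract per-step bearings and signed turns from a preprocessed track.

    Consecutive samples closer than ``min_step`` cm (Euclidean distance from
    the last retained point) are merged before bearings are computed, so
    jitter-dominated micro-steps cannot create spurious angulation.  Signed
    turns are wrapped to (-180, 180], positive clockwise.  Fewer than three
    retained points yield an empty turn series ("no turns measurable").
    """
    if min_step < 0:
        raise ValueError("min_step must be non-negative")
    x, y, t = traj.x, traj.y, traj.t
    keep = [0]
    last = 0
    for i in range(1, traj.n):
        if np.hypot(x[i] - x[last], y[i] - y[last]) >= min_step:
            keep.append(i)
            last = i
    keep = np.asarray(keep, dtype=int)
    kx, ky, kt = x[keep], y[keep], t[keep]
    dx, dy = np.diff(kx), np.diff(ky)
    bearing = np.degrees(np.arctan2(dx, dy)) % 360.0
    d = np.diff(bearing)
    turn = -((-d + 180.0) % 360.0 - 180.0)  # wrap to (-180, 180]
    return HeadingSeries(
        bearing=bearing,
        turn=turn,
        displacement=np.hypot(dx, dy),
        t_mid=(kt[:-1] + kt[1:]) / 2,
        x_mid=(kx[:-1] + kx[1:]) / 2,
        y_mid=(ky[:-1] + ky[1:]) / 2,
        point_t=kt,
        point_index=keep,
    )
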