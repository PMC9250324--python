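"""Traditional per-trial Morris water maze measurements.

Latency and distance to the first platform-zone entry, mean swim speed,
percentage of time in the correct quadrant, and the number of platform-zone
crossings.  "Reaching the platform" is operationalized as the first entry
into zone 0 (the platform disc); an optional minimum dwell supports labs
that require a platform mount.  Probe trials use the same zone-0 disc even
though the platform is physically absent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import PoolConfig, zone_of, quadrant_of, correct_quadrant
from .tracks import Trajectory

__all__ = [
    "TrialMetrics",
    "TrialMetricsExtractor",
    "first_platform_index",
    "platform_latency",
    "platform_distance",
    "mean_speed",
    "quadrant_time_pct",
    "platform_crossings",
    "trial_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class TrialMetrics:
    """The traditional measures for one trial.

    If the platform was never reached the latency is censored at the trial
    duration and the distance is the full path length.
    """

    platform_latency: float  # s
    platform_distance: float  # cm
    mean_speed: float  # cm/s
    quadrant_time_pct: float  # % of trial time in the correct quadrant
    platform_crossings: int
    found_platform: bool


def _zones(traj: Trajectory, cfg: PoolConfig) -> np.ndarray:
    return np.asarray(zone_of(traj.x, traj.y, cfg))


def first_platform_index(traj: Trajectory, cfg: PoolConfig, min_dwell: float = 0.0) -> Optional[int]:
    """Index of the first zone-0 sample (first entry with >= ``min_dwell`` s
    of continuous occupancy), or None if the platform zone is never reached."""
    z = _zones(traj, cfg)
    inside = z == 0
    if not inside.any():
        return None
    if min_dwell <= 0:
        return int(np.argmax(inside))
    # first run of zone-0 samples lasting at least min_dwell
    padded = np.diff(np.concatenate([[0], inside.view(np.int8), [0]]))
    starts, ends = np.where(padded == 1)[0], np.where(padded == -1)[0]
    for s, e in zip(starts, ends):
        if traj.t[e - 1] - traj.t[s] >= min_dwell:
            return int(s)
    return None


def platform_latency(traj: Trajectory, cfg: PoolConfig, min_dwell: float = 0.0) -> float:
    """Time (s) to the first platform-zone entry; trial duration if never reached."""
    i = first_platform_index(traj, cfg, min_dwell)
    return float(traj.trial_duration) if i is None else float(traj.t[i] - traj.t[0])


def platform_distance(traj: Trajectory, cfg: PoolConfig, min_dwell: float = 0.0) -> float:
    """Swim path length (cm) until the first platform-zone entry; full path if never reached."""
    seg = np.hypot(np.diff(traj.x), np.diff(traj.y))
    i = first_platform_index(traj, cfg, min_dwell)
    return float(seg.sum()) if i is None else float(seg[:i].sum())


def mean_speed(traj: Trajectory) -> float:
    """Mean swim speed (cm/s): total path length / elapsed time.

    Use the cleaned, unsmoothed (resampled) track: smoothing shortens paths
    and would bias the speed downward.
    """
    if traj.duration <= 0:
        raise ValueError("zero elapsed time")
    return traj.path_length() / traj.duration


def quadrant_time_pct(traj: Trajectory, cfg: PoolConfig) -> float:
    """Percentage of trial time spent in the correct quadrant.

    Each sample interval contributes its duration to the quadrant containing
    its midpoint.
    """
    xm, ym = (traj.x[:-1] + traj.x[1:]) / 2, (traj.y[:-1] + traj.y[1:]) / 2
    q = np.asarray(quadrant_of(xm, ym, cfg))
    dt = np.diff(traj.t)
    return float(100.0 * dt[q == correct_quadrant(cfg)].sum() / dt.sum())


def platform_crossings(traj: Trajectory, cfg: PoolConfig) -> int:
    """Number of entry transitions into the platform zone (zone 0).

    Starting inside the platform zone counts as one crossing.
    """
    z = _zones(traj, cfg)
    entries = int(np.sum((z[1:] == 0) & (z[:-1] != 0)))
    return entries + int(z[0] == 0)


def trial_metrics(traj: Trajectory, cfg: PoolConfig, min_dwell: float = 0.0) -> TrialMetrics:
    """All traditional measures for one trial."""
    i = first_platform_index(traj, cfg, min_dwell)
    return TrialMetrics(
        platform_latency=platform_latency(traj, cfg, min_dwell),
        platform_distance=platform_distance(traj, cfg, min_dwell),
        mean_speed=mean_speed(traj),
        quadrant_time_pct=quadrant_time_pct(traj, cfg),
        platform_crossings=platform_crossings(traj, cfg),
        found_platform=i is not None,
    )


_META_COLS = ("animal_id", "group", "day", "trial_index", "trial_type")


def metrics_table(trajectories: Iterable[Trajectory], cfg: PoolConfig, min_dwell: float = 0.0) -> pd.DataFrame:
    """Per-trial metrics table: one row per trial, metadata + TrialMetrics fields."""
    rows = []
    for traj in trajectories:
        row = {k: getattr(traj, k) for k in _META_COLS}
        row.update(asdict(trial_metrics(traj, cfg, min_dwell)))
        rows.append(row)
    return pd.DataFrame(rows)


class TrialMetricsExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer turning trajectories into a metrics table.

    ``transform`` maps a sequence of :class:`Trajectory` to the per-trial
    metrics :class:`~pandas.DataFrame`; stateless apart from the pool
    geometry resolved at ``fit``.
    """

    def __init__(self, pool: Optional[PoolConfig] = None, min_dwell: float = 0.0):
        self.pool = pool
        self.min_dwell = min_dwell

    def fit(self, X, y=None):
        self.pool_ = self.pool if self.pool is not None else PoolConfig()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "pool_"):
            self.fit(X)
        return metrics_table(X, self.pool_, self.min_dwell)
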