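"""Pool coordinate system, octants, quadrants, and the five analysis zones.

Coordinates are pool-centered Cartesian centimeters with +y = north and
compass bearings measured clockwise from north.  The maze is divided in
octants by the eight compass axes (octant 0 is the 45-degree sector centered
on N, counted clockwise), in quadrants by the N-S and E-W axes, and into
five circular zones:

* zone 0 - the platform disc,
* zone 1 - the peripheral platform zone, a disc centered on the platform,
* zones 2-4 - the central, intermediate, and outer (thigmotaxis) annuli,
  concentric with the pool.

Zones overlap geometrically; membership uses the precedence 0 > 1 > 2 > 3 > 4
(most specific wins) so that the zones partition the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "PoolConfig",
    "Point",
    "OutsidePoolError",
    "OCTANT_NAMES",
    "octant_of",
    "zone_of",
    "quadrant_of",
    "correct_quadrant",
    "bearing_of",
    "rotate_xy",
]

#: Octant names clockwise from north; octant i is centered on bearing 45*i.
OCTANT_NAMES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")

#: Quadrant names clockwise; quadrant i spans bearings [90*i, 90*(i+1)).
QUADRANT_NAMES = ("NE", "SE", "SW", "NW")


class OutsidePoolError(ValueError):
    """A coordinate lies outside the pool beyond the wall tolerance.

    Raised by the membership queries to signal a corrupt track rather than
    silently assigning a zone to an impossible position.
    """


class Point(NamedTuple):
    """Pool-centered Cartesian position in cm (+y = north)."""

    x: float
    y: float


@dataclass(frozen=True)
class PoolConfig:
    """Geometry of the pool, platform, octants, and analysis zones.

    All lengths are centimeters, all angles degrees.  Defaults reproduce a
    common aged-rat protocol: a 180 cm pool with a 15 cm platform on the NE
    axis halfway between the wall and the center (45 cm radial offset of the
    platform center).

    ``north_reference`` rotates the whole compass frame (octant axes,
    quadrants, and the platform bearing) relative to the +y axis, so tracks
    recorded in an arbitrarily oriented camera frame can be mapped in.
    ``wall_tolerance`` absorbs tracking jitter at the wall; points farther
    outside the pool are rejected.
    """

    pool_diameter: float = 180.0
    pool_depth: float = 60.0  # informational only
    platform_diameter: float = 15.0
    platform_bearing: float = 45.0  # NE
    platform_radial_offset: float = 45.0
    zone1_diameter: float = 75.0
    zone2_diameter: float = 90.0
    zone3_diameter: float = 150.0
    zone4_diameter: float = 180.0
    north_reference: float = 0.0
    wall_tolerance: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.platform_diameter < self.zone1_diameter):
            raise ValueError("platform_diameter must be positive and smaller than zone1_diameter")
        if not (self.zone1_diameter < self.zone2_diameter < self.zone3_diameter <= self.zone4_diameter):
            raise ValueError("zone diameters must satisfy zone1 < zone2 < zone3 <= zone4")
        if abs(self.zone4_diameter - self.pool_diameter) > 1e-9:
            raise ValueError("zone4_diameter must equal pool_diameter")
        if self.platform_radial_offset + self.platform_diameter / 2 >= self.pool_diameter / 2:
            raise ValueError("platform must lie entirely inside the pool")
        if self.wall_tolerance < 0:
            raise ValueError("wall_tolerance must be non-negative")

    @property
    def pool_radius(self) -> float:
        return self.pool_diameter / 2

    @property
    def platform_radius(self) -> float:
        return self.platform_diameter / 2

    @property
    def platform_center(self) -> Point:
        """Platform center in pool-centered coordinates."""
        theta = np.deg2rad(self.north_reference + self.platform_bearing)
        r = self.platform_radial_offset
        return Point(r * np.sin(theta), r * np.cos(theta))

    def rotated(self, angle: float) -> "PoolConfig":
        """Config for the same maze viewed in a frame rotated clockwise by ``angle``."""
        return PoolConfig(**{**asdict(self), "north_reference": self.north_reference + angle})

    @classmethod
    def from_file(cls, path) -> "PoolConfig":
        """Load a pool configuration from a YAML/flat key-value file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pool configuration keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _as_xy(x, y=None):
    """Accept ``(x, y)`` arrays/scalars or a single Point/2-sequence."""
    if y is None:
        x, y = x  # Point or (x, y) pair
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def _check_in_pool(x, y, cfg: PoolConfig) -> None:
    r = np.hypot(x, y)
    limit = cfg.pool_radius + cfg.wall_tolerance
    if np.any(r > limit):
        worst = float(np.max(r))
        raise OutsidePoolError(
            f"point(s) up to {worst:.2f} cm from pool center exceed pool radius "
            f"{cfg.pool_radius:.1f} + tolerance {cfg.wall_tolerance:.1f} cm (corrupt track?)"
        )


def bearing_of(x, y=None, cfg: PoolConfig | None = None):
    """Compass bearing of point(s) in degrees [0, 360), clockwise from north."""
    x, y = _as_xy(x, y)
    north = cfg.north_reference if cfg is not None else 0.0
    return (np.degrees(np.arctan2(x, y)) - north) % 360.0


def octant_of(x, y=None, cfg: PoolConfig | None = None):
    """Octant index (0-7) of point(s); octant 0 is centered on N, counted clockwise.

    Sectors are half-open ``[center - 22.5, center + 22.5)`` so the octants
    partition the pool.  The exact pool center has no defined bearing and is
    assigned octant 0 by convention.
    """
    cfg = cfg or PoolConfig()
    x, y = _as_xy(x, y)
    _check_in_pool(x, y, cfg)
    b = bearing_of(x, y, cfg)
    idx = np.floor(((b + 22.5) % 360.0) / 45.0).astype(int) % 8
    return idx if idx.ndim else int(idx)


def zone_of(x, y=None, cfg: PoolConfig | None = None):
    """Zone id (0-4) of point(s) under the precedence 0 > 1 > 2 > 3 > 4.

    Zones 0 and 1 are discs centered on the platform (the platform zone and
    the peripheral platform zone); zones 2-4 are concentric with the pool.
    Boundary circles belong to the more specific (inner) zone.
    """
    cfg = cfg or PoolConfig()
    x, y = _as_xy(x, y)
    _check_in_pool(x, y, cfg)
    px, py = cfg.platform_center
    d_plat = np.hypot(x - px, y - py)
    r = np.hypot(x, y)
    z = np.select(
        [
            d_plat <= cfg.platform_radius,
            d_plat <= cfg.zone1_diameter / 2,
            r <= cfg.zone2_diameter / 2,
            r <= cfg.zone3_diameter / 2,
        ],
        [0, 1, 2, 3],
        default=4,
    )
    return z if z.ndim else int(z)


def quadrant_of(x, y=None, cfg: PoolConfig | None = None):
    """Quadrant id (0-3 = NE, SE, SW, NW) of point(s)."""
    cfg = cfg or PoolConfig()
    x, y = _as_xy(x, y)
    _check_in_pool(x, y, cfg)
    q = np.floor(bearing_of(x, y, cfg) / 90.0).astype(int) % 4
    return q if q.ndim else int(q)


def correct_quadrant(cfg: PoolConfig | None = None) -> int:
    """Quadrant containing the platform center (NE = 0 under defaults)."""
    cfg = cfg or PoolConfig()
    return quadrant_of(*cfg.platform_center, cfg)


def rotate_xy(x, y, angle: float):
    """Rotate point(s) clockwise (compass sense) by ``angle`` degrees."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    a = np.deg2rad(angle)
    return x * np.cos(a) + y * np.sin(a), -x * np.sin(a) + y * np.cos(a)
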