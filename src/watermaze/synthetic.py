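"""Synthetic swim trajectories with known ground-truth strategy labels.

Stands in for real tracking data: every archetype trajectory is built from
motion primitives so that its trajectory-change count, directionality, and
category are fixed **by construction** (never by running the classifier).

Construction vocabulary
-----------------------
A counted change is inserted as a dedicated *motif*:

* curve      - a sustained 300-degree counterclockwise loop (one >90-degree
  same-direction turn run, below the spiral limit);
* spiral     - a 420-degree arc (cumulative turn beyond a full circle);
* zigzag     - three alternating 50-degree bends with short legs, wrapped
  in sub-90-degree arc blocks that fold the motif into a compact loop;
* peripheral - a wall-following pass across two octant boundaries in the
  thigmotaxis zone, opening the trial so that no entry maneuver is needed.

Everything that must *not* count stays below every detection threshold:
steering is done with sharp vertex turns of at most 40 degrees (below the
45-degree zigzag bend and far below the 90-degree curve threshold), and
every deliberate turn is separated from the next by a straight gap long
enough that resampling and smoothing cannot fuse two turns into one run.
Each turning motif rotates the heading by exactly +60 degrees and is
re-anchored at ring sites on the far side of the pool, so displacement
differences cannot accumulate; chain layouts are retried over ring phases
and motif orders until the whole path fits the pool, keeps clear of the
platform, and realizes the required directionality.  Every generated polyline is finally audited against an
independent run-scan of its exact turn sequence and zone/octant occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import PoolConfig, zone_of, octant_of
from .tracks import Trajectory, read_track
from .strategy import ChangeEvent, SSALabel, CATEGORIES

__all__ = [
    "ArchetypeSpec",
    "CohortSpec",
    "GenerationError",
    "generate_archetype",
    "generate_cohort",
    "write_tracks",
    "load_tracks",
    "DEFAULT_MIXTURES",
]

DT = 0.1  # s, sampling step of generated tracks

_DIRECT = set("ABCD")
_INDIRECT = set("EFG")
_INEFFECTIVE = set("HIJ")

_BANDS = {"A": (0, 0), "B": (1, 3), "C": (4, 6), "D": (7, 10), "E": (1, 3), "F": (4, 6), "G": (7, 10)}


class GenerationError(ValueError):
    """A spec cannot be realized as a valid trajectory."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """Recipe for one trajectory with a known strategy label.

    Event counts apply to the effective categories A-G and must lie in the
    target category's precision band; the ineffective archetypes H-J place
    their own motions and take no event counts.  ``seed`` drives noise and
    the shuffling of event kinds along the path.
    """

    target_category: str
    n_curves: int = 0
    n_zigzags: int = 0
    n_spirals: int = 0
    n_peripheral: int = 0
    start_octant: Optional[int] = None
    speed: float = 20.0  # cm/s
    noise_sd: float = 0.0  # cm
    seed: int = 0
    trial_duration: float = 90.0

    @property
    def n_events(self) -> int:
        return self.n_curves + self.n_zigzags + self.n_spirals + self.n_peripheral

    @property
    def pre_zone1_events(self) -> int:
        """Changes committed before reaching the peripheral platform zone."""
        return self.n_events if self.target_category in _INDIRECT else 0

    def validate(self) -> None:
        cat = self.target_category
        if cat not in CATEGORIES:
            raise GenerationError(f"unknown category {cat!r}")
        counts = (self.n_curves, self.n_zigzags, self.n_spirals, self.n_peripheral)
        if any(c < 0 for c in counts):
            raise GenerationError("event counts must be non-negative")
        if cat in _INEFFECTIVE:
            if self.n_events:
                raise GenerationError(f"{cat} archetypes place their own motions; give no event counts")
            return
        lo, hi = _BANDS[cat]
        if not lo <= self.n_events <= hi:
            raise GenerationError(
                f"{self.n_events} trajectory changes inconsistent with category {cat} "
                f"(band {lo}..{hi}; counts above {hi} are not constructible within the trial)"
            )
        if self.n_peripheral > 1:
            raise GenerationError("at most one peripheral change is constructible per trial")
        if self.n_peripheral and cat in _DIRECT:
            raise GenerationError(
                "peripheral changes are only constructible for indirect archetypes "
                "(the generator opens E-G trials with the wall-seeking episode)"
            )
        if not 10.0 <= self.speed <= 35.0:
            raise GenerationError("speed outside the plausible 10-35 cm/s swimming range")


# ---------------------------------------------------------------------------
# path builder

def _unit(bearing_deg: float) -> np.ndarray:
    a = math.radians(bearing_deg)
    return np.array([math.sin(a), math.cos(a)])


def _wrap(angle: float) -> float:
    return -((-angle + 180.0) % 360.0 - 180.0)


class _PathBuilder:
    """Constant-speed polyline builder with heading state.

    Samples are ``step`` cm apart.  Deliberate turns are either circular
    arcs (the counted motifs) or sharp vertex turns of at most ``MAX_BEND``
    degrees (steering); the builder keeps every turn separated from the
    next by a straight ``gap`` so turn runs never fuse downstream.
    """

    MAX_BEND = 40.0  # deg; steering turns never reach the 45-deg zigzag bend
    ARC_RADIUS = 6.0

    def __init__(self, start_xy: Sequence[float], heading: float, step: float, gap: float,
                 avoid: Optional[Sequence[float]] = None):
        self.pts: List[np.ndarray] = [np.asarray(start_xy, dtype=float)]
        self.heading = float(heading)
        self.step = float(step)
        self.gap = float(gap)
        #: point large curls should keep away from (the platform surround)
        self.avoid = None if avoid is None else np.asarray(avoid, dtype=float)

    # -- state ----------------------------------------------------------
    @property
    def pos(self) -> np.ndarray:
        return self.pts[-1]

    @property
    def length(self) -> float:
        return (len(self.pts) - 1) * self.step

    def mark(self) -> Tuple[int, float]:
        return len(self.pts), self.heading

    def rollback(self, mark: Tuple[int, float]) -> None:
        n, heading = mark
        del self.pts[n:]
        self.heading = heading

    def bearing_to(self, target) -> float:
        d = np.asarray(target, dtype=float) - self.pos
        return math.degrees(math.atan2(d[0], d[1])) % 360.0

    def dist_to(self, target) -> float:
        return float(np.hypot(*(np.asarray(target, dtype=float) - self.pos)))

    # -- primitives -----------------------------------------------------
    def straight(self, length: float) -> None:
        n = max(1, int(round(length / self.step)))
        u = _unit(self.heading) * self.step
        for _ in range(n):
            self.pts.append(self.pos + u)

    def arc(self, total: float, radius: Optional[float] = None) -> None:
        """Turn by ``total`` signed degrees along a circular arc."""
        if abs(total) < 1e-9:
            return
        radius = radius or self.ARC_RADIUS
        per = math.degrees(self.step / radius)
        n = max(1, int(round(abs(total) / per)))
        phi = total / n
        for _ in range(n):
            u = _unit(self.heading + phi / 2.0) * self.step
            self.pts.append(self.pos + u)
            self.heading += phi

    def turn(self, tau: float) -> None:
        """Sharp sub-threshold vertex turn."""
        if abs(tau) > 44.0:
            raise GenerationError(f"sharp turn of {tau:.1f} deg would register as a change")
        self.heading += tau

    # -- steering -------------------------------------------------------
    def leg_to(self, target, prefer_sign: int = 0) -> None:
        """Rotate toward ``target`` (sub-threshold turns, gap-separated) and
        go there in one straight leg, re-aiming as the curl displaces us."""
        turn_limit = 43.0  # final residual executable as one sharp turn
        if self.dist_to(target) <= max(1.5 * self.step, 3.0):
            return  # already there; a bearing to a coincident point is noise
        err = _wrap(self.bearing_to(target) - self.heading)
        if not prefer_sign and abs(err) > 95.0 and self.avoid is not None:
            prefer_sign = _curl_sign(self, self.avoid)
        if prefer_sign and err and np.sign(err) != prefer_sign:
            err -= math.copysign(360.0, err)
        guard = 0
        while abs(err) > turn_limit:
            if (guard := guard + 1) > 20:
                raise GenerationError(f"steering failed to face {np.round(target, 1)}")
            if self.dist_to(target) < 46.0 and abs(err) > 70.0:
                # target inside the turning circle: curl to gain room, on
                # the side clear of the platform surround if one is set
                s = _curl_sign(self, self.avoid) if self.avoid is not None else -np.sign(err)
                self.turn(s * self.MAX_BEND)
                self.straight(self.gap)
                err = _wrap(self.bearing_to(target) - self.heading)
                continue
            self.turn(math.copysign(self.MAX_BEND, err))
            self.straight(self.gap)
            err -= math.copysign(self.MAX_BEND, err)
            if abs(err) < 90.0:  # nearly facing it: trust geometry again
                err = _wrap(self.bearing_to(target) - self.heading)
        d = self.dist_to(target)
        if abs(err) > 1e-9:
            self.turn(err)
            # after a turn, travel at least a gap so the next deliberate
            # bend cannot fuse with it
            self.straight(max(d, self.gap))
        elif d > self.step / 2:
            self.straight(d)

    def approach(self, target) -> None:
        """Best-effort move toward ``target``: anchors the chain without
        insisting on hitting the point (sites are soft waypoints)."""
        for _ in range(8):
            err = _wrap(self.bearing_to(target) - self.heading)
            d = self.dist_to(target)
            if abs(err) <= 43.0:
                if abs(err) > 1e-9:
                    self.turn(err)
                    self.straight(max(d, self.gap))
                elif d > self.step / 2:
                    self.straight(d)
                return
            if d < 2.5 * self.gap:
                break  # awkwardly close: fire the motif from here instead
            self.turn(math.copysign(self.MAX_BEND, err))
            self.straight(self.gap)
        self.straight(self.gap)  # separation before whatever comes next


# ---------------------------------------------------------------------------
# motifs (each inserts exactly one counted trajectory change and rotates the
# heading by exactly +60 degrees)

def _motif_curve(pb: _PathBuilder) -> None:
    pb.arc(-300.0)  # one >90-deg run, below the spiral limit; -300 = +60 net
    pb.straight(pb.gap)


def _motif_spiral(pb: _PathBuilder) -> None:
    pb.arc(420.0, radius=5.0)  # single run beyond a full circle
    pb.straight(pb.gap)


def _motif_zigzag(pb: _PathBuilder) -> None:
    """One counted zigzag: the alternating -50/+50/-50 triple.

    The triple is wrapped in sub-90-degree clockwise arc blocks totalling a
    +420-degree swing, folding the whole motif into a compact loop (net +60
    like every motif).  The wrapping arcs extend the alternating run seen
    by a rater but cannot add events: same-sign neighbours stay in separate
    sub-curve runs, and the maximal alternating run still yields exactly
    one zigzag.
    """
    for _ in range(3):
        pb.arc(85.0)
        pb.straight(pb.gap)
    pb.arc(-50.0)
    pb.straight(10.0)  # opposite-sign corners never fuse: legs can be short
    pb.arc(50.0)
    pb.straight(10.0)
    pb.arc(-50.0)
    pb.straight(10.0)
    for _ in range(2):
        pb.arc(85.0)
        pb.straight(pb.gap)
    pb.arc(45.0)  # heading bookkeeping
    pb.straight(pb.gap)


def _curl_sign(pb: _PathBuilder, plat: np.ndarray) -> int:
    """Rotation sense whose curl region keeps clear of the platform
    surround and of the wall.  A long rotation with gap-separated bends
    traces a polygon around a center one curl radius to the side of the
    heading; pick the side with the better worst-case margin."""
    rc = pb.gap / (2.0 * math.sin(math.radians(pb.MAX_BEND / 2.0)))
    best, best_margin = 1, -np.inf
    for s in (1, -1):
        c = pb.pos + rc * _unit(pb.heading + s * 90.0)
        margin = min(
            float(np.hypot(*(c - plat))) - rc - 38.0,  # platform surround
            86.0 - float(np.hypot(*c)) - rc,  # wall
        )
        if margin > best_margin:
            best, best_margin = s, margin
    return best


_WALL_R = 82.0  # wall-following vertex radius; chords dip to ~80, above zone 3


def _wall_opening(pb: _PathBuilder, U, theta0: float, n_chords: int = 3, dtheta: float = 25.0) -> None:
    """One counted peripheral-seeking episode, opening a trial.

    Wall-following from the release point: the trajectory starts on the
    wall already aligned with the first chord, so no entry maneuver is
    needed; self-correcting vertex turns of ~``dtheta`` degrees (far below
    the curve threshold) sweep the thigmotaxis zone across two octant
    boundaries, then the path peels back inward.
    """
    for k in range(1, n_chords + 1):
        v = _WALL_R * U(theta0 + dtheta * k)
        tau = _wrap(pb.bearing_to(v) - pb.heading)
        if abs(tau) > 43.0:
            raise GenerationError("wall-following geometry broke down")
        pb.turn(tau)
        pb.straight(max(pb.dist_to(v), pb.step))
    pb.turn(40.0)  # peel off inward, ending the thigmotaxis-zone episode
    pb.straight(pb.gap)
    pb.turn(40.0)
    pb.straight(pb.gap)


_MOTIFS = {"curve": _motif_curve, "zigzag": _motif_zigzag, "spiral": _motif_spiral}


# ---------------------------------------------------------------------------
# construction audit (independent run-scan on the exact polyline)

def _polyline_turns(pts: np.ndarray) -> np.ndarray:
    d = np.diff(pts, axis=0)
    keep = np.hypot(d[:, 0], d[:, 1]) > 1e-9
    d = d[keep]
    b = np.degrees(np.arctan2(d[:, 0], d[:, 1]))
    db = np.diff(b)
    return -((-db + 180.0) % 360.0 - 180.0)


def _scan_turn_events(turns: np.ndarray):
    """(curves, spirals, zigzags, first event vertex) by direct run-scan."""
    signs = np.where(np.abs(turns) <= 1e-7, 0, np.sign(turns)).astype(int)
    bends: List[Tuple[int, float, int]] = []  # (sign, |total|, first vertex)
    i = 0
    while i < signs.size:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < signs.size and signs[j + 1] == signs[i]:
            j += 1
        bends.append((signs[i], abs(float(turns[i : j + 1].sum())), i))
        i = j + 1
    first_vertex = None

    def note(v):
        nonlocal first_vertex
        if first_vertex is None or v < first_vertex:
            first_vertex = v

    spirals = curves = zig = 0
    for s, m, v in bends:
        if m > 360.0 + 1e-6:
            spirals += 1
            note(v)
        elif m > 90.0 + 1e-6:
            curves += 1
            note(v)
    eligible = [45.0 - 1e-6 <= m <= 360.0 for s, m, v in bends]
    k = 0
    while k < len(bends):
        if not eligible[k]:
            k += 1
            continue
        j = k
        while j + 1 < len(bends) and eligible[j + 1] and bends[j + 1][0] == -bends[j][0]:
            j += 1
        if j - k + 1 >= 3:
            zig += 1
            note(bends[k][2])
        k = j + 1
    return curves, spirals, zig, first_vertex


def _peripheral_scan(z: np.ndarray, o: np.ndarray):
    """(count, first sample index) of peripheral episodes."""
    count, first = 0, None
    for zone_id, limit in ((3, 3), (4, 1)):
        mask = (z == zone_id).view(np.int8)
        d = np.diff(np.concatenate([[0], mask, [0]]))
        for s, e in zip(np.where(d == 1)[0], np.where(d == -1)[0]):
            if np.unique(o[s:e]).size > limit:
                count += 1
                if first is None or s < first:
                    first = int(s)
    return count, first


def _audit(pts: np.ndarray, spec: ArchetypeSpec, cfg: PoolConfig) -> None:
    """Verify the built polyline realizes the spec; raise otherwise."""
    r = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(r > cfg.pool_radius - 1.0):
        raise GenerationError(f"construction too close to the wall (max r = {r.max():.1f} cm)")
    zones = np.asarray(zone_of(pts[:, 0], pts[:, 1], cfg))
    octs_all = np.asarray(octant_of(pts[:, 0], pts[:, 1], cfg))
    cat = spec.target_category
    if cat in _INEFFECTIVE:
        if (zones == 0).any():
            raise GenerationError(f"{cat} construction reached the platform zone")
        frac4 = float(np.mean(zones == 4))
        if cat == "J" and frac4 < 0.999:
            raise GenerationError("thigmotaxis construction left zone 4")
        if cat == "H" and np.unique(octs_all).size > 3:
            raise GenerationError(f"localized construction spread over {np.unique(octs_all).size} octants")
        if cat == "I" and (np.unique(octs_all).size <= 4 or frac4 > 0.5):
            raise GenerationError("nonlocalized construction not pool-wide")
        return
    if not (zones == 0).any():
        raise GenerationError(f"{cat} construction never reached the platform zone")
    cut = int(np.argmax(zones == 0))
    pre = pts[: cut + 1]
    curves, spirals, zig, first_vertex = _scan_turn_events(_polyline_turns(pre))
    peri, first_peri = _peripheral_scan(zones[: cut + 1], octs_all[: cut + 1])
    got = (curves, spirals, zig, peri)
    want = (spec.n_curves, spec.n_spirals, spec.n_zigzags, spec.n_peripheral)
    if got != want:
        raise GenerationError(
            f"construction audit mismatch for {cat}: built (curves, spirals, zigzags, "
            f"peripheral) = {got}, spec wants {want}"
        )
    # directionality: compare first zone<=1 arrival vs first change
    arrive = int(np.argmax(zones[: cut + 1] <= 1))
    starts = [v + 1 for v in (first_vertex,) if v is not None]
    if first_peri is not None:
        starts.append(first_peri)
    first_event = min(starts) if starts else None
    if spec.target_category in _DIRECT:
        if first_event is not None and arrive > first_event:
            raise GenerationError("direct construction committed a change before reaching zone 1")
    else:
        if first_event is None or arrive <= first_event:
            raise GenerationError("indirect construction reached zone 1 before its first change")


# ---------------------------------------------------------------------------
# archetype generation
#
# All layout bearings below are expressed in a canonical frame with the
# platform on the NE axis; generation rotates them rigidly with the actual
# platform bearing and north reference, so construction commutes with frame
# rotation.

def _frame(cfg: PoolConfig):
    """Rotation (deg) of the canonical platform-on-NE frame, and its unit fn."""
    delta = cfg.north_reference + cfg.platform_bearing - 45.0

    def U(bearing: float) -> np.ndarray:
        return _unit(delta + bearing)

    return delta, U


#: Motif sites sit on a ring around a center displaced to the SW: every
#: site keeps >=38 cm clearance from the platform while the ring still
#: spans the pool widely enough to host up to ten motifs.
_SITE_CENTER = (22.0, 225.0)  # (radius, canonical bearing)
_SITE_R = 22.0


def _run_chain(pb: _PathBuilder, kinds: Sequence[str], cfg: PoolConfig, phi0: float,
               phi_step: float = 60.0) -> None:
    """Execute the turning-motif chain, re-anchoring at a ring site before
    each motif so displacement differences cannot accumulate."""
    delta, U = _frame(cfg)
    centre = _SITE_CENTER[0] * U(_SITE_CENTER[1])
    phi = phi0
    for kind in kinds:
        pb.approach(centre + _SITE_R * U(phi))
        _MOTIFS[kind](pb)
        phi += phi_step


def _build_effective(spec: ArchetypeSpec, cfg: PoolConfig, rng: np.random.Generator) -> np.ndarray:
    delta, U = _frame(cfg)
    step = spec.speed * DT
    gap = 19.0  # fuse-safe straight separation at any speed (measured worst ~16.5)
    plat = np.asarray(cfg.platform_center, dtype=float)
    direct = spec.target_category in _DIRECT
    so = spec.start_octant if spec.start_octant is not None else (4 if direct else 5)
    start = 83.0 * U(45.0 * so)

    turning = (
        ["curve"] * spec.n_curves
        + ["zigzag"] * spec.n_zigzags
        + ["spiral"] * spec.n_spirals
    )
    kinds = [str(k) for k in rng.permutation(turning)] if turning else []

    if not kinds and not spec.n_peripheral:  # A: beeline to the platform
        pb = _PathBuilder(start, 0.0, step, gap, avoid=plat)
        pb.heading = pb.bearing_to(plat)
        pb.straight(pb.dist_to(plat))
        return _finish_effective(pb, spec)

    if direct:
        # touch the peripheral platform zone (NW flank of the zone-1 disc,
        # ~34 cm from the platform center) before any change is committed,
        # then curl away counterclockwise toward the far half of the pool
        pb = _PathBuilder(start, 0.0, step, gap, avoid=plat)
        touch = 20.0 * U(0.0)
        pb.heading = pb.bearing_to(touch)
        pb.straight(pb.dist_to(touch))
        pb.leg_to(38.0 * U(250.0), prefer_sign=-1)
    elif spec.n_peripheral:
        # open the trial with the wall-seeking episode: it is the first
        # change by construction, long before any zone-1 contact
        theta0 = 45.0 * so
        v0 = _WALL_R * U(theta0)
        pb = _PathBuilder(v0, 0.0, step, gap, avoid=plat)
        pb.heading = pb.bearing_to(_WALL_R * U(theta0 + 25.0))
        _wall_opening(pb, U, theta0)
        pb.leg_to(32.0 * U(theta0 + 60.0))
    else:
        # reach a staging anchor on the start side, far from the platform;
        # the first change is committed before any zone-1 contact
        anchor = 32.0 * U(45.0 * so)
        pb = _PathBuilder(start, 0.0, step, gap, avoid=plat)
        pb.heading = pb.bearing_to(anchor)
        pb.straight(pb.dist_to(anchor))

    base = pb.mark()
    centre = _SITE_CENTER[0] * U(_SITE_CENTER[1])
    d = pb.pos - centre
    phi_near = (math.degrees(math.atan2(d[0], d[1])) - delta) % 360.0
    errors = []
    orders = [kinds]
    for _ in range(2):  # alternative motif orders move the troublemakers
        orders.append([str(k) for k in rng.permutation(orders[-1])])
    for order in orders:
        for phi_step in (60.0, 45.0):
            for dh in (0.0, 60.0, -60.0, 120.0, -120.0, 180.0, 30.0, -30.0, 90.0, -90.0, 150.0, -150.0):
                pb.rollback(base)
                try:
                    _run_chain(pb, kinds=order, cfg=cfg, phi0=phi_near + dh, phi_step=phi_step)
                    pb.leg_to(plat)
                    pts = _finish_effective(pb, spec)
                    _audit(pts, spec, cfg)
                    return pts
                except GenerationError as exc:
                    errors.append(str(exc))
    raise GenerationError(
        f"no feasible layout for {spec.target_category} with {spec.n_events} changes: "
        + "; ".join(sorted(set(errors)))
    )


def _finish_effective(pb: _PathBuilder, spec: ArchetypeSpec) -> np.ndarray:
    pts = np.asarray(pb.pts)
    if (len(pts) - 1) * DT > spec.trial_duration - 0.5:
        raise GenerationError(
            f"{spec.n_events} changes at {spec.speed:.1f} cm/s do not fit in a "
            f"{spec.trial_duration:.0f} s trial"
        )
    return pts


def _tangent_point(start: np.ndarray, centre: np.ndarray, radius: float) -> np.ndarray:
    """Touch point of the tangent from ``start`` to the circle, chosen so
    that continuing clockwise around the circle is a gentle turn."""
    v = centre - start
    d = float(np.hypot(*v))
    if d <= radius:
        raise GenerationError("circuit entry point lies inside the circuit")
    alpha = math.degrees(math.acos(radius / d))
    b = math.degrees(math.atan2(-v[0], -v[1]))  # bearing centre -> start
    for sgn in (1.0, -1.0):
        p = centre + radius * _unit(b + sgn * alpha)
        approach = math.degrees(math.atan2(*(p - start)))
        tangent = math.degrees(math.atan2(*(p - centre))) + 90.0  # clockwise sense
        if abs(_wrap(tangent - approach)) < 90.0:
            return p
    raise GenerationError("no clockwise tangent found")  # pragma: no cover


def _loop_circuit(pb: _PathBuilder, centre: np.ndarray, radius: float, delta: float,
                  U, length_needed: float, phi_step: float = 35.0) -> None:
    """Hop clockwise around a polygonal circuit until the path is long
    enough.  Entry is along a tangent line, so every vertex turn equals the
    polygon's exterior angle and stays below the steering limit."""
    entry = _tangent_point(pb.pos, centre, radius)
    pb.heading = pb.bearing_to(entry)
    pb.straight(pb.dist_to(entry))
    d = pb.pos - centre
    phi = (math.degrees(math.atan2(d[0], d[1])) - delta) % 360.0
    while pb.length < length_needed:
        phi += phi_step
        target = centre + radius * U(phi)
        # ineffective categories are defined by occupancy, not turning, so
        # plain vertex turns are fine here whatever their size
        pb.heading = pb.bearing_to(target)
        pb.straight(max(pb.dist_to(target), pb.step))


def _build_ineffective(spec: ArchetypeSpec, cfg: PoolConfig, rng: np.random.Generator) -> np.ndarray:
    delta, U = _frame(cfg)
    step = spec.speed * DT
    gap = 19.0  # fuse-safe straight separation at any speed (measured worst ~16.5)
    cat = spec.target_category
    n_target = int(math.floor(spec.trial_duration / DT)) + 1
    length_needed = (n_target + 2) * step

    if cat == "J":
        # wall-hugging polygon: vertices at r = 88, chords dipping to ~84
        # (clear of the zone-1 disc even on the platform side), vertex turns
        # ~34.5 deg - below every turning threshold
        rv, dtheta = 88.0, 34.5
        theta = 45.0 * (spec.start_octant if spec.start_octant is not None else 5)
        v0 = rv * U(theta)
        pb = _PathBuilder(v0, 0.0, step, gap)
        k = 1
        pb.heading = pb.bearing_to(rv * U(theta + dtheta))
        while pb.length < length_needed:
            v = rv * U(theta + k * dtheta)
            pb.straight(max(pb.dist_to(v), step))
            pb.heading = pb.bearing_to(rv * U(theta + (k + 1) * dtheta))
            k += 1
        return np.asarray(pb.pts[:n_target])

    so = spec.start_octant if spec.start_octant is not None else 5
    start = 83.0 * U(45.0 * so)
    if cat == "H":
        # circuit tucked into the SW wedge: search confined to at most the
        # three contiguous S/SW/W octants
        centre = 45.0 * U(222.0)
        radius = 24.0
    else:  # I: roams the whole pool, skirting the platform zone
        centre = 8.0 * U(225.0)
        radius = 30.0
    pb = _PathBuilder(start, 0.0, step, gap)
    _loop_circuit(pb, centre, radius, delta, U, length_needed)
    return np.asarray(pb.pts[:n_target])


def generate_archetype(
    spec: ArchetypeSpec,
    cfg: Optional[PoolConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Trajectory, SSALabel]:
    """Build one trajectory realizing ``spec`` plus its ground-truth label.

    The label reflects the constructed event count and placement; the
    construction is audited against an independent run-scan of its exact
    turn sequence and zone/octant occupancy, and generation fails loudly if
    the spec is infeasible.
    """
    spec.validate()
    cfg = cfg or PoolConfig()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    if spec.target_category in _INEFFECTIVE:
        pts = _build_ineffective(spec, cfg, rng)
    else:
        pts = _build_effective(spec, cfg, rng)
    _audit(pts, spec, cfg)

    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
        # noise must not push samples beyond the wall tolerance
        r = np.hypot(pts[:, 0], pts[:, 1])
        lim = cfg.pool_radius + 0.9 * cfg.wall_tolerance
        over = r > lim
        if over.any():
            pts[over] *= (lim / r[over])[:, None]

    t = np.arange(len(pts)) * DT
    so = spec.start_octant
    if so is None:
        so = 4 if spec.target_category in _DIRECT else 5
    traj = Trajectory(
        t=t,
        x=pts[:, 0],
        y=pts[:, 1],
        trial_type="acquisition",
        trial_duration=spec.trial_duration,
        start_octant=so,
    )

    cat = spec.target_category
    effective = cat not in _INEFFECTIVE
    direction = "not-applicable" if not effective else ("direct" if cat in _DIRECT else "indirect")
    events = tuple(
        ChangeEvent(kind=k, start_time=-1.0, end_time=-1.0, start_index=-1, end_index=-1, magnitude=float("nan"))
        for k in ["curve"] * spec.n_curves
        + ["nonsense"] * (spec.n_zigzags + spec.n_spirals)
        + ["peripheral"] * spec.n_peripheral
    )
    label = SSALabel(cat, effective, direction, spec.n_events, events)
    return traj, label


# ---------------------------------------------------------------------------
# cohorts

#: Default per-acquisition-day category mixtures.  Qualitative emulation of
#: the typical progression: young animals move from ineffective search
#: through indirect to direct, precise strategies by day 10; aged animals
#: progress more slowly and plateau in the effective-but-indirect range.
DEFAULT_MIXTURES = {
    "young": [
        {"J": 0.25, "I": 0.35, "H": 0.15, "E": 0.15, "F": 0.05, "B": 0.05},
        {"J": 0.15, "I": 0.30, "H": 0.15, "E": 0.20, "F": 0.08, "B": 0.12},
        {"J": 0.10, "I": 0.22, "H": 0.13, "E": 0.25, "F": 0.08, "B": 0.18, "A": 0.04},
        {"J": 0.05, "I": 0.15, "H": 0.10, "E": 0.25, "F": 0.05, "B": 0.30, "A": 0.10},
        {"J": 0.04, "I": 0.12, "H": 0.06, "E": 0.20, "F": 0.05, "B": 0.38, "A": 0.15},
        {"J": 0.03, "I": 0.10, "H": 0.05, "E": 0.17, "F": 0.03, "B": 0.42, "A": 0.20},
        {"I": 0.08, "H": 0.04, "E": 0.15, "F": 0.03, "B": 0.45, "C": 0.02, "A": 0.23},
        {"I": 0.07, "H": 0.03, "E": 0.12, "B": 0.45, "C": 0.03, "A": 0.30},
        {"I": 0.06, "E": 0.11, "B": 0.43, "C": 0.05, "A": 0.35},
        {"I": 0.05, "E": 0.10, "B": 0.40, "C": 0.05, "A": 0.40},
    ],
    "aged": [
        {"J": 0.35, "I": 0.40, "H": 0.10, "E": 0.10, "G": 0.05},
        {"J": 0.30, "I": 0.35, "H": 0.12, "E": 0.15, "F": 0.05, "G": 0.03},
        {"J": 0.22, "I": 0.30, "H": 0.13, "E": 0.20, "F": 0.10, "G": 0.05},
        {"J": 0.15, "I": 0.25, "H": 0.12, "E": 0.25, "F": 0.13, "G": 0.05, "B": 0.05},
        {"J": 0.12, "I": 0.22, "H": 0.10, "E": 0.28, "F": 0.15, "G": 0.05, "B": 0.08},
        {"J": 0.10, "I": 0.20, "H": 0.08, "E": 0.30, "F": 0.15, "G": 0.04, "B": 0.10, "A": 0.03},
        {"J": 0.08, "I": 0.18, "H": 0.06, "E": 0.32, "F": 0.16, "G": 0.03, "B": 0.13, "A": 0.04},
        {"J": 0.07, "I": 0.16, "H": 0.05, "E": 0.32, "F": 0.18, "G": 0.03, "B": 0.15, "A": 0.04},
        {"J": 0.06, "I": 0.15, "H": 0.04, "E": 0.32, "F": 0.20, "B": 0.18, "A": 0.05},
        {"J": 0.05, "I": 0.15, "E": 0.30, "F": 0.22, "C": 0.03, "B": 0.20, "A": 0.05},
    ],
}

_SPEED_PROFILES = {"young": (20.5, 3.5), "aged": (19.3, 2.0)}  # cm/s mean, sd
_START_OCTANTS = (4, 5, 6)  # S, SW, W: three pseudo-random starting points


@dataclass(frozen=True)
class CohortSpec:
    """One simulated training cohort (group x rats x days x trials).

    ``mixtures`` is a per-day list of category->probability dicts; defaults
    follow the group's typical acquisition progression.
    """

    group: str = "young"
    n_rats: int = 8
    days: int = 10
    trials_per_day: int = 4
    mixtures: Optional[Sequence[dict]] = None
    seed: int = 0

    def day_mixture(self, day: int) -> dict:
        mixtures = self.mixtures if self.mixtures is not None else DEFAULT_MIXTURES[self.group]
        mix = mixtures[min(day - 1, len(mixtures) - 1)]
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-6:
            raise GenerationError(f"day-{day} mixture weights sum to {total}, not 1")
        return mix


def _draw_counts(cat: str, speed: float, rng: np.random.Generator) -> dict:
    """Event-kind counts for one effective trial, feasible at ``speed``."""
    if cat in _INEFFECTIVE:
        return {}
    lo, hi = _BANDS[cat]
    hi = min(hi, 7 if speed < 18.0 else 8)
    total = int(rng.integers(lo, max(lo, hi) + 1))
    if total == 0:
        return {}
    n_zig = min(2, int(rng.binomial(total, 0.15)))
    n_spiral = min(2, int(rng.binomial(total - n_zig, 0.10))) if total - n_zig else 0
    rest = total - n_zig - n_spiral
    # the wall-seeking opening is only constructible for indirect trials
    n_peri = min(1, int(rng.binomial(rest, 0.10))) if rest and cat in _INDIRECT else 0
    return {
        "n_curves": total - n_zig - n_spiral - n_peri,
        "n_zigzags": n_zig,
        "n_spirals": n_spiral,
        "n_peripheral": n_peri,
    }


def generate_cohort(
    spec: CohortSpec,
    cfg: Optional[PoolConfig] = None,
    noise_sd: float = 0.0,
) -> List[Tuple[Trajectory, SSALabel]]:
    """Simulate every trial of a cohort; reproducible under ``spec.seed``."""
    if spec.group not in _SPEED_PROFILES:
        raise GenerationError(f"unknown group {spec.group!r}")
    cfg = cfg or PoolConfig()
    rng = np.random.default_rng(spec.seed)
    mean, sd = _SPEED_PROFILES[spec.group]
    out = []
    for rat in range(spec.n_rats):
        for day in range(1, spec.days + 1):
            mix = spec.day_mixture(day)
            cats, probs = zip(*sorted(mix.items()))
            for trial in range(spec.trials_per_day):
                cat = str(rng.choice(cats, p=probs))
                for attempt in range(8):
                    speed = float(np.clip(rng.normal(mean, sd), 16.0, 26.0))
                    counts = _draw_counts(cat, speed, rng)
                    if attempt >= 2 and cat not in _INEFFECTIVE:
                        # rare awkward layouts: fall back to curve-only changes
                        counts = {"n_curves": sum(counts.values())} if counts else {}
                    aspec = ArchetypeSpec(
                        target_category=cat,
                        start_octant=int(_START_OCTANTS[(day + trial + attempt) % 3]),
                        speed=speed,
                        noise_sd=noise_sd,
                        **counts,
                    )
                    try:
                        traj, label = generate_archetype(aspec, cfg, rng)
                        break
                    except GenerationError:
                        if attempt == 7:
                            raise
                traj = replace(
                    traj,
                    animal_id=f"{spec.group}-{rat:02d}",
                    group=spec.group,
                    day=day,
                    trial_index=trial,
                )
                out.append((traj, label))
    return out


# ---------------------------------------------------------------------------
# file output

_META_COLS = ("animal_id", "group", "day", "trial_index", "trial_type", "trial_duration", "start_octant")


def write_tracks(trials, out_dir, dialect: str = "generic") -> pd.DataFrame:
    """Write one delimited track file per trial plus a metadata sidecar.

    Returns the sidecar table; ``category`` carries the ground-truth label
    for generated trials.  Output is byte-stable for a fixed input.
    """
    if dialect != "generic":
        raise ValueError("only the generic dialect is written")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for traj, label in trials:
        fname = f"{traj.animal_id}_d{traj.day:02d}_t{traj.trial_index}.csv"
        df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
        df.to_csv(out_dir / fname, index=False, float_format="%.6f")
        row = {"file": fname, **{k: getattr(traj, k) for k in _META_COLS}}
        row["category"] = label.category if label is not None else ""
        rows.append(row)
    meta = pd.DataFrame(rows)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    return meta


def load_tracks(in_dir, dialect: str = "generic") -> List[Tuple[Trajectory, Optional[str]]]:
    """Read a directory written by :func:`write_tracks` (or hand-assembled
    in the same layout) back into trajectories + optional reference labels."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "metadata.csv")
    out = []
    for _, row in meta.iterrows():
        meta_kwargs = {k: row[k] for k in _META_COLS if k in row and pd.notna(row[k])}
        for key in ("day", "trial_index", "start_octant"):
            if key in meta_kwargs:
                meta_kwargs[key] = int(meta_kwargs[key])
        traj = read_track(in_dir / row["file"], dialect=dialect, meta=meta_kwargs)
        cat = row.get("category")
        out.append((traj, cat if isinstance(cat, str) and cat else None))
    return out
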