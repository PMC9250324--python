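"""Search-strategy classification of swim trajectories (categories A-J).

The decision tree mirrors how trained observers score a trial:

1. **Effectiveness** - did the path ever reach the platform zone (zone 0)?
2. **Initial directionality** (effective trials) - did the animal reach the
   peripheral platform zone (zone 1, or zone 0 directly) before committing
   its first *trajectory change*?
3. **Precision** - the ordinal band of the number of trajectory changes
   committed before reaching the platform zone: direct A (0), B (1-3),
   C (4-6), D (>=7); indirect E (1-3), F (4-6), G (>=7).

Ineffective trials split into J (thigmotaxis: search confined to the outer
zone 4), H (localized: search confined to at most three contiguous
octants), and I (nonlocalized: everything else).

A *trajectory change* is a discrete mistake episode: a curved movement with
more than 90 degrees of angulation, a nonsense movement (zigzag or spiral),
or peripheral seeking (crossing more than three contiguous octants while in
zone 3, or more than one octant while in zone 4).  Each maximal qualifying
episode counts as one change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin

from .geometry import PoolConfig, zone_of, octant_of
from .tracks import Trajectory, HeadingSeries, resample, smooth, headings

__all__ = [
    "ChangeEvent",
    "ClassifierParams",
    "SSALabel",
    "SearchStrategyClassifier",
    "detect_curves",
    "detect_nonsense",
    "detect_peripheral",
    "merge_events",
    "classify",
    "CATEGORIES",
]

CATEGORIES = tuple("ABCDEFGHIJ")

#: guard against float round-off on strict angle thresholds: a cumulative
#: turn must exceed the threshold by more than this to qualify.
_ANGLE_EPS = 1e-6


@dataclass(frozen=True)
class ChangeEvent:
    """One detected trajectory change.

    ``magnitude`` is the cumulative signed turn in degrees for curves and
    spirals, the total absolute turn for zigzags, and the octant count for
    peripheral seeking.
    """

    kind: str  # "curve" | "nonsense" | "peripheral"
    start_time: float
    end_time: float
    start_index: int
    end_index: int
    magnitude: float
    subkind: str = ""  # "zigzag" | "spiral" for nonsense events

    def overlaps(self, other: "ChangeEvent") -> bool:
        return self.start_time < other.end_time and other.start_time < self.end_time


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable thresholds of the strategy classifier.

    The curve threshold (90 deg, strict), the peripheral octant limits
    (3 in zone 3, 1 in zone 4), and the precision bands are the defining
    constants of the method.  The zigzag/spiral operationalizations
    (``zig_angle``/``zig_count``/``spiral_total``), the preprocessing
    constants, the small-wobble bridge, and the thigmotaxis tolerance are
    package decisions, exposed here precisely because the method defines
    nonsense movements only by name and sketch.
    """

    curve_angle: float = 90.0  # deg, strict ">"
    zig_angle: float = 45.0  # deg, per alternating bend, ">="
    zig_count: int = 3  # minimum consecutive alternating bends
    spiral_total: float = 360.0  # deg, strict ">"
    z3_octants: int = 3  # peripheral limit while in zone 3, strict ">"
    z4_octants: int = 1  # peripheral limit while in zone 4, strict ">"
    thigmotaxis_tol: float = 0.05  # fraction of samples allowed outside zone 4 for J
    dt: float = 0.1  # s, resampling step
    smooth_window: int = 5  # samples, centered moving average
    min_step: float = 2.0  # cm, jitter-merging step for headings
    straight_tol: float = 2.5  # deg, |turn| below this is "straight"
    bridge_tol: float = 20.0  # deg, opposite-sign wobbles smaller than this
    #   between two same-direction bends are absorbed into the enclosing bend

    @classmethod
    def from_file(cls, path) -> "ClassifierParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown classifier parameter(s): {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class SSALabel:
    """The strategy category of one trial with its three parameters."""

    category: str  # A..J
    effective: bool
    directionality: str  # "direct" | "indirect" | "not-applicable"
    n_changes: int  # trajectory changes up to first platform-zone entry
    #   (effective trials) or over the whole trial (ineffective trials)
    events: tuple = field(default_factory=tuple)  # ordered ChangeEvents


# ---------------------------------------------------------------------------
# bend extraction

@dataclass(frozen=True)
class _Bend:
    """A maximal same-sign run of turns: one sustained change of direction."""

    sign: int
    total: float  # signed cumulative turn, deg
    first: int  # first vertex index (into HeadingSeries.turn)
    last: int  # last vertex index

    @property
    def magnitude(self) -> float:
        return abs(self.total)


def _bends(h: HeadingSeries, straight_tol: float, bridge_tol: float = 0.0) -> List[_Bend]:
    """Split the turn sequence into maximal same-sign bends.

    Turns with magnitude <= ``straight_tol`` are straight travel: they end
    the current bend (two same-direction arcs separated by a straight stretch
    are two separate changes) but carry no sign of their own.  If
    ``bridge_tol`` > 0, an opposite-sign bend smaller than it that sits
    *immediately* between two same-sign bends (no straight gap) is treated as
    tracking wobble and merged into the surrounding bend.
    """
    turns = h.turn
    signs = np.where(np.abs(turns) <= straight_tol, 0, np.sign(turns)).astype(int)
    bends: List[_Bend] = []
    i = 0
    n = turns.size
    while i < n:
        s = signs[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and signs[j + 1] == s:
            j += 1
        bends.append(_Bend(int(s), float(turns[i : j + 1].sum()), i, j))
        i = j + 1
    if bridge_tol <= 0 or len(bends) < 3:
        return bends
    # absorb small immediately-adjacent opposite-sign wobbles
    merged: List[_Bend] = []
    k = 0
    while k < len(bends):
        b = bends[k]
        while (
            k + 2 < len(bends)
            and bends[k + 1].magnitude < bridge_tol
            and bends[k + 1].sign == -b.sign
            and bends[k + 2].sign == b.sign
            and bends[k + 1].first == b.last + 1  # immediately adjacent,
            and bends[k + 2].first == bends[k + 1].last + 1  # no straight gap
        ):
            b = _Bend(b.sign, b.total + bends[k + 1].total + bends[k + 2].total, b.first, bends[k + 2].last)
            k += 2
        merged.append(b)
        k += 1
    return merged


def _bend_event(h: HeadingSeries, first: int, last: int, kind: str, magnitude: float, subkind: str = "") -> ChangeEvent:
    # vertex v lies at retained point v + 1; the episode spans the retained
    # point entering the first vertex through the one leaving the last.
    i0, i1 = first, last + 2
    return ChangeEvent(
        kind=kind,
        start_time=float(h.point_t[i0]),
        end_time=float(h.point_t[i1]),
        start_index=int(h.point_index[i0]),
        end_index=int(h.point_index[i1]),
        magnitude=magnitude,
        subkind=subkind,
    )


# ---------------------------------------------------------------------------
# detectors

def detect_curves(
    h: HeadingSeries,
    angle_threshold: float = 90.0,
    straight_tol: float = 0.5,
    bridge_tol: float = 0.0,
) -> List[ChangeEvent]:
    """Curved movements: maximal same-sign runs whose cumulative turn
    strictly exceeds ``angle_threshold`` degrees.

    A run interrupted by a sign flip restarts accumulation (alternating
    runs are candidates for nonsense detection instead).  Spiral-sized runs
    are also returned here; :func:`merge_events` subsumes them under the
    nonsense event they belong to.
    """
    out = []
    for b in _bends(h, straight_tol, bridge_tol):
        if b.magnitude > angle_threshold + _ANGLE_EPS:
            out.append(_bend_event(h, b.first, b.last, "curve", b.total))
    return out


def detect_nonsense(
    h: HeadingSeries,
    zig_angle: float = 45.0,
    zig_count: int = 3,
    spiral_total: float = 360.0,
    straight_tol: float = 0.5,
    bridge_tol: float = 0.0,
) -> List[ChangeEvent]:
    """Nonsense movements: zigzags and spirals.

    A *spiral* is a single sustained bend with cumulative turn strictly
    beyond ``spiral_total`` degrees (it subsumes the curve event the same
    run would otherwise yield).  A *zigzag* is a maximal run of at least
    ``zig_count`` consecutive sign-alternating bends, each of magnitude at
    least ``zig_angle`` degrees; straight stretches between the alternating
    bends (zigzag legs) do not break the run, but any sub-threshold bend
    does.  Each maximal run yields exactly one event.
    """
    bends = _bends(h, straight_tol, bridge_tol)
    events: List[ChangeEvent] = []
    is_spiral = [b.magnitude > spiral_total + _ANGLE_EPS for b in bends]
    for b, sp in zip(bends, is_spiral):
        if sp:
            events.append(_bend_event(h, b.first, b.last, "nonsense", b.total, "spiral"))
    eligible = [
        (not sp) and b.magnitude >= zig_angle - _ANGLE_EPS for b, sp in zip(bends, is_spiral)
    ]
    i = 0
    while i < len(bends):
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(bends) and eligible[j + 1] and bends[j + 1].sign == -bends[j].sign:
            j += 1
        if j - i + 1 >= zig_count:
            total_abs = float(sum(b.magnitude for b in bends[i : j + 1]))
            events.append(_bend_event(h, bends[i].first, bends[j].last, "nonsense", total_abs, "zigzag"))
        i = j + 1
    events.sort(key=lambda e: (e.start_time, e.end_time))
    return events


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop is exclusive."""
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    return zip(np.where(padded == 1)[0], np.where(padded == -1)[0])


def detect_peripheral(
    traj: Trajectory,
    cfg: PoolConfig,
    z3_octants: int = 3,
    z4_octants: int = 1,
) -> List[ChangeEvent]:
    """Peripheral seeking episodes.

    From the per-sample (zone, octant) sequence, a peripheral event is a
    maximal contiguous episode during which the animal, while remaining in
    zone 3, traverses more than ``z3_octants`` distinct (necessarily
    contiguous, by path continuity) octants - or, while in zone 4, more than
    ``z4_octants``.  Remaining within the starting octant counts as one
    octant traversed.
    """
    z = np.asarray(zone_of(traj.x, traj.y, cfg))
    o = np.asarray(octant_of(traj.x, traj.y, cfg))
    events = []
    for zone_id, limit in ((3, z3_octants), (4, z4_octants)):
        for s, e in _runs(z == zone_id):
            n_oct = np.unique(o[s:e]).size
            if n_oct > limit:
                events.append(
                    ChangeEvent(
                        kind="peripheral",
                        start_time=float(traj.t[s]),
                        end_time=float(traj.t[e - 1]),
                        start_index=int(s),
                        end_index=int(e - 1),
                        magnitude=float(n_oct),
                    )
                )
    events.sort(key=lambda e: (e.start_time, e.end_time))
    return events


def merge_events(
    curves: Sequence[ChangeEvent],
    nonsense: Sequence[ChangeEvent],
    peripheral: Sequence[ChangeEvent],
) -> List[ChangeEvent]:
    """Combine the three detectors' outputs into the trial's ordered
    trajectory-change sequence.

    A curve overlapping a nonsense event is subsumed by it (a spiral already
    contains its own >90-degree run, and the bends of a zigzag are part of
    the zigzag, not separate mistakes).  Peripheral events live on a
    different substrate (zone occupancy, not turning) and are kept
    separately.
    """
    kept = [c for c in curves if not any(c.overlaps(nz) for nz in nonsense)]
    out = list(kept) + list(nonsense) + list(peripheral)
    out.sort(key=lambda e: (e.start_time, e.end_time))
    return out


# ---------------------------------------------------------------------------
# classification

def _contiguous_octants(occupied: np.ndarray, max_count: int = 3) -> bool:
    """True if the occupied octant set has <= max_count members forming a
    contiguous arc (wraparound allowed)."""
    occ = set(int(v) for v in occupied)
    if len(occ) > max_count:
        return False
    for shift in range(8):
        window = {(shift + k) % 8 for k in range(max_count)}
        if occ <= window:
            return True
    return False


def _precision_band(n: int, direct: bool) -> str:
    if direct:
        if n == 0:
            return "A"
        if n <= 3:
            return "B"
        if n <= 6:
            return "C"
        return "D"
    if n <= 3:
        return "E"
    if n <= 6:
        return "F"
    return "G"


def classify(traj: Trajectory, cfg: Optional[PoolConfig] = None, params: Optional[ClassifierParams] = None) -> SSALabel:
    """Label one trial with its search-strategy category A-J.

    Every valid trajectory receives exactly one label.  For effective trials
    only the portion up to the first platform-zone entry is examined, so
    whatever happens after arrival cannot change the label.
    """
    cfg = cfg or PoolConfig()
    params = params or ClassifierParams()
    traj.validate_in_pool(cfg)

    r = resample(traj, params.dt) if traj.duration > params.dt else traj
    zones = np.asarray(zone_of(r.x, r.y, cfg))
    effective = bool((zones == 0).any())

    if effective:
        cut = int(np.argmax(zones == 0))
        ev_traj = r.sliced(cut + 1) if cut >= 1 else None
    else:
        ev_traj = r

    events: List[ChangeEvent] = []
    if ev_traj is not None and ev_traj.n >= 2:
        window = min(params.smooth_window, ev_traj.n)
        if window % 2 == 0:
            window -= 1
        s = smooth(ev_traj, max(window, 1))
        h = headings(s, params.min_step)
        curves = detect_curves(h, params.curve_angle, params.straight_tol, params.bridge_tol)
        nonsense = detect_nonsense(
            h, params.zig_angle, params.zig_count, params.spiral_total, params.straight_tol, params.bridge_tol
        )
        peripheral = detect_peripheral(ev_traj, cfg, params.z3_octants, params.z4_octants)
        events = merge_events(curves, nonsense, peripheral)

    n_changes = len(events)

    if not effective:
        frac_z4 = float(np.mean(zones == 4))
        if frac_z4 >= 1.0 - params.thigmotaxis_tol:
            category = "J"
        else:
            octants = np.asarray(octant_of(r.x, r.y, cfg))
            category = "H" if _contiguous_octants(octants) else "I"
        return SSALabel(category, False, "not-applicable", n_changes, tuple(events))

    # directionality: arrival at zone 1 (or zone 0 directly) must not come
    # after the start of the first trajectory change
    arrive_idx = int(np.argmax(zones <= 1))
    t_arrive = float(r.t[arrive_idx])
    direct = (not events) or t_arrive <= events[0].start_time
    if not direct and n_changes == 0:  # defensive; indirect implies >= 1 change
        direct = True
    category = _precision_band(n_changes, direct)
    return SSALabel(category, True, "direct" if direct else "indirect", n_changes, tuple(events))


# ---------------------------------------------------------------------------
# sklearn estimator

class SearchStrategyClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based search-strategy classifier with the sklearn estimator API.

    ``X`` is a sequence of :class:`~watermaze.tracks.Trajectory`; ``predict``
    returns the category letters A-J.  The classifier learns nothing from
    data - ``fit`` only resolves and freezes the pool geometry - but the
    estimator interface lets it ride inside sklearn pipelines, be cloned,
    and have its thresholds grid-searched against a reference rater.

    Parameters mirror :class:`ClassifierParams`; see there for meaning and
    defaults.
    """

    def __init__(
        self,
        pool: Optional[PoolConfig] = None,
        curve_angle: float = 90.0,
        zig_angle: float = 45.0,
        zig_count: int = 3,
        spiral_total: float = 360.0,
        z3_octants: int = 3,
        z4_octants: int = 1,
        thigmotaxis_tol: float = 0.05,
        dt: float = 0.1,
        smooth_window: int = 5,
        min_step: float = 2.0,
        straight_tol: float = 2.5,
        bridge_tol: float = 20.0,
    ):
        self.pool = pool
        self.curve_angle = curve_angle
        self.zig_angle = zig_angle
        self.zig_count = zig_count
        self.spiral_total = spiral_total
        self.z3_octants = z3_octants
        self.z4_octants = z4_octants
        self.thigmotaxis_tol = thigmotaxis_tol
        self.dt = dt
        self.smooth_window = smooth_window
        self.min_step = min_step
        self.straight_tol = straight_tol
        self.bridge_tol = bridge_tol

    def _params(self) -> ClassifierParams:
        names = set(ClassifierParams.__dataclass_fields__)
        return ClassifierParams(**{k: getattr(self, k) for k in names})

    def fit(self, X=None, y=None):
        """Freeze the pool geometry and parameter set; y is ignored."""
        self.pool_ = self.pool if self.pool is not None else PoolConfig()
        self.params_ = self._params()
        self.classes_ = np.asarray(CATEGORIES)
        return self

    def _check_fitted(self):
        if not hasattr(self, "pool_"):
            self.fit()

    def predict_detail(self, X: Iterable[Trajectory]) -> List[SSALabel]:
        """Full :class:`SSALabel` (category, parameters, events) per trial."""
        self._check_fitted()
        return [classify(traj, self.pool_, self.params_) for traj in X]

    def predict(self, X: Iterable[Trajectory]) -> np.ndarray:
        """Category letter A-J per trial."""
        return np.asarray([lab.category for lab in self.predict_detail(X)], dtype=object)

    def score(self, X, y):
        """Agreement rate with reference labels ``y`` (category letters)."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))
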