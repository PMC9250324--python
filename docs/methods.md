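# Methods

This note records how the package operationalizes the search-strategy
algorithm (SSA), the choices made where the method is defined only
qualitatively, what the synthetic generator does and does not emulate, and
the numerical conventions.

## Pool geometry

Coordinates are pool-centered Cartesian centimeters, +y = north, bearings
clockwise from north. `north_reference` rotates the whole compass frame so
tracks from arbitrarily oriented cameras can be mapped in; every geometry
query and the classifier are exactly equivariant under rotating points and
frame together (tested).

The maze is divided into eight half-open 45° octants (octant 0 centered on
N, counted clockwise) and five zones. The zone diameters are given by the
protocol (platform 15 cm, zone 1 = 75, zone 2 = 90, zone 3 = 150, zone 4 =
180 cm) but not their centers; a 75 cm disc concentric with the pool could
not contain a platform whose center sits 45 cm off-center, so **zones 0–1
are centered on the platform** ("platform zone", "peripheral platform
zone") **and zones 2–4 on the pool**. Zones overlap geometrically;
membership uses the precedence 0 > 1 > 2 > 3 > 4, which makes the zones a
partition (required by the metrics). Boundary circles belong to the more
specific zone — in particular a sample exactly on the platform edge counts
as having reached the platform. Points up to 2 cm outside the nominal wall
are tolerated (tracking jitter); anything further is rejected as a corrupt
track.

"Halfway between the wall and the center" is read as a 45 cm radial offset
of the platform *center*; the protocol does not say whether it refers to
the center or the edge.

## Preprocessing

Tracks are linearly resampled to a uniform 0.1 s grid (gaps from dropped
samples up to 1 s are interpolated across; longer gaps void the trial),
smoothed with a centered 5-sample moving average (odd-reflection padding,
so straight ends stay straight), and reduced to a heading series after
merging samples closer than `min_step` = 2 cm so jitter-dominated
micro-steps cannot manufacture angulation. Zone and octant sequences are
computed from the *unsmoothed* resampled track; smoothing only feeds the
turning-angle analysis. Mean swim speed also uses the unsmoothed track
(smoothing shortens paths). None of these constants comes from the
protocol — human raters scored video — and all are configuration.

## Trajectory-change detection

The turn sequence is segmented into **bends**: maximal runs of same-sign
turns. Turns below `straight_tol` = 2.5° count as straight travel and end
a bend (two same-direction arcs separated by straight swimming are two
separate changes); an opposite-sign wobble smaller than `bridge_tol` = 20°
sitting immediately between two same-direction bends is absorbed into them
(tracking-noise hysteresis). Both tolerances are package decisions: 2.5°
per ~2 cm step corresponds to a curvature radius of ~45 cm, gentler than
anything a rater would call a turning mistake, and the pair was chosen by
measuring ground-truth label recovery on noisy synthetic tracks (see
below) — noise-free behavior is unaffected.

* **Curve**: a bend whose cumulative turn strictly exceeds 90°
  (the defining threshold; float guard 10⁻⁶).
* **Spiral** (nonsense): a bend beyond a full 360° circle; it subsumes the
  curve event the same run would otherwise yield.
* **Zigzag** (nonsense): at least `zig_count` = 3 consecutive alternating
  bends, each of magnitude ≥ `zig_angle` = 45°. Straight legs between the
  alternating bends do not break the run (zigzags have legs); any sub-45°
  bend does. One maximal run is one event.
* **Peripheral seeking**: on the per-sample (zone, octant) sequence, a
  maximal episode spent in zone 3 visiting more than 3 distinct octants,
  or in zone 4 visiting more than 1. Path continuity makes the visited
  octants contiguous; remaining in the start octant counts as one octant.

The zigzag/spiral internals are package decisions — the method defines
nonsense movements only by name and sketch — and are exposed as
parameters. Where a curve overlaps a nonsense event it is subsumed by it;
peripheral events live on a different substrate and are kept separately.

## Classification

For effective trials (any sample in zone 0), everything after the first
platform-zone sample is discarded before event detection, so nothing after
arrival can affect the label. Directionality is **direct** iff the first
entry into zone 1 *or* zone 0 does not come after the start of the first
trajectory change (a trial with no changes is direct). Precision counts
all changes up to the first zone-0 entry and maps them through the A–G
bands. Ineffective trials are **J** if at least 95% of samples lie in
zone 4 (`thigmotaxis_tol` = 0.05: raters judge "limited to the periphery"
holistically, and brief wall departures should not demote a thigmotactic
trial), else **H** if the occupied octant set has at most three members
forming a contiguous arc (wraparound allowed; a 2-octant search is also
localized), else **I**. Every valid trajectory receives exactly one label.

The classifier is exposed as a scikit-learn estimator
(`SearchStrategyClassifier`): `fit` only freezes the pool geometry and
thresholds (nothing is learned), which makes the rule set cloneable,
pipeline-compatible, and grid-searchable against a reference rater.

## Traditional measures

Latency and distance run to the *first entry* into zone 0 (a configurable
minimum dwell, default 0 s, supports platform-mount criteria); unfound
platforms censor latency at the trial duration and distance at the full
path length. Quadrant time assigns each sample interval to the quadrant of
its midpoint. Platform crossings count entry transitions into zone 0,
with a start inside the zone counting once. Probe trials reuse the zone-0
disc even though the platform is physically absent.

## Synthetic trajectories

The generator builds constant-speed polylines from motion primitives so
that the trajectory-change count, directionality, and category are fixed
**by construction** — ground truth never comes from running the
classifier. Counted changes are inserted as motifs (a −300° loop for a
curve; a 420° loop for a spiral; a buffered ±50° alternating triple folded
inside sub-90° arc blocks for a zigzag; a wall-following pass across two
octant boundaries for peripheral seeking), chained around ring sites on
the far side of the pool. All steering uses vertex turns of at most 40°
(below the 45° zigzag bend and far below the 90° curve threshold),
separated by 19 cm straight gaps — measured to be longer than the worst
distance (~16.5 cm, at 19 cm/s) at which resampling + smoothing can fuse
two turns into one run. Every generated polyline is audited by an
independent run-scan of its exact turn sequence and zone/octant occupancy;
layouts are retried over ring phases and motif orders, and a genuinely
infeasible spec raises an error naming the constraint.

Generator conditions: 90 s trials sampled at 0.1 s; release points rotate
among three pseudo-random wall positions (S, SW, W octants); cohorts of 8
rats × 10 acquisition days × 4 trials; per-day category mixtures follow
the typical progression qualitatively (young animals drift from
ineffective through indirect to direct, precise strategies by day 10; aged
animals progress more slowly and plateau in the indirect range); swim
speeds young ≈ N(20.5, 3.5) and aged ≈ N(19.3, 2.0) cm/s clipped to
[16, 26], consistent with reported group medians of ~20 cm/s.

Two generator limitations are deliberate: at most one peripheral change
per trial, realized for indirect archetypes as the trial-opening wall pass
(a mid-trial wall excursion cannot be steered reliably without creating
spurious turning events); direct archetypes realize their counts with
turning-type changes only. The detectors themselves are exercised on
directly constructed annulus paths independent of the generator.

What the generator does **not** emulate: biomechanics (accelerations,
lag, wall contact), behavioral idiosyncrasy (it composes a small motif
vocabulary), occlusion dropouts, or real rater ambiguity. Passing the
recovery tests therefore shows that the classifier implements the decision
tree exactly and tolerates moderate tracking noise — not that it matches
human raters on real video.

Under Gaussian positional noise of 0.5 cm, ground-truth recovery measured
~89% over the generator's own spec distribution (errors are almost all
one-band neighbors from noise-split or noise-merged turning runs); the
regression test asserts a conservative ≥ 75% floor. Noise-free recovery
is 100% across the exhaustive grid and random-spec batteries.

## Statistics

Categories pool into direct (A–D), indirect (E–G), and non-effective
(H–J). Group comparisons use Pearson chi-square on the pooled 2×3 table
without continuity correction; empty categories are dropped with a warning
and the degrees of freedom adjusted. Cohen's kappa is computed on whatever
label alphabet the raters used (raw A–J or a single parameter); identical
vectors give exactly 1. Mann–Whitney U is two-sided with midranks;
Friedman requires complete blocks and uses Bonferroni-corrected pairwise
Wilcoxon signed-rank post-hocs (family = all pairwise day comparisons;
adjusted p = raw p × number of pairs, capped at 1). Normality screening
uses the Kolmogorov–Smirnov test with estimated moments (Lilliefors), the
default behavior of common statistics packages. All p-values are
asymptotic; the test suite cross-checks them against brute-force
permutation oracles at small n.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
at deliberately modest sizes — a 21-trajectory archetype grid, 100–500
random specs, cohorts of 320 trials, 10³ chi-square simulations, full
enumeration of the 8-vs-8 rank assignment — which keeps a complete run in
the tens of seconds while still exercising every branch of the method.
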