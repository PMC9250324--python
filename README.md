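# watermaze

Search-strategy classification and traditional measures for Morris water
maze (MWM) swim tracks.

The MWM is the standard assay of rodent spatial learning: an animal swims
in a circular pool (180 cm here) and must find a hidden escape platform
using distal cues. The classic read-outs — escape latency, path length,
correct-quadrant time, platform crossings — are noisy and confounded by
swimming ability, especially in aged animals. This package implements a
parameter-based **search-strategy algorithm (SSA)** that instead classifies
each trial's swim path into one of ten ordinal categories **A–J** from
three observable parameters:

1. **Effectiveness** — did the path reach the platform zone (zone 0)?
2. **Initial directionality** — did the animal reach the peripheral
   platform zone (zone 1) *before* committing its first trajectory change
   (direct) or after (indirect)?
3. **Precision** — the number of trajectory changes *n* committed before
   reaching the platform zone, banded as
   direct: A (*n* = 0), B (1–3), C (4–6), D (≥ 7);
   indirect: E (1–3), F (4–6), G (≥ 7).

Ineffective trials split into H (search confined to ≤ 3 contiguous
octants), I (non-localized search), and J (thigmotaxis: wall-hugging in
the outer zone). A *trajectory change* is a discrete mistake episode: a
curved movement with more than 90° of cumulative turning, a nonsense
movement (zigzag or spiral), or peripheral seeking (crossing more than
three contiguous octants in the intermediate zone 3, or more than one
octant in the outer zone 4).

The pool geometry follows the standard layout: eight 45° octants about
the compass axes, and five zones — zone 0 the 15 cm platform disc, zone 1
a 75 cm disc around the platform, zones 2–4 concentric annuli at 90, 150,
and 180 cm diameter.

The package provides:

* `watermaze.geometry` — pool/platform/zone/octant geometry and membership;
* `watermaze.tracks` — track-file reading, resampling, smoothing, heading
  and turning-angle extraction;
* `watermaze.metrics` — the traditional per-trial measures;
* `watermaze.strategy` — trajectory-change detectors and the A–J
  classifier, exposed both as functions and as a scikit-learn-style
  estimator (`SearchStrategyClassifier`);
* `watermaze.synthetic` — a trajectory generator that constructs swim
  paths with known ground-truth labels (the test bed for everything else);
* `watermaze.stats` — pooled-set chi-square, Cohen's kappa, Mann–Whitney
  U, Friedman + Bonferroni, KS normality, and summary tables;
* an `ssa` command line (`ssa classify`, `ssa simulate`, `ssa stats`).

## Worked example

```python
from watermaze import PoolConfig, SearchStrategyClassifier
from watermaze.metrics import trial_metrics
from watermaze.synthetic import ArchetypeSpec, generate_archetype

cfg = PoolConfig()                       # the standard 180 cm maze
traj, truth = generate_archetype(        # a synthetic indirect trial with
    ArchetypeSpec("E", n_curves=2, seed=7), cfg)   # two curve changes

clf = SearchStrategyClassifier(pool=cfg).fit()
label = clf.predict_detail([traj])[0]
print(label.category, label.directionality, label.n_changes)
for ev in label.events:
    print(f"  {ev.kind} {ev.start_time:.1f}-{ev.end_time:.1f} s "
          f"magnitude {ev.magnitude:.1f}")
m = trial_metrics(traj, cfg)
print(f"latency {m.platform_latency:.1f} s  distance "
      f"{m.platform_distance:.0f} cm  speed {m.mean_speed:.1f} cm/s")
```

prints

```
E indirect 2
  curve 3.3-5.6 s magnitude -300.0
  curve 6.9-9.1 s magnitude -298.1
latency 18.5 s  distance 370 cm  speed 20.0 cm/s
```

The trial is **E**: effective (it reached the platform) but indirect (both
counted curves — sustained ~300° turning episodes, negative = counter-
clockwise — were committed before the animal first reached the platform's
surround), with 2 changes placing it in the 1–3 precision band. The
traditional measures for the same trial follow: 18.5 s to the platform
over a 370 cm path at 20 cm/s.

The same pipeline runs from the shell on directories of delimited track
files (`t,x,y` per row, cm and seconds, pool-centered):

```sh
ssa simulate --cohort cohort.yaml --out tracks/ --seed 1
ssa classify --tracks tracks/ --out labels.csv --events events.csv
ssa stats    --labels labels.csv --out report/
```

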