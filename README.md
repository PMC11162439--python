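# flumetrack

Simulation, tracking and behavioural analysis of grouped fish swimming in a
laboratory flume.

## The problem

Social facilitation — an individual performing better in the presence of
conspecifics — is well studied in still water, but riverine fish live in
flow. Flume experiments that probe it expose groups of small rheophilic fish
(1, 2 or 6 individuals) to increasing mean flow velocities (10, 20, 35 cm/s)
in a 60 × 30 × 15 cm test section, film them from below and from the side,
and ask whether group size increases each fish's **explored area** (EA) and
**trajectory length** (TL), and whether flow velocity modulates that effect.
The raw videos of such studies are rarely redistributable, so this package
pairs the full analysis chain with a synthetic-data generator that emulates
the statistical structure of the recordings — making every downstream stage
testable against ground truth.

The chain, each stage usable on its own:

* **`flumetrack.sim`** — an agent-based model of schooling fish
  (refuge-seeking drift toward the downstream grid, side walls and bottom
  that grows with flow velocity; cohesion; short-range collision avoidance;
  a per-trial shared "temperament" factor; and a programmable group-size
  activity multiplier active only at or above 20 cm/s), plus a detector
  model producing per-frame bounding-box detections with misses,
  localisation noise, confidence scores and occlusion merging.
* **`flumetrack.calib`** — four-corner projective (homography) calibration
  from pixels to arena centimetres, and LED-based time alignment of the two
  camera streams.
* **`flumetrack.tracker`** — identity-preserving tracking on the horizontal
  plane: a constant-velocity Kalman filter per fish, with per-frame identity
  assignment by exhaustive enumeration of all injective detection-to-track
  maps (group size ≤ 6, so at most 6! = 720 bijections), choosing the map
  that minimises the total group acceleration
  `Σᵢ ‖dᵢ − 2pᵢ(t−1) + pᵢ(t−2)‖ / dt²`. Occluded fish share merged
  detections with inflated measurement noise or coast on the motion model.
  An evaluator scores identity preservation across occlusion events against
  ground truth.
* **`flumetrack.metrics`** — EA (fraction of the 1800 one-cm² grid cells
  visited, group-averaged), TL (group-averaged path length in metres),
  kernel-density space use P_H(x, y) and P_V(z) (the latter weighted so each
  experiment contributes equal mass), per-trial positional medians
  (x̃, ỹ, z̃), the 3-minute adaptation window and the 5-cm bottom filter.
* **`flumetrack.stats`** — the nonparametric battery: one-sided
  Jonckheere–Terpstra trend tests for group size (implemented from first
  principles with tie-corrected variance and a permutation mode),
  Kruskal–Wallis on positional medians, Friedman for the within-subject
  velocity factor, paired Wilcoxon post-hocs with Bonferroni correction;
  plus Videler's sustained-speed relation `U_ms[m/s] = 0.15 + 2.4·L[m]` and
  body-length speed conversion.
* **`flumetrack.pipeline`** — one-command orchestration with manifests,
  config hashing, byte-reproducible CSV outputs and a tracker-validation
  report.

## Worked example

```python
import flumetrack as ft

base = ft.SimConfig(fps=5.0, duration_s=90.0)          # desk-scale treatments
runs = ft.generate_cohort(base=base, seed=1)           # 20/10/10 trials x 3 velocities
m = ft.cohort_metrics(runs, skip_s=27.0)               # per-trial EA, TL, medians
battery = ft.run_battery(m)                            # the full test layout
report = ft.validate_tracker(seed=1, min_events=100, duration_s=120.0)
```

Output (seed 1):

```
120 treatment runs, 40 trials
                        EA   TL_m
group_size velocity
1          10.0      0.014  0.310
           20.0      0.014  0.305
           35.0      0.015  0.322
2          10.0      0.023  0.469
           20.0      0.029  0.573
           35.0      0.028  0.572
6          10.0      0.016  0.350
           20.0      0.040  0.785
           35.0      0.040  0.798
variable cluster  statistic  z_or_chi2      p
      EA 10 cm/s      301.5     1.3120 0.0948
    TL_m 10 cm/s      298.0     1.2225 0.1108
      EA 20 cm/s      409.0     4.0507 0.0000
    TL_m 20 cm/s      408.0     4.0240 0.0000
      EA 35 cm/s      401.5     3.8607 0.0001
    TL_m 35 cm/s      399.0     3.7948 0.0001
occlusion events: 843, identity accuracy: 93.1% (95% CI 91.2%-94.6%)
U_ms(5 cm) = 27.0 cm/s; 5 BL/s at 5.14 cm = 26.0 cm/s
```

Read this as the study design in miniature: group size has no significant
trend on exploration or activity at the non-challenging velocity (10 cm/s,
below the ~27 cm/s maximum sustained speed of a 5-cm fish), but strongly
significant increasing trends at the challenging velocities (20 and
35 cm/s) — the velocity-gated social facilitation the generator encodes.
The tracker resolves identities correctly in ~93% of occlusion events on
six-fish groups.

A CLI wraps the same functionality:

```bash
flumetrack simulate --n-fish 6 --velocity 20 --duration 60 --seed 1 --out truth.csv
flumetrack track --detections calibrated.csv --n-fish 6 --out tracks.csv
flumetrack stats --metrics metrics.csv --out results.csv
flumetrack run-all --seed 1 --out runs/demo
flumetrack validate-tracker --seed 1 --min-events 100
```

## Layout

```
src/flumetrack/    sim, calib, tracker, metrics, stats, pipeline, cli
tests/             unit + property tests, and test_acceptance.py
docs/methods.md    the model, its assumptions, parameters and limitations
scripts/acceptance.py
```
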