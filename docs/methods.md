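# Methods

This note documents the models and procedures implemented in `flumetrack`,
the parameters that matter, the choices made where the design was genuinely
open, and what the synthetic benchmarks do and do not demonstrate.

## The agent model (`flumetrack.sim`)

Field observations of small rheophilic fish in a flume constrain *what* the
data look like — space use concentrating near walls and bottom as velocity
rises, wide between-trial spread in activity, a group-size effect on
exploration that appears only under challenging flow — but not a generative
mechanism. The simulator is therefore a deliberately minimal discrete-time
model whose purpose is to give every downstream stage (calibration,
tracking, metrics, statistics) inputs with the right statistical structure
and a known ground truth.

Per frame, each fish's velocity `v` (cm/frame) updates as

```
v ← inertia·v + drift + cohesion·(centroid_others − p) + alignment·(v̄_others − v)
      + repulsion-kernel + jitter
p ← reflect(p + activity_eff · v)
```

with reflective walls on the 60 × 30 × 15 cm box. The terms:

* **drift** — constant acceleration toward the downstream end (+x), the
  nearest side wall (±y, at half weight) and the bottom (−z), all scaled by
  `velocity_cm_s / 35`. This encodes refuge seeking: boundary layers carry
  lower local velocities, so the incentive to hug boundaries grows with
  flow. It produces the two directional signatures the metrics suite
  checks: the longitudinal median x̃ moves downstream and the vertical
  median z̃ moves toward the bottom as velocity increases.
* **cohesion** (default 2·10⁻⁴ frame⁻²) — a weak spring toward the centroid
  of the other fish. At a 7-minute treatment this binds the group into a
  loose school; over the shorter windows used in the statistical
  calibration suites its effect on per-fish activity is negligible, which
  keeps the no-facilitation baseline group-size neutral (see below).
* **alignment** (default 0) — relaxation toward the neighbours' mean
  velocity. It is implemented and tunable but off by default: averaging
  velocities across fish mechanically *reduces* each fish's speed relative
  to a solitary fish, which would inject a spurious negative group-size
  effect into EA and TL under the null and bias the trend tests. With the
  default model, group structure comes from cohesion and the shared start.
* **repulsion** (default 0.05 frame⁻², radius 1.5 cm) — a soft-core
  collision-avoidance kernel, force `(1 − d/r)` along the separation below
  radius `r`. Real fish do not overlap; without this term simulated fish
  can coincide in the bottom-view projection, where two-dimensional
  identity assignment is ill-posed for any tracker.
* **jitter** (default s.d. 0.035 cm/frame) — isotropic Gaussian velocity
  noise; with inertia 0.9 this makes each fish an Ornstein–Uhlenbeck walker
  with ~10-frame velocity memory.
* **activity** — the step-length scale. The effective value is
  `activity · exp(activity_cv·Z_trial) · (1 + facilitation_gain·(n_fish−1))`,
  the last factor applied only at or above `facilitation_threshold_cm_s`
  (default 20 cm/s).

Two structural features deserve emphasis:

* **The shared trial factor** (`activity_cv`, default 0.45 log-s.d.). Wild
  fish and wild groups differ widely in baseline activity; published
  group-level coefficients of variation for EA and TL in this kind of assay
  are roughly 0.45–0.65. The factor is drawn once per trial and held fixed
  across the three consecutive velocity treatments, giving the
  repeated-measures correlation the Friedman test relies on. It is also
  statistically load-bearing: because it is shared by all fish of a trial,
  it dominates between-trial variance *equally* at every group size. Without
  it, group-averaged metrics would have systematically smaller variance in
  larger groups, and the rank tests — whose null calibration assumes
  exchangeability — would over-reject under the null.
* **The school start** — fish initialise clustered (3 cm spread) around a
  common random centroid. Initialising fish independently across the arena
  lets cohesion drag group members toward each other through fresh grid
  cells, creating a transient explored-area surplus for groups that a
  solitary fish cannot have; the clustered start removes this artifact.

`facilitation_gain` defaults to 0.25 (a 2.25× activity multiplier for six
fish at challenging velocities). The observable consequences — six-fish EA
and TL roughly 1.6–2× the single-fish values at 20 and 35 cm/s and no group
effect at 10 cm/s — sit inside the envelope reported for this assay, where
the group effect on exploration (≈2–3×) exceeds that on path length
(≈1.4×); a single multiplier cannot match both ends exactly, so the default
is a compromise within that range.

### The detector model

Each view projects the 3-D truth (bottom: x, y; side: x, z), merges fish
whose projected separation falls below `occlusion_radius_cm`
(single-linkage, merged detection at the cluster centroid), drops each
surviving detection independently with `p_miss`, adds Gaussian pixel noise
to centroids, and draws a Beta confidence score. Defaults: bottom view
radius 1.2 cm, miss rate 3%; side view radius 3.0 cm, miss rate 6% — the
side view merges far more readily because projecting along the flume width
collapses depth, which is why vertical data are analysed as detections
only, never tracked. Confidence values are simulation dressing: the tracker
uses them solely to prune surplus detections.

## Calibration (`flumetrack.calib`)

Pixel-to-arena mapping uses the unique projective homography sending the
four pixel corners of the visible arena rectangle to the rectangle corners,
solved by direct linear transform with the scale fixed (exact at the
corners; the test suite checks it against an independent SVD-based DLT and
a round-trip property at 10⁻⁶ cm). A homography rather than bilinear
interpolation because four point pairs determine it exactly and it models
camera perspective. Calibrated coordinates up to 0.5 cm outside the arena
are clamped to the boundary (small calibration error should not delete
data); farther outliers are excluded and counted. Camera streams are
aligned from LED onset frames by an integer frame shift.

## Tracking (`flumetrack.tracker`)

One constant-velocity Kalman filter per fish on (x, y, vx, vy), with
white-acceleration process noise of intensity `q` and measurement noise
s.d. `r`. Identity assignment per frame is *exhaustive*: all injective maps
from tracks to detections are enumerated (≤ 720 bijections at the six-fish
cap, via a precomputed permutation table) and the gate-feasible map of
maximal cardinality and minimal total group acceleration is chosen, where a
pairing's cost is the second-difference acceleration magnitude
`‖d − 2p(t−1) + p(t−2)‖/dt²` computed from the track's last two emitted
positions. Sum of Euclidean norms is the default aggregation (sum of
squares selectable); ties break on total squared innovation and then on the
canonical detection order, making the result independent of input row
order. Surplus detections are pruned before enumeration by lowest
confidence, then largest gate distance.

Occlusion handling: a track left unassigned attaches to any detection still
inside its Mahalanobis gate with 3× measurement noise (a merged detection
may thus update several tracks, each keeping its own velocity memory — this
is what lets the minimum-acceleration rule re-separate identities when the
merge ends); otherwise it coasts on the prediction. Tracks coasting beyond
`max_coast_frames` (default 25) re-acquire the nearest unclaimed detection
unconditionally, with the identity uncertainty logged.

Numerical choices worth recording:

* **Emission**: measured track positions are the raw assigned detection
  coordinates; the filter state serves prediction, gating and coasting.
  This makes the tracker exactly transparent on noise-free input (the
  posterior of a finite-`r` filter would not be) and keeps the emitted
  trajectory free of filter lag.
* **`q` = 2000 cm²/s³** by default. The simulated fish change velocity by
  hundreds of cm/s² between frames; a small `q` makes the filter
  over-confident, so genuine detections fall outside the gate and tracks
  coast away. The value is set, as in the original tracking procedure, to
  maximise performance through occlusions rather than from a physical
  noise model.
* **Wall-bounce rescue**: reflection reverses velocity instantaneously,
  which the constant-velocity model cannot anticipate; after assignment,
  leftover unassigned tracks are paired with leftover unclaimed detections
  by minimum total distance (ignoring the gate) instead of coasting out of
  the arena, with inflated noise on that update.
* **dt** is fixed at 1/fps; missing frames are handled by the per-frame
  predict loop (a frame with no detections simply coasts every track).

The identity evaluator defines an occlusion event as a maximal run of
frames in which ≥ 2 fish share a merged detection or any fish is
undetected; an event is correct iff the optimal track-to-truth position
matching on the first post-event frame equals the matching on the last
pre-event frame for every involved track — i.e. the tracker carried
identities *through* the event. Events truncated by the video boundaries
are unscorable and excluded; with zero events the accuracy is reported as
undefined, never as 0 or 1.

## Metrics (`flumetrack.metrics`)

* The arena grid is 60 × 30 half-open 1-cm² cells (1800 total); a position
  exactly on the far boundary belongs to the last cell. EA is the per-fish
  count of distinct visited cells over 1800, averaged (not unioned) over
  the group. Coasted positions count: they are the trajectory.
* TL sums Euclidean inter-frame steps per fish (converted to metres) and
  group-averages; only consecutive frames contribute, so removing frames
  (e.g. the bottom filter) breaks segments rather than bridging them —
  filtered TL can only be smaller.
* P_H and P_V are Gaussian KDEs evaluated at 1-cm cell centres and
  renormalised to unit mass over the arena. The evaluation bin is fixed at
  1 cm; the bandwidth is Silverman's rule by default and overridable
  (renormalisation over the arena was chosen over boundary reflection:
  simpler and exactly mass-preserving). For P_V each detection is weighted
  by the inverse of its experiment's detection count so every experiment
  contributes equal mass regardless of its occlusion losses.
* Per-trial medians x̃, ỹ (from tracks) and z̃ (from side detections) are
  computed from raw positions, not from the smoothed KDE marginals — for a
  symmetric kernel the two coincide asymptotically and raw medians are
  exactly reproducible. A trial without side data reports z̃ as missing and
  is excluded from vertical tests only.
* The analysis window drops the first 180 s of each 10-minute treatment
  (adaptation to the new velocity); the bottom filter removes every frame
  in which any side detection exceeds 5 cm above the bottom.

## Statistics (`flumetrack.stats`)

The Jonckheere–Terpstra statistic is the sum of pairwise Mann–Whitney
counts over ordered group pairs (ties counted half), with mean
`(N² − Σn_k²)/4` and the Hollander–Wolfe tie-corrected variance (which
reduces to `[N²(2N+3) − Σn_k²(2n_k+3)]/72` without ties); the one-sided p
for an increasing trend is the upper normal tail, and a permutation mode
(label reshuffling) is available for small samples. The direction —
increasing with group size — is part of the hypothesis and never inferred
from data. Kruskal–Wallis, Friedman (with tie correction) and the paired
Wilcoxon signed-rank test delegate to `scipy.stats` behind this module's
interface; Wilcoxon discards zero differences (classical policy, recorded
in the result metadata), reports W⁺ on mid-ranks of |d|, and is exact for
n ≤ 25 without ties. The battery layout: JT on EA and TL at each velocity;
Kruskal–Wallis on x̃, ỹ, z̃ at each velocity; Friedman on every variable
within each group-size cluster; Wilcoxon post-hocs with Bonferroni m = 3
only where the Friedman test is significant at α = 0.05. No correction is
applied across test families — only within post-hoc triples. Friedman
clusters with fewer than two complete blocks are skipped with a log entry.

Reference speeds: `videler_ums` implements the linear sustained-speed
relation `U_ms[m/s] = 0.15 + 2.4·L[m]` (27 cm/s at L = 5 cm, the boundary
between aerobic sustained and anaerobically fuelled prolonged swimming);
`bl_rate_to_speed` converts body lengths per second to cm/s (5 BL/s at
5.14 cm ≈ 26 cm/s).

## Benchmark problem sizes

The package's self-checks run at desk scale, chosen as follows:

* **Statistical calibration suites** use the full study design (20
  single-fish, 10 two-fish and 10 six-fish trials, each through 10/20/35
  cm/s) with 90-second treatments at 5 fps and a 27-second adaptation skip
  — 30% of the treatment, the same proportion as the full-scale 3 of 10
  minutes. Metrics for these suites are computed directly from simulated
  ground truth (the statistics operate on per-trial metrics; the tracker is
  benchmarked separately). Under the no-facilitation null the JT stage
  rejects at 5.9–6.7% across 300–500 replicate cohorts (nominal 5%); with
  the default gain the velocity-gated significance pattern (no trend at 10
  cm/s, significant EA and TL trends at 20 and 35 cm/s) appears in ~95% of
  replicate cohorts.
* **The tracker benchmark** uses six-fish groups at 20 cm/s in two-minute
  trials — the length of a typical manual-validation sample — with the
  default detector; a single trial yields ~800 occlusion events, and
  identity accuracy is 93–95% across seeds, above the 87% reference level
  for this class of tracker.
* **The perfect-input fixture** (zero noise, zero misses, no merging) uses
  a shallow 60 × 30 × 3 cm water column with stiff collision avoidance.
  Exact recovery is a property of the *regime*, not just the tracker: when
  fish can stack vertically, their bottom-view projections coincide and
  identity is unknowable from that view alone. Near-planar swimming — which
  is also how these fish actually distribute themselves, mostly within 5 cm
  of the bottom — is the regime in which two-dimensional tracking is well
  posed, and there the tracker reproduces ground truth to machine
  precision.

## What the synthetic benchmarks do not show

The generator reproduces the *statistical* structure of the recordings, not
their physics: there is no hydrodynamic flow field (velocity enters only as
a scalar behavioural covariate), no body shape or posture (occlusion is a
distance threshold, not a visibility computation), no rod-tapping
interventions, and detector errors are independent across frames whereas
real CNN misses cluster in time and space. Passing the suite therefore
demonstrates that the chain — calibration, identity assignment, metrics,
tests — is correct and well calibrated on data with known truth; it does
not validate the behavioural model against real fish. Tracker accuracy
measured here depends on the simulated occlusion regime and should be
re-estimated on real footage (by manual review of occlusion events) before
being quoted for any particular study. The identity-assignment enumeration
is exact but capped at six fish; larger groups need a combinatorial
(e.g. assignment-problem) formulation instead.
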