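"""Agent-based simulation of grouped fish in a flume test section.

The generator produces ground-truth 3-D trajectories of small rheophilic
fish (1, 2 or 6 individuals) holding station in an open-channel flow, plus
synthetic camera detections for a bottom and a side view.  It emulates the
statistical structure the downstream analysis assumes:

* a 60 x 30 x 15 cm test section with reflective walls;
* refuge seeking: drift toward the downstream end, the side walls and the
  bottom, all increasing with mean flow velocity (fish exploit the lower
  local velocities of boundary layers);
* schooling: cohesion toward the neighbour centroid and alignment with the
  neighbour mean heading;
* social facilitation: a group-size multiplier on swimming activity that is
  switched on only at or above a velocity threshold (default 20 cm/s) --
  groups move more than singletons, but only when the flow is challenging;
* an imperfect detector: independent misses, Gaussian pixel localisation
  noise, Beta-distributed confidence scores, and occlusion merging of fish
  whose projected separation falls below a view-specific radius (frequent
  in the side view, where projection along the flume width collapses depth).

Every source of randomness is derived from a single integer seed, so all
outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Behaviour",
    "SimConfig",
    "DetectorModel",
    "TruthTrajectorySet",
    "TrialRun",
    "simulate_trial",
    "render_detections",
    "generate_cohort",
    "DEFAULT_DESIGN",
    "VELOCITIES_CM_S",
]

#: treatment velocities applied consecutively to every group, cm/s
VELOCITIES_CM_S = (10.0, 20.0, 35.0)

#: trials per group size in the study design (20 singletons, 10 pairs, 10 six-fish groups)
DEFAULT_DESIGN = {1: 20, 2: 10, 6: 10}


@dataclass(frozen=True)
class Behaviour:
    """Per-frame behavioural rates of the agent model.

    Accelerations are in cm/frame^2, velocities in cm/frame.  The wall and
    bottom attractions are scaled by ``velocity_cm_s / 35`` at run time, so
    the values below are the rates at the highest treatment velocity.
    """

    wall_attraction: float = 0.0004    # downstream + lateral-wall drift, cm/frame^2
    bottom_attraction: float = 0.003   # downward drift, cm/frame^2
    cohesion: float = 0.0002           # spring rate toward neighbour centroid, 1/frame^2
    alignment: float = 0.0             # relaxation toward neighbour mean velocity, 1/frame
    repulsion: float = 0.05            # short-range collision avoidance, cm/frame^2
    repulsion_radius_cm: float = 1.5   # separation below which repulsion acts
    activity: float = 1.0              # dimensionless step-length scale
    jitter_sd: float = 0.035           # isotropic velocity noise, cm/frame
    inertia: float = 0.9               # velocity persistence per frame


@dataclass(frozen=True)
class SimConfig:
    """One simulated treatment run (a group at one flow velocity).

    ``activity_cv`` is the log-scale s.d. of a per-trial activity factor
    shared by every fish of the group: wild fish (and groups) differ widely
    in baseline activity, and this shared temperament is what dominates
    between-trial spread of activity measures in practice.  The cohort
    generator draws the factor once per trial and keeps it fixed across the
    three velocity treatments (the repeated-measures structure).
    """

    n_fish: int = 1
    velocity_cm_s: float = 10.0
    arena: tuple[float, float, float] = (60.0, 30.0, 15.0)
    fps: float = 50.0
    duration_s: float = 420.0
    body_length_cm: float = 5.14
    behaviour: Behaviour = field(default_factory=Behaviour)
    facilitation_gain: float = 0.25
    facilitation_threshold_cm_s: float = 20.0
    activity_cv: float = 0.45
    school_spread_cm: float = 3.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def activity_multiplier(self) -> float:
        """Group-size activity multiplier; unity below the velocity threshold."""
        if self.velocity_cm_s >= self.facilitation_threshold_cm_s:
            return 1.0 + self.facilitation_gain * (self.n_fish - 1)
        return 1.0


def _validate_config(config: SimConfig) -> None:
    scalars = {
        "velocity_cm_s": config.velocity_cm_s,
        "fps": config.fps,
        "duration_s": config.duration_s,
        "body_length_cm": config.body_length_cm,
        "facilitation_gain": config.facilitation_gain,
        "facilitation_threshold_cm_s": config.facilitation_threshold_cm_s,
        "activity_cv": config.activity_cv,
    }
    for name, val in scalars.items():
        if not math.isfinite(val):
            raise ValueError(f"SimConfig.{name} must be finite, got {val!r}")
    if config.n_fish < 1:
        raise ValueError(f"SimConfig.n_fish must be >= 1, got {config.n_fish}")
    if any(not math.isfinite(v) or v <= 0 for v in config.arena):
        raise ValueError(f"SimConfig.arena dimensions must be positive, got {config.arena}")
    b = config.behaviour
    for name in ("wall_attraction", "bottom_attraction", "cohesion", "alignment",
                 "repulsion", "repulsion_radius_cm", "activity", "jitter_sd", "inertia"):
        val = getattr(b, name)
        if not math.isfinite(val):
            raise ValueError(f"Behaviour.{name} must be finite, got {val!r}")
        if val < 0:
            raise ValueError(f"Behaviour.{name} must be >= 0, got {val!r}")
    if config.facilitation_gain < 0:
        raise ValueError("SimConfig.facilitation_gain must be >= 0")
    if config.activity_cv < 0:
        raise ValueError("SimConfig.activity_cv must be >= 0")
    if config.school_spread_cm < 0:
        raise ValueError("SimConfig.school_spread_cm must be >= 0")
    n_frames = config.fps * config.duration_s
    if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 1:
        raise ValueError(
            f"SimConfig.fps * duration_s must be a positive whole number of frames, got {n_frames}"
        )


@dataclass(frozen=True)
class TruthTrajectorySet:
    """Ground-truth positions of all fish in one treatment run.

    ``positions`` has shape (n_frames, n_fish, 3) in arena cm; frame t of
    fish i is ``positions[t, i]``.  There are no gaps: every fish has one
    record per frame.
    """

    positions: np.ndarray
    config: SimConfig

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        T, n, _ = self.positions.shape
        frames = np.repeat(np.arange(T), n)
        fish = np.tile(np.arange(n), T)
        flat = self.positions.reshape(T * n, 3)
        return pd.DataFrame(
            {"fish_id": fish, "frame": frames,
             "x_cm": flat[:, 0], "y_cm": flat[:, 1], "z_cm": flat[:, 2]}
        )


def _simulate_batch(configs: list[SimConfig]) -> list["TruthTrajectorySet"]:
    """Run the agent model for several same-shape trials in one loop.

    All configs must share n_fish, frame count, arena and fps; seeds,
    velocities and behaviour rates may differ per trial.  Each trial consumes
    its own RNG stream and all per-frame operations are elementwise across
    trials, so results are bitwise identical to running trials one at a time.
    """
    for cfg in configs:
        _validate_config(cfg)
    ref = configs[0]
    T, n = ref.n_frames, ref.n_fish
    L = np.asarray(ref.arena, dtype=float)
    for cfg in configs[1:]:
        if (cfg.n_frames, cfg.n_fish, tuple(cfg.arena)) != (T, n, tuple(ref.arena)):
            raise ValueError("batched trials must share frame count, group size and arena")
    B = len(configs)

    act = np.empty((B, 1, 1))
    drift = np.empty((B, 1, 3))
    lat = np.empty((B, 1))
    coh = np.empty((B, 1, 1))
    ali = np.empty((B, 1, 1))
    rep = np.empty((B, 1, 1))
    rep_r = np.empty((B, 1, 1))
    inertia = np.empty((B, 1, 1))
    p = np.empty((B, n, 3))
    jitter = np.empty((T, B, n, 3))
    for k, cfg in enumerate(configs):
        b = cfg.behaviour
        rng = np.random.default_rng(cfg.seed)
        vscale = cfg.velocity_cm_s / 35.0
        trial_factor = float(np.exp(cfg.activity_cv * rng.standard_normal())) \
            if cfg.activity_cv > 0 else 1.0
        act[k] = b.activity * trial_factor * cfg.activity_multiplier
        drift[k, 0] = (b.wall_attraction * vscale, 0.0, -b.bottom_attraction * vscale)
        lat[k] = 0.5 * b.wall_attraction * vscale
        coh[k], ali[k], inertia[k] = b.cohesion, b.alignment, b.inertia
        rep[k], rep_r[k] = b.repulsion, max(b.repulsion_radius_cm, 1e-12)
        # the group enters as a school: common centroid, clustered spread
        centre = rng.uniform(low=np.zeros(3), high=L)
        p[k] = np.clip(centre + rng.standard_normal((n, 3)) * cfg.school_spread_cm, 0.0, L)
        jitter[:, k] = rng.standard_normal((T, n, 3)) * b.jitter_sd

    pos = np.empty((T, B, n, 3))
    v = np.zeros((B, n, 3))
    half_y = L[1] / 2.0
    for t in range(T):
        a = jitter[t] + drift
        a[:, :, 1] += lat * np.sign(p[:, :, 1] - half_y)
        if n > 1:
            others_centroid = (p.sum(axis=1, keepdims=True) - p) / (n - 1)
            a += coh * (others_centroid - p)
            others_v = (v.sum(axis=1, keepdims=True) - v) / (n - 1)
            a += ali * (others_v - v)
            # soft-core collision avoidance between close neighbours
            sep = p[:, :, None, :] - p[:, None, :, :]
            dist = np.linalg.norm(sep, axis=-1)
            np.einsum("bii->bi", dist)[:] = np.inf
            # coincident fish give no repulsion direction; jitter separates them
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(dist > 0.0,
                             np.maximum(1.0 - dist / rep_r, 0.0) / dist, 0.0)
            a += rep * (w[..., None] * sep).sum(axis=2)
        v = inertia * v + a
        pnew = p + act * v
        # reflect off the arena walls (steps are far smaller than the box)
        folded = np.abs(pnew)
        folded = np.where(folded > L, 2.0 * L - folded, folded)
        flip = (pnew < 0.0) | (pnew > L)
        v = np.where(flip, -v, v)
        p = np.clip(folded, 0.0, L)
        pos[t] = p

    return [TruthTrajectorySet(positions=pos[:, k].copy(), config=cfg)
            for k, cfg in enumerate(configs)]


def simulate_trial(config: SimConfig) -> TruthTrajectorySet:
    """Run the discrete-time agent model for one treatment.

    Per frame each fish's velocity is updated with inertia, drift toward the
    downstream grid / nearest side wall / bottom (scaled by flow velocity),
    cohesion toward the centroid of its neighbours, alignment with their mean
    velocity and isotropic Gaussian jitter; the position step is the velocity
    scaled by ``activity * (1 + facilitation_gain*(n_fish-1))`` when the flow
    is at or above the facilitation threshold.  Boundaries are reflective.
    """
    return _simulate_batch([config])[0]


# ---------------------------------------------------------------------------
# detector model


@dataclass(frozen=True)
class DetectorModel:
    """Statistical model of a single-view object detector.

    Fish whose projected separation in a view falls below
    ``occlusion_radius_cm`` merge into one detection at the cluster centroid;
    each surviving detection is dropped independently with ``p_miss``;
    centroid pixels get isotropic Gaussian noise; the confidence score is a
    Beta(conf_alpha, conf_beta) draw (simulation dressing only).
    """

    p_miss: float = 0.03
    loc_noise_px: float = 1.0
    occlusion_radius_cm: float = 1.2
    conf_alpha: float = 8.0
    conf_beta: float = 2.0
    px_per_cm: float = 16.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_miss <= 1.0:
            raise ValueError(f"DetectorModel.p_miss must be in [0, 1], got {self.p_miss}")
        if self.occlusion_radius_cm < 0:
            raise ValueError("DetectorModel.occlusion_radius_cm must be >= 0")
        if self.loc_noise_px < 0:
            raise ValueError("DetectorModel.loc_noise_px must be >= 0")
        if self.px_per_cm <= 0:
            raise ValueError("DetectorModel.px_per_cm must be > 0")

    @classmethod
    def for_view(cls, view: str) -> "DetectorModel":
        """Default detector per view; the side view merges far more readily
        because projecting along the flume width collapses depth."""
        if view == "bottom":
            return cls()
        if view == "side":
            return cls(occlusion_radius_cm=3.0, p_miss=0.06, conf_alpha=6.0)
        raise ValueError(f"unknown view {view!r}; expected 'bottom' or 'side'")


_VIEW_AXES = {"bottom": (0, 1), "side": (0, 2)}


def _merge_clusters(pts: np.ndarray, radius: float) -> list[list[int]]:
    """Single-linkage clusters of points closer than ``radius`` (n is tiny)."""
    n = len(pts)
    if radius <= 0.0:
        return [[i] for i in range(n)]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    adj = d < radius
    seen = np.zeros(n, dtype=bool)
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, members = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            members.append(j)
            for k in np.nonzero(adj[j] & ~seen)[0]:
                seen[k] = True
                stack.append(int(k))
        clusters.append(sorted(members))
    return clusters


def render_detections(
    truth: TruthTrajectorySet,
    det: DetectorModel,
    view: str,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project ground truth through a detector model for one camera view.

    Returns ``(detections, correspondence)``: the detection table with
    columns ``frame, det_idx, cx_px, cy_px, w_px, h_px, conf`` and the
    ground-truth correspondence with ``frame, det_idx, fish_ids`` where
    ``fish_ids`` is a semicolon-joined list of the contributing fish.
    """
    if view not in _VIEW_AXES:
        raise ValueError(f"unknown view {view!r}; expected 'bottom' or 'side'")
    if truth.n_frames == 0 or truth.n_fish == 0:
        raise ValueError("truth trajectory set is empty")
    ax = _VIEW_AXES[view]
    proj = truth.positions[:, :, ax]  # (T, n, 2) in cm
    rng = np.random.default_rng(truth.config.seed + 1 if seed is None else seed)
    bl = truth.config.body_length_cm

    rows: list[tuple] = []
    corr: list[tuple] = []
    for t in range(truth.n_frames):
        clusters = _merge_clusters(proj[t], det.occlusion_radius_cm)
        det_idx = 0
        for members in clusters:
            if rng.random() < det.p_miss:
                continue
            pts = proj[t][members]
            centroid_px = pts.mean(axis=0) * det.px_per_cm
            centroid_px = centroid_px + rng.standard_normal(2) * det.loc_noise_px
            span = pts.max(axis=0) - pts.min(axis=0)
            w_px = (span[0] + 0.4 * bl) * det.px_per_cm
            h_px = (span[1] + 0.25 * bl) * det.px_per_cm
            conf = rng.beta(det.conf_alpha, det.conf_beta)
            rows.append((t, det_idx, centroid_px[0], centroid_px[1], w_px, h_px, conf))
            corr.append((t, det_idx, ";".join(str(m) for m in members)))
            det_idx += 1

    detections = pd.DataFrame(
        rows, columns=["frame", "det_idx", "cx_px", "cy_px", "w_px", "h_px", "conf"]
    )
    correspondence = pd.DataFrame(corr, columns=["frame", "det_idx", "fish_ids"])
    return detections, correspondence


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class TrialRun:
    """One treatment run of one trial (a group at one velocity)."""

    trial_id: int
    group_size: int
    velocity_cm_s: float
    truth: TruthTrajectorySet
    seed: int


def generate_cohort(
    design: dict[int, int] | None = None,
    base: SimConfig | None = None,
    seed: int = 0,
    velocities: tuple[float, ...] = VELOCITIES_CM_S,
) -> list[TrialRun]:
    """Simulate a full experimental campaign.

    ``design`` maps group size to trial count (default: 20 singleton, 10
    two-fish and 10 six-fish trials).  Each trial is run through all
    velocities in sequence, preserving the within-subject (repeated
    measures) structure; per-run seeds derive deterministically from
    ``seed`` via a SeedSequence spawn tree.
    """
    if design is None:
        design = dict(DEFAULT_DESIGN)
    if not design:
        raise ValueError("cohort design is empty")
    for gs, count in design.items():
        if count < 1:
            raise ValueError(f"trial count for group size {gs} must be >= 1, got {count}")
    if base is None:
        base = SimConfig()

    n_trials = sum(design.values())
    children = np.random.SeedSequence(seed).spawn(n_trials * (len(velocities) + 1))
    pending: list[tuple[int, int, float, int, SimConfig]] = []
    trial_id = 0
    k = 0
    for gs in sorted(design):
        for _ in range(design[gs]):
            # the per-trial activity factor (group temperament) persists
            # across the three consecutive velocity treatments
            trial_rng = np.random.default_rng(children[k])
            k += 1
            factor = float(np.exp(base.activity_cv * trial_rng.standard_normal())) \
                if base.activity_cv > 0 else 1.0
            beh = replace(base.behaviour, activity=base.behaviour.activity * factor)
            for vel in velocities:
                child_seed = int(children[k].generate_state(1)[0] % (2**31))
                k += 1
                cfg = replace(base, n_fish=gs, velocity_cm_s=vel, seed=child_seed,
                              behaviour=beh, activity_cv=0.0)
                pending.append((trial_id, gs, vel, child_seed, cfg))
            trial_id += 1

    # batch same-shape trials through one vectorised pass (identical results)
    truths: dict[int, TruthTrajectorySet] = {}
    groups: dict[tuple[int, float], list[int]] = {}
    for idx, (_, gs, vel, _, _) in enumerate(pending):
        groups.setdefault((gs, vel), []).append(idx)
    for idxs in groups.values():
        batch = _simulate_batch([pending[i][4] for i in idxs])
        for i, truth in zip(idxs, batch):
            truths[i] = truth

    return [
        TrialRun(trial_id=tid, group_size=gs, velocity_cm_s=vel,
                 truth=truths[i], seed=s)
        for i, (tid, gs, vel, s, _) in enumerate(pending)
    ]
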