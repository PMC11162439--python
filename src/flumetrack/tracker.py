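"""Identity-preserving tracking of fish from per-frame detections.

Trajectories are reconstructed on the horizontal plane only (the side view
suffers occlusions too frequent for tracking).  Each fish carries a
constant-velocity Kalman filter on (x, y, vx, vy).  Per frame the tracker
predicts all filters, then assigns detections to tracks by exhaustively
enumerating every injective assignment (group sizes are at most six, so at
most 6! = 720 bijections) and selecting the one minimising the total group
acceleration implied by the candidate detections: the cost of assigning
detection ``d`` to a track with last two confirmed positions ``p1, p2`` is
``||d - 2 p1 + p2|| / dt^2`` (a second-difference acceleration magnitude).
Identity swaps between crossing fish force a spurious acceleration, so the
minimum-acceleration assignment preserves identities through crossings.

Occlusion handling: a merged detection may update several gated tracks (the
surplus tracks attach with inflated measurement noise), and tracks with no
gated detection coast on the motion model.  Measured track positions are
emitted as the raw assigned detection coordinates; the filter state is used
for prediction, gating and coasting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrackerConfig",
    "KalmanTrack",
    "predict",
    "update",
    "assign_identities",
    "track_trial",
    "evaluate_identity_accuracy",
    "MAX_GROUP_SIZE",
]

#: enumeration bound: all injective assignments are enumerated, so group size is capped
MAX_GROUP_SIZE = 6

_PERM_TABLES: dict[int, np.ndarray] = {}


def _perm_table(n: int) -> np.ndarray:
    if n not in _PERM_TABLES:
        _PERM_TABLES[n] = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    return _PERM_TABLES[n]


@dataclass(frozen=True)
class TrackerConfig:
    """Tuning parameters of the Kalman/minimum-acceleration tracker.

    ``q`` is the white-acceleration process-noise intensity (cm^2/s^3), ``r``
    the measurement noise s.d. (cm), ``gate`` a Mahalanobis radius in
    innovation sigmas.  ``cost_norm`` selects how per-fish acceleration
    magnitudes aggregate ('l2' = sum of Euclidean norms, 'sq' = sum of
    squares).  Tie-breaking between equal-cost assignments: lowest total
    squared innovation, then lexicographic over the canonically ordered
    detections — deterministic and independent of input order.
    """

    dt: float = 1.0 / 50.0
    q: float = 2000.0
    r: float = 0.15
    gate: float = 8.0
    max_coast_frames: int = 25
    cost_norm: str = "l2"
    shared_r_inflation: float = 9.0
    init_speed_sd_cm_s: float = 10.0

    def __post_init__(self) -> None:
        if self.q <= 0 or self.r <= 0:
            raise ValueError("TrackerConfig.q and r must be > 0")
        if self.gate <= 0:
            raise ValueError("TrackerConfig.gate must be > 0")
        if self.cost_norm not in ("l2", "sq"):
            raise ValueError(f"unknown cost_norm {self.cost_norm!r}")


@dataclass
class KalmanTrack:
    """State of one fish: (x, y, vx, vy) in cm and cm/s."""

    fish_id: int
    x: np.ndarray                 # state mean, shape (4,)
    P: np.ndarray                 # state covariance, shape (4, 4)
    prev1: np.ndarray             # last confirmed (emitted) position, cm
    prev2: np.ndarray             # second-to-last confirmed position, cm
    status: str = "tracking"      # 'tracking' | 'coasting'
    coast_count: int = 0

    @property
    def position(self) -> np.ndarray:
        return self.x[:2]


_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


def _F(dt: float) -> np.ndarray:
    F = np.eye(4)
    F[0, 2] = F[1, 3] = dt
    return F


def _Q(dt: float, q: float) -> np.ndarray:
    # white-acceleration (continuous) process noise, per axis blocks
    q11 = q * dt**3 / 3.0
    q12 = q * dt**2 / 2.0
    q22 = q * dt
    Q = np.zeros((4, 4))
    Q[0, 0] = Q[1, 1] = q11
    Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = q12
    Q[2, 2] = Q[3, 3] = q22
    return Q


def new_track(fish_id: int, pos: np.ndarray, config: TrackerConfig) -> KalmanTrack:
    x = np.array([pos[0], pos[1], 0.0, 0.0])
    P = np.diag([config.r**2, config.r**2,
                 config.init_speed_sd_cm_s**2, config.init_speed_sd_cm_s**2])
    return KalmanTrack(fish_id=fish_id, x=x, P=P,
                       prev1=np.asarray(pos, dtype=float).copy(),
                       prev2=np.asarray(pos, dtype=float).copy())


def predict(track: KalmanTrack, dt: float, q: float) -> KalmanTrack:
    """Constant-velocity prediction with white-acceleration process noise."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    F = _F(dt)
    track.x = F @ track.x
    track.P = F @ track.P @ F.T + _Q(dt, q)
    return track


def update(track: KalmanTrack, z: np.ndarray, r: float) -> KalmanTrack:
    """Standard innovation-weighted Kalman correction with noise s.d. ``r``."""
    z = np.asarray(z, dtype=float)
    S = _H @ track.P @ _H.T + (r**2) * np.eye(2)
    K = track.P @ _H.T @ np.linalg.inv(S)
    innov = z - _H @ track.x
    track.x = track.x + K @ innov
    track.P = (np.eye(4) - K @ _H) @ track.P
    track.P = 0.5 * (track.P + track.P.T)  # keep symmetric
    return track


def _gate_distances(tracks: list[KalmanTrack], dets: np.ndarray, r: float) -> np.ndarray:
    """Squared Mahalanobis innovation distances, shape (n_tracks, n_dets)."""
    n, m = len(tracks), len(dets)
    d2 = np.empty((n, m))
    for i, trk in enumerate(tracks):
        S = _H @ trk.P @ _H.T + (r**2) * np.eye(2)
        Sinv = np.linalg.inv(S)
        innov = dets - trk.x[:2]
        d2[i] = np.einsum("kj,jl,kl->k", innov, Sinv, innov)
    return d2


def _canonical_order(dets: np.ndarray, conf: np.ndarray) -> np.ndarray:
    """Deterministic detection ordering (x, then y, then confidence)."""
    return np.lexsort((conf, dets[:, 1], dets[:, 0]))


def assign_identities(
    tracks: list[KalmanTrack],
    detections: np.ndarray,
    config: TrackerConfig,
    conf: np.ndarray | None = None,
) -> tuple[dict[int, int | None], float]:
    """Minimum-group-acceleration assignment of detections to tracks.

    Enumerates every injective map from tracks to detections (after pruning
    surplus detections by lowest confidence, then largest gate distance) and
    returns the gate-feasible map of maximal cardinality and minimal total
    acceleration cost.  Returns ``(assignment, cost)`` where ``assignment``
    maps track index to detection index in the input order (None = coast).
    """
    n = len(tracks)
    if n > MAX_GROUP_SIZE:
        raise ValueError(
            f"group size {n} exceeds the exhaustive-enumeration bound of {MAX_GROUP_SIZE}"
        )
    detections = np.asarray(detections, dtype=float).reshape(-1, 2)
    m = len(detections)
    if conf is None:
        conf = np.ones(m)
    if m == 0 or n == 0:
        return {i: None for i in range(n)}, 0.0

    order = _canonical_order(detections, conf)
    dets = detections[order]
    conf_o = np.asarray(conf, dtype=float)[order]

    d2 = _gate_distances(tracks, dets, config.r)

    keep = np.arange(len(dets))
    if m > n:
        # prune surplus: drop lowest confidence first, ties by largest gate distance
        drop_order = np.lexsort((-d2.min(axis=0), conf_o))
        keep = np.sort(drop_order[(m - n):])
        dets = dets[keep]
        conf_o = conf_o[keep]
        d2 = d2[:, keep]
    mm = len(dets)

    dt2 = config.dt**2
    # acceleration cost of pairing track i with detection j
    C = np.zeros((n, max(n, mm)))
    for i, trk in enumerate(tracks):
        accel = np.linalg.norm(dets - 2.0 * trk.prev1 + trk.prev2, axis=1) / dt2
        C[i, :mm] = accel if config.cost_norm == "l2" else accel**2
    in_gate = np.zeros((n, max(n, mm)), dtype=bool)
    in_gate[:, :mm] = d2 <= config.gate**2
    I2 = np.zeros((n, max(n, mm)))
    I2[:, :mm] = np.linalg.norm(dets - np.array([t.x[:2] for t in tracks])[:, None, :], axis=2) ** 2

    k = max(n, mm)
    perms = _perm_table(k)[:, :n] if k > n else _perm_table(n)
    rows = np.arange(n)
    valid = in_gate[rows, perms]                       # (P, n)
    card = valid.sum(axis=1)
    cost = np.where(valid, C[rows, perms], 0.0).sum(axis=1)
    tie = np.where(valid, I2[rows, perms], 0.0).sum(axis=1)
    # maximal cardinality, then minimal cost, then minimal squared innovation,
    # then lexicographically smallest permutation (perm table is lexicographic)
    best = np.lexsort((tie, cost, -card))[0]
    perm = perms[best]
    val = valid[best]

    assignment: dict[int, int | None] = {}
    for i in range(n):
        if val[i]:
            assignment[i] = int(order[keep[perm[i]]])
        else:
            assignment[i] = None
    return assignment, float(cost[best])


@dataclass
class _TrialLog:
    coasted_frames: int = 0
    shared_updates: int = 0
    reacquisitions: int = 0


def track_trial(
    detections: pd.DataFrame,
    n_fish: int,
    config: TrackerConfig | None = None,
) -> pd.DataFrame:
    """Reconstruct ``n_fish`` trajectories from calibrated bottom detections.

    ``detections`` needs columns ``frame, x_cm, y_cm`` (and optionally
    ``conf``).  Tracks initialise at the first frame carrying at least
    ``n_fish`` detections; thereafter each frame runs predict -> assign ->
    update/coast.  Unassigned tracks whose prediction still gates a detection
    attach to it with inflated measurement noise (occlusion sharing, flagged
    ``shared``); otherwise they coast on the motion model.  A track coasting
    longer than ``max_coast_frames`` re-acquires the nearest unclaimed
    detection unconditionally.

    Returns a frame-complete table ``fish_id, frame, x_cm, y_cm, source,
    shared`` with ``source`` in {'measured', 'coasted'}.
    """
    if config is None:
        config = TrackerConfig()
    if len(detections) == 0:
        raise ValueError("empty detection table")
    if n_fish < 1 or n_fish > MAX_GROUP_SIZE:
        raise ValueError(f"n_fish must be in 1..{MAX_GROUP_SIZE}, got {n_fish}")

    det = detections.sort_values("frame", kind="stable")
    if "conf" not in det.columns:
        det = det.assign(conf=1.0)
    frames = det["frame"].to_numpy()
    xy = det[["x_cm", "y_cm"]].to_numpy(dtype=float)
    confs = det["conf"].to_numpy(dtype=float)

    by_frame: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for f in np.unique(frames):
        sel = frames == f
        by_frame[int(f)] = (xy[sel], confs[sel])

    # initialisation: first frame with >= n_fish detections
    init_frame = None
    for f in sorted(by_frame):
        if len(by_frame[f][0]) >= n_fish:
            init_frame = f
            break
    if init_frame is None:
        raise ValueError(f"no frame carries {n_fish} detections; cannot initialise tracks")

    pts, cf = by_frame[init_frame]
    order = _canonical_order(pts, cf)
    if len(pts) > n_fish:  # prune surplus by lowest confidence
        keep = np.sort(np.argsort(cf)[len(pts) - n_fish:])
        pts, cf = pts[keep], cf[keep]
        order = _canonical_order(pts, cf)
    tracks = [new_track(i, pts[order[i]], config) for i in range(n_fish)]

    log = _TrialLog()
    records: list[tuple] = []
    for i, trk in enumerate(tracks):
        records.append((trk.fish_id, init_frame, trk.prev1[0], trk.prev1[1], "measured", False))

    last_frame = max(by_frame)
    for f in range(init_frame + 1, last_frame + 1):
        for trk in tracks:
            predict(trk, config.dt, config.q)
        pts, cf = by_frame.get(f, (np.empty((0, 2)), np.empty(0)))
        assignment, _ = assign_identities(tracks, pts, config, conf=cf)
        claimed = {j for j in assignment.values() if j is not None}

        # rescue: a gate can reject a true detection when the fish bounced
        # off a wall (instant velocity reversal).  Pair leftover unassigned
        # tracks with unclaimed detections by minimum total distance rather
        # than coasting a track out of the arena.
        unassigned = [i for i in range(len(tracks)) if assignment[i] is None]
        unclaimed = [j for j in range(len(pts)) if j not in claimed]
        rescued: set[int] = set()
        if unassigned and unclaimed:
            from scipy.optimize import linear_sum_assignment

            d = np.linalg.norm(
                np.array([tracks[i].x[:2] for i in unassigned])[:, None, :]
                - pts[unclaimed][None, :, :], axis=2)
            rows, cols = linear_sum_assignment(d)
            for ri, ci in zip(rows, cols):
                i, j = unassigned[ri], unclaimed[ci]
                assignment[i] = j
                claimed.add(j)
                rescued.add(i)

        for i, trk in enumerate(tracks):
            j = assignment[i]
            if j is not None:
                z = pts[j]
                # a rescued pairing is less certain: inflate its noise
                update(trk, z, config.r * (2.0 if i in rescued else 1.0))
                emit = z
                source, shared = "measured", False
                trk.status, trk.coast_count = "tracking", 0
            else:
                # occlusion sharing: attach to any still-gated detection with
                # inflated noise; otherwise coast on the prediction
                shared_j = None
                if len(pts):
                    d2 = _gate_distances([trk], pts, config.r)[0]
                    jj = int(np.argmin(d2))
                    if d2[jj] <= config.gate**2:
                        shared_j = jj
                if shared_j is not None:
                    update(trk, pts[shared_j], config.r * np.sqrt(config.shared_r_inflation))
                    emit = trk.x[:2].copy()
                    source, shared = "measured", True
                    trk.status, trk.coast_count = "tracking", 0
                    log.shared_updates += 1
                else:
                    emit = trk.x[:2].copy()
                    source, shared = "coasted", False
                    trk.status = "coasting"
                    trk.coast_count += 1
                    log.coasted_frames += 1
                    if trk.coast_count > config.max_coast_frames:
                        unclaimed = [jj for jj in range(len(pts)) if jj not in claimed]
                        if unclaimed:
                            dists = np.linalg.norm(pts[unclaimed] - trk.x[:2], axis=1)
                            jj = unclaimed[int(np.argmin(dists))]
                            claimed.add(jj)
                            trk.x[:2] = pts[jj]
                            trk.x[2:] = 0.0
                            trk.P = new_track(trk.fish_id, pts[jj], config).P
                            emit = pts[jj]
                            source, shared = "measured", False
                            trk.status, trk.coast_count = "tracking", 0
                            log.reacquisitions += 1
                            logger.info(
                                "track %d re-acquired a detection at frame %d after "
                                "prolonged coasting; identity uncertain", trk.fish_id, f,
                            )
            trk.prev2 = trk.prev1
            trk.prev1 = np.asarray(emit, dtype=float).copy()
            records.append((trk.fish_id, f, emit[0], emit[1], source, shared))

    out = pd.DataFrame(records, columns=["fish_id", "frame", "x_cm", "y_cm", "source", "shared"])
    logger.info("track_trial: %d coasted frames, %d shared updates, %d re-acquisitions",
                log.coasted_frames, log.shared_updates, log.reacquisitions)
    return out


# ---------------------------------------------------------------------------
# identity-accuracy evaluation against synthetic ground truth


def _occlusion_frames(correspondence: pd.DataFrame, n_fish: int,
                      frame_range: range) -> dict[int, set[int]]:
    """Map occlusion frame -> set of involved fish (merged or undetected)."""
    per_frame_fish: dict[int, list[set[int]]] = {}
    for f, grp in correspondence.groupby("frame"):
        per_frame_fish[int(f)] = [
            {int(s) for s in ids.split(";")} for ids in grp["fish_ids"]
        ]
    all_fish = set(range(n_fish))
    out: dict[int, set[int]] = {}
    for f in frame_range:
        clusters = per_frame_fish.get(f, [])
        involved: set[int] = set()
        for c in clusters:
            if len(c) >= 2:
                involved |= c
        detected = set().union(*clusters) if clusters else set()
        involved |= all_fish - detected
        if involved:
            out[f] = involved
    return out


def _match_tracks_to_truth(track_pos: np.ndarray, truth_pos: np.ndarray) -> np.ndarray:
    """Optimal distance matching track index -> truth fish index."""
    from scipy.optimize import linear_sum_assignment

    d = np.linalg.norm(track_pos[:, None, :] - truth_pos[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(d)
    out = np.empty(len(track_pos), dtype=int)
    out[rows] = cols
    return out


def align_to_truth(trajectories: pd.DataFrame, truth) -> pd.DataFrame:
    """Relabel track ids to ground-truth fish ids.

    Track labels are arbitrary (assigned in canonical detection order at
    initialisation); this matches tracks to truth by optimal position
    matching on the first output frame and renames ``fish_id`` accordingly.
    """
    first = int(trajectories["frame"].min())
    sub = trajectories.loc[trajectories["frame"] == first].sort_values("fish_id")
    mapping = _match_tracks_to_truth(
        sub[["x_cm", "y_cm"]].to_numpy(), truth.positions[first, :, :2])
    relabel = {int(tid): int(mapping[i]) for i, tid in enumerate(sub["fish_id"])}
    out = trajectories.copy()
    out["fish_id"] = out["fish_id"].map(relabel)
    return out


def evaluate_identity_accuracy(
    trajectories: pd.DataFrame,
    truth,
    correspondence: pd.DataFrame,
) -> tuple[float | None, int, int]:
    """Score identity preservation across occlusion events.

    An occlusion event is a maximal run of frames in which at least two fish
    share a merged detection or any fish is undetected.  An event is scored
    correct iff every involved track is matched (by optimal position matching
    against ground truth) to the same fish on the first post-event frame as
    on the last pre-event frame, i.e. the tracker carried identities through
    the occlusion.  Returns ``(accuracy or None, n_events, n_correct)``;
    accuracy is None (undefined) when no event occurred.
    """
    n_fish = truth.n_fish
    tracks_by_frame = {
        int(f): grp.sort_values("fish_id")[["x_cm", "y_cm"]].to_numpy()
        for f, grp in trajectories.groupby("frame")
    }
    first_frame = int(trajectories["frame"].min())
    last_frame = int(trajectories["frame"].max())

    truth_xy = truth.positions[:, :, :2]

    occ = _occlusion_frames(correspondence, n_fish, range(first_frame, last_frame + 1))
    occ_frames = sorted(occ)

    n_events = 0
    n_correct = 0
    i = 0
    while i < len(occ_frames):
        start = occ_frames[i]
        end = start
        involved = set(occ[start])
        while i + 1 < len(occ_frames) and occ_frames[i + 1] == end + 1:
            i += 1
            end = occ_frames[i]
            involved |= occ[end]
        i += 1
        pre = start - 1
        post = end + 1
        if pre < first_frame or post > last_frame or post >= truth.n_frames:
            continue  # event truncated by the video boundaries: unscorable
        before = _match_tracks_to_truth(tracks_by_frame[pre], truth_xy[pre])
        after = _match_tracks_to_truth(tracks_by_frame[post], truth_xy[post])
        n_events += 1
        involved_tracks = [t for t in range(n_fish) if before[t] in involved]
        if all(after[t] == before[t] for t in involved_tracks):
            n_correct += 1

    if n_events == 0:
        return None, 0, 0
    return n_correct / n_events, n_events, n_correct
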