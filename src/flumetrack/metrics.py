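"""Behavioural outcome measures of fish space use and activity.

Per trial and treatment the analysis computes:

* **EA** (explored area): for each fish, the number of distinct 1-cm^2 cells
  of the 60 x 30 horizontal grid containing at least one of its positions,
  divided by the 1800 available cells; EA is the unweighted mean of that
  fraction over the fish of the group.
* **TL** (trajectory length): the cumulative horizontal inter-frame distance
  of each fish in the stationary (ground) frame, in metres, group-averaged.
* **Space-use densities** P_H(x, y) and P_V(z): Gaussian kernel density
  estimates of pooled fish positions evaluated on a 1-cm grid and
  renormalised over the arena.  P_V weighs each experiment inversely by its
  detection count so every experiment contributes equal mass.
* **Per-trial medians** (x~, y~, z~) of position, the observations entering
  the nonparametric test battery.

The first three minutes of each ten-minute treatment are excluded to let the
fish adapt to the new velocity; an optional bottom filter re-analyses only
frames with no fish above 5 cm from the flume bottom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageGrid",
    "TrialMetrics",
    "apply_window",
    "explored_area",
    "trajectory_length",
    "horizontal_density",
    "vertical_density",
    "trial_medians",
    "bottom_filter",
    "metrics_from_truth",
    "cohort_metrics",
]


@dataclass(frozen=True)
class CoverageGrid:
    """Arena grid of half-open 1-cm^2 cells [i, i+1) x [j, j+1)."""

    nx: int = 60
    ny: int = 30

    @property
    def total_cells(self) -> int:
        return self.nx * self.ny

    def cell_indices(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat cell index per position; points on the far boundary fall in the last cell."""
        ix = np.minimum(np.floor(x).astype(int), self.nx - 1)
        iy = np.minimum(np.floor(y).astype(int), self.ny - 1)
        if (ix < 0).any() or (iy < 0).any():
            raise ValueError("positions outside the arena grid")
        return ix * self.ny + iy


@dataclass(frozen=True)
class TrialMetrics:
    """Per-trial-treatment outcome measures feeding the statistics."""

    trial_id: int
    group_size: int
    velocity_cm_s: float
    ea: float
    tl_m: float
    median_x: float
    median_y: float
    median_z: float | None


def apply_window(
    trajectories: pd.DataFrame,
    fps: float,
    start_frame: int = 0,
    skip_s: float = 180.0,
    end_frame: int | None = None,
) -> pd.DataFrame:
    """Drop the adaptation window: frames before ``start_frame + skip_s*fps``.

    Raises if nothing survives (the window must be non-empty).
    """
    cut = start_frame + int(round(skip_s * fps))
    out = trajectories.loc[trajectories["frame"] >= cut]
    if end_frame is not None:
        out = out.loc[out["frame"] <= end_frame]
    if len(out) == 0:
        raise ValueError(
            f"analysis window is empty: no frames at or after {cut}"
        )
    return out.reset_index(drop=True)


def explored_area(trajectories: pd.DataFrame, grid: CoverageGrid | None = None) -> float:
    """Group-mean fraction of distinct grid cells visited per fish."""
    if grid is None:
        grid = CoverageGrid()
    fractions = []
    for _, grp in trajectories.groupby("fish_id"):
        cells = grid.cell_indices(grp["x_cm"].to_numpy(), grp["y_cm"].to_numpy())
        fractions.append(len(np.unique(cells)) / grid.total_cells)
    return float(np.mean(fractions))


def trajectory_length(trajectories: pd.DataFrame) -> float:
    """Group-mean horizontal path length in metres.

    Only consecutive frames (frame difference of one) contribute, so removed
    frames break segments rather than being bridged by a straight line.
    """
    lengths = []
    for fid, grp in trajectories.groupby("fish_id"):
        grp = grp.sort_values("frame")
        if len(grp) < 2:
            logger.warning("fish %s has a single position; contributes TL = 0", fid)
            lengths.append(0.0)
            continue
        xy = grp[["x_cm", "y_cm"]].to_numpy()
        df = np.diff(grp["frame"].to_numpy())
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        lengths.append(float(seg[df == 1].sum()) / 100.0)
    return float(np.mean(lengths))


def _kde_bandwidth(rule: str | float):
    if isinstance(rule, (int, float)):
        return rule
    if rule in ("silverman", "scott"):
        return rule
    raise ValueError(f"unknown bandwidth rule {rule!r}")


def horizontal_density(
    positions: pd.DataFrame,
    arena_xy: tuple[float, float] = (60.0, 30.0),
    bandwidth: str | float = "silverman",
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gaussian-kernel horizontal space-use density P_H on 1-cm cell centres.

    Positions are pooled over every experiment of a condition; the returned
    table (x_cm, y_cm, density) is renormalised so cell mass sums to one over
    the arena.
    """
    x = positions["x_cm"].to_numpy(dtype=float)
    y = positions["y_cm"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("at least two positions are required for a density estimate")
    nx, ny = int(arena_xy[0]), int(arena_xy[1])
    cx, cy = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        warnings.warn("all positions identical; returning a single-cell point mass")
        dens = np.zeros((nx, ny))
        g = CoverageGrid(nx, ny)
        idx = g.cell_indices(x[:1], y[:1])[0]
        dens[idx // ny, idx % ny] = 1.0
    else:
        kde = gaussian_kde(np.vstack([x, y]), bw_method=_kde_bandwidth(bandwidth),
                           weights=weights)
        dens = kde(np.vstack([cx.ravel(), cy.ravel()])).reshape(nx, ny)
        dens = dens / dens.sum()
    return pd.DataFrame(
        {"x_cm": cx.ravel(), "y_cm": cy.ravel(), "density": dens.ravel()}
    )


def vertical_density(
    side_detections: pd.DataFrame,
    depth_cm: float = 15.0,
    bandwidth: str | float = "silverman",
    experiment_col: str = "trial_id",
) -> pd.DataFrame:
    """Vertical space-use density P_V(z) on 1-cm cell centres.

    Each detection is weighted by the inverse of its experiment's total
    detection count, so every experiment contributes equal mass regardless
    of how many detections it produced (occlusions make counts uneven).
    """
    z = side_detections["z_cm"].to_numpy(dtype=float)
    if len(z) < 2:
        raise ValueError("at least two detections are required for a density estimate")
    counts = side_detections.groupby(experiment_col)["z_cm"].transform("size").to_numpy()
    weights = 1.0 / counts
    weights = weights / weights.sum()
    centres = np.arange(int(depth_cm)) + 0.5
    if np.ptp(z) == 0:
        warnings.warn("all vertical positions identical; returning a single-cell point mass")
        dens = np.zeros(int(depth_cm))
        dens[min(int(z[0]), int(depth_cm) - 1)] = 1.0
    else:
        kde = gaussian_kde(z, bw_method=_kde_bandwidth(bandwidth), weights=weights)
        dens = kde(centres)
        dens = dens / dens.sum()
    return pd.DataFrame({"z_cm": centres, "density": dens})


def trial_medians(
    trajectories: pd.DataFrame,
    side_detections: pd.DataFrame | None = None,
) -> tuple[float, float, float | None]:
    """Per-trial medians (x~, y~, z~), pooling all fish of the group.

    z~ comes from the synchronised side detections and is None when side
    data are missing (the trial is then excluded from vertical tests only).
    """
    if len(trajectories) == 0:
        raise ValueError("empty trajectory table")
    mx = float(trajectories["x_cm"].median())
    my = float(trajectories["y_cm"].median())
    mz = None
    if side_detections is not None and len(side_detections) > 0:
        mz = float(side_detections["z_cm"].median())
    return mx, my, mz


def bottom_filter(
    trajectories: pd.DataFrame,
    side_detections: pd.DataFrame,
    z_threshold_cm: float = 5.0,
) -> tuple[pd.DataFrame, int]:
    """Retain only frames in which no fish was detected above ``z_threshold_cm``.

    Frames with any side detection higher than the threshold are removed from
    the bottom-view trajectories; EA/TL/P_H can then be recomputed on the
    remainder (TL segments spanning removed frames are broken, not bridged).
    Returns the filtered trajectories and the number of frames removed.
    """
    high = side_detections.loc[side_detections["z_cm"] > z_threshold_cm, "frame"].unique()
    out = trajectories.loc[~trajectories["frame"].isin(high)]
    n_removed = trajectories["frame"].nunique() - out["frame"].nunique()
    if len(out) == 0:
        raise ValueError(
            f"bottom filter removed every frame (threshold {z_threshold_cm} cm)"
        )
    return out.reset_index(drop=True), int(n_removed)


# ---------------------------------------------------------------------------
# cohort-level convenience


def metrics_from_truth(run, skip_s: float = 180.0) -> TrialMetrics:
    """Compute one treatment run's metrics directly from simulated truth.

    Operates on the dense position array for speed; numerically identical to
    windowing the trajectory table and applying ``explored_area`` /
    ``trajectory_length`` / ``trial_medians`` (asserted by the test suite).
    """
    truth = run.truth
    fps = truth.config.fps
    cut = int(round(skip_s * fps))
    P = truth.positions[cut:]
    if P.shape[0] == 0:
        raise ValueError(f"analysis window is empty: no frames at or after {cut}")
    nx, ny = int(truth.config.arena[0]), int(truth.config.arena[1])
    ix = np.minimum(P[:, :, 0].astype(int), nx - 1)
    iy = np.minimum(P[:, :, 1].astype(int), ny - 1)
    cells = ix * ny + iy
    n = P.shape[1]
    ea = float(np.mean([len(np.unique(cells[:, i])) for i in range(n)])) / (nx * ny)
    seg = np.linalg.norm(np.diff(P[:, :, :2], axis=0), axis=2)
    tl = float(seg.sum(axis=0).mean()) / 100.0
    mx = float(np.median(P[:, :, 0]))
    my = float(np.median(P[:, :, 1]))
    mz = float(np.median(P[:, :, 2]))
    return TrialMetrics(
        trial_id=run.trial_id,
        group_size=run.group_size,
        velocity_cm_s=run.velocity_cm_s,
        ea=ea,
        tl_m=tl,
        median_x=mx,
        median_y=my,
        median_z=mz,
    )


def cohort_metrics(runs, skip_s: float = 180.0) -> pd.DataFrame:
    """Per-trial-treatment metrics table for a simulated cohort."""
    rows = [metrics_from_truth(r, skip_s=skip_s) for r in runs]
    return pd.DataFrame(
        {
            "trial_id": [r.trial_id for r in rows],
            "group_size": [r.group_size for r in rows],
            "velocity": [r.velocity_cm_s for r in rows],
            "EA": [r.ea for r in rows],
            "TL_m": [r.tl_m for r in rows],
            "median_x": [r.median_x for r in rows],
            "median_y": [r.median_y for r in rows],
            "median_z": [r.median_z for r in rows],
        }
    )
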