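"""Pixel-to-arena calibration and two-camera time alignment.

The arena frame has its origin at the upstream (honeycomb) bottom-right
corner: x in cm downstream [0, 60], y transversal [0, 30], z vertical up
[0, 15].  Each camera view is calibrated from the four pixel corners of the
visible arena rectangle via the unique projective homography sending them to
the rectangle corners — exact at the corners and modelling perspective in
between.  The two camera streams are aligned in time from the onset frame of
synchronisation LEDs visible in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ViewCalibration",
    "PlaneMapping",
    "fit_view_mapping",
    "apply_mapping",
    "synchronise_views",
    "VIEW_COLUMNS",
]

#: arena-frame column names produced per view
VIEW_COLUMNS = {"bottom": ("x_cm", "y_cm"), "side": ("x_cm", "z_cm")}


@dataclass(frozen=True)
class ViewCalibration:
    """Four ordered pixel corners of the arena rectangle in one view.

    Corner order: origin corner, +first-axis end, +both, +second-axis end
    (counter-clockwise around the rectangle (0,0) -> (W,0) -> (W,H) -> (0,H)).
    ``rect_cm`` is (W, H): (60, 30) for the bottom view, (60, 15) for the side.
    """

    corners_px: tuple[tuple[float, float], ...]
    rect_cm: tuple[float, float]
    view: str

    def __post_init__(self) -> None:
        if self.view not in VIEW_COLUMNS:
            raise ValueError(f"unknown view {self.view!r}; expected 'bottom' or 'side'")
        if len(self.corners_px) != 4:
            raise ValueError("exactly four pixel corners are required")
        if any(d <= 0 for d in self.rect_cm):
            raise ValueError("rectangle dimensions must be positive")


def _check_nondegenerate(corners: np.ndarray) -> None:
    for triple in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
        a, b, c = corners[list(triple)]
        area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(area2) < 1e-9:
            raise ValueError(f"degenerate calibration: corners {triple} are collinear")


@dataclass(frozen=True)
class PlaneMapping:
    """Fitted projective mapping pixel -> arena plane for one view."""

    H: np.ndarray  # 3x3, maps pixel homogeneous coords to cm
    view: str
    rect_cm: tuple[float, float]

    def to_cm(self, pts_px: np.ndarray) -> np.ndarray:
        pts_px = np.atleast_2d(np.asarray(pts_px, dtype=float))
        ones = np.ones((len(pts_px), 1))
        h = np.hstack([pts_px, ones]) @ self.H.T
        return h[:, :2] / h[:, 2:3]

    def to_px(self, pts_cm: np.ndarray) -> np.ndarray:
        pts_cm = np.atleast_2d(np.asarray(pts_cm, dtype=float))
        Hinv = np.linalg.inv(self.H)
        ones = np.ones((len(pts_cm), 1))
        h = np.hstack([pts_cm, ones]) @ Hinv.T
        return h[:, :2] / h[:, 2:3]


def fit_view_mapping(cal: ViewCalibration) -> PlaneMapping:
    """Fit the unique homography sending the four pixel corners to the
    rectangle corners (0,0), (W,0), (W,H), (0,H).

    Solved by the direct linear transform: with h33 fixed to 1 the four
    correspondences give an 8x8 linear system; exact at the corners.
    """
    src = np.asarray(cal.corners_px, dtype=float)
    _check_nondegenerate(src)
    W, Hc = cal.rect_cm
    dst = np.array([(0.0, 0.0), (W, 0.0), (W, Hc), (0.0, Hc)])

    # orientation consistency: the corner quad must wind the same way as the rectangle
    def _signed_area(q: np.ndarray) -> float:
        return 0.5 * float(
            np.sum(q[:, 0] * np.roll(q[:, 1], -1) - np.roll(q[:, 0], -1) * q[:, 1])
        )

    if _signed_area(src) == 0:
        raise ValueError("degenerate calibration: corner quadrilateral has zero area")

    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((u, v), (x, y)) in enumerate(zip(src, dst)):
        A[2 * i] = [u, v, 1, 0, 0, 0, -u * x, -v * x]
        b[2 * i] = x
        A[2 * i + 1] = [0, 0, 0, u, v, 1, -u * y, -v * y]
        b[2 * i + 1] = y
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - caught above in practice
        raise ValueError(f"degenerate calibration quadrilateral: {exc}") from exc
    H = np.append(h, 1.0).reshape(3, 3)

    mapping = PlaneMapping(H=H, view=cal.view, rect_cm=cal.rect_cm)
    # sanity: corners must reproduce (guards against near-degenerate input)
    err = np.max(np.abs(mapping.to_cm(src) - dst))
    if not np.isfinite(err) or err > 1e-6:
        raise ValueError(f"homography fit failed: max corner error {err:.3g} cm")
    return mapping


def apply_mapping(
    mapping: PlaneMapping,
    detections: pd.DataFrame,
    view: str | None = None,
    clamp_cm: float = 0.5,
) -> tuple[pd.DataFrame, int]:
    """Transform pixel centroids to arena cm and enforce the arena box.

    Coordinates outside the rectangle by at most ``clamp_cm`` are clamped to
    the boundary (small calibration error should not delete data); farther
    outliers are excluded.  Returns the calibrated table (with the two
    view-appropriate cm columns added) and the exclusion count.
    """
    if view is not None and view != mapping.view:
        raise ValueError(f"mapping fitted for view {mapping.view!r}, got {view!r}")
    cols = VIEW_COLUMNS[mapping.view]
    out = detections.copy()
    if len(out) == 0:
        out[cols[0]] = np.array([], dtype=float)
        out[cols[1]] = np.array([], dtype=float)
        return out, 0
    cm = mapping.to_cm(out[["cx_px", "cy_px"]].to_numpy())
    W, Hc = mapping.rect_cm
    lims = np.array([W, Hc])
    inside = np.all((cm >= -clamp_cm) & (cm <= lims + clamp_cm), axis=1)
    n_excluded = int((~inside).sum())
    if n_excluded:
        logger.info("apply_mapping(%s): excluded %d detections beyond %.2f cm of the arena",
                    mapping.view, n_excluded, clamp_cm)
    cm = np.clip(cm, 0.0, lims)
    out[cols[0]] = cm[:, 0]
    out[cols[1]] = cm[:, 1]
    return out.loc[inside].reset_index(drop=True), n_excluded


def synchronise_views(
    led_onset_bottom: int,
    led_onset_side: int,
    side_detections: pd.DataFrame,
) -> pd.DataFrame:
    """Re-index side-view frames to the bottom camera clock.

    Side frame f becomes ``f - (led_onset_side - led_onset_bottom)``; records
    that land on negative frames are dropped (they precede the bottom video).
    """
    if led_onset_bottom < 0 or led_onset_side < 0:
        raise ValueError("LED onset frames must be >= 0")
    shift = led_onset_side - led_onset_bottom
    out = side_detections.copy()
    out["frame"] = out["frame"] - shift
    n_dropped = int((out["frame"] < 0).sum())
    if n_dropped:
        logger.info("synchronise_views: dropped %d side records before bottom frame 0", n_dropped)
    return out.loc[out["frame"] >= 0].reset_index(drop=True)
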