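"""Endocardial contour extraction, branching on LVOT presence.

Marching from the mid slice toward the base, the basal slice containing the
left-ventricular outflow tract (LVOT) is recognized by a jump of the
moment-equivalent major axis: if the ratio of the current major axis to the
previous slice's exceeds a threshold (default 1.2, strict inequality), the
wall is open and the blood pool has leaked into the outflow tract.

Without LVOT the endocardial contour is simply the convex hull of the blood
pool's boundary (papillary notches are bridged by convexity).  With LVOT the
binarized ROI is masked with the dilated previous pool, the masked boundary
is expressed in polar form about the previous center, a least-squares circle
is fitted, points whose polar radius exceeds the fitted radius by more than
an outlier threshold are pruned, and the survivors are closed, hulled and
Bezier-smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops
from skimage.morphology import disk

from .errors import SegmentationError
from .imaging_io import Contour
from .smoothing import SmoothingParams, bezier_smooth

__all__ = ["LvotDecision", "CircleFit", "major_axis_length", "detect_lvot",
           "endo_without_lvot", "fit_circle", "endo_with_lvot",
           "boundary_pixels"]


@dataclass
class LvotDecision:
    major_axis_current: float
    major_axis_previous: float
    ratio: float
    threshold: float
    has_lvot: bool


@dataclass
class CircleFit:
    center: tuple[float, float]  # (row, col)
    radius: float
    outlier_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")


def major_axis_length(mask: np.ndarray) -> float:
    """Major axis of the ellipse with the same normalized second central
    moments as the mask (all foreground pixels form one region)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = regionprops(mask.astype(np.uint8))
    return float(props[0].axis_major_length)


def detect_lvot(major_axis_current: float, major_axis_previous: float,
                threshold: float = 1.2) -> LvotDecision:
    """LVOT flag from the major-axis jump; strict '>' at the threshold."""
    if major_axis_current <= 0 or major_axis_previous <= 0:
        raise ValueError("major-axis lengths must be positive")
    ratio = major_axis_current / major_axis_previous
    return LvotDecision(major_axis_current, major_axis_previous, ratio,
                        threshold, ratio > threshold)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of the mask's inner boundary pixels."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool),
                                    border_value=0)
    rows, cols = np.nonzero(mask & ~eroded)
    return np.column_stack([rows, cols])


def endo_without_lvot(blood_pool: np.ndarray) -> Contour:
    """Convex hull of the blood pool's boundary, counter-clockwise."""
    pts = boundary_pixels(blood_pool)
    if len(pts) == 0:
        raise SegmentationError("empty blood pool", stage="endocardium")
    xy = pts[:, ::-1].astype(float)  # (x, y)
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise SegmentationError(f"degenerate blood pool (collinear): {exc}",
                                stage="endocardium") from exc
    return Contour(xy[hull.vertices])  # ConvexHull vertices are CCW in (x, y)


def fit_circle(points: np.ndarray, outlier_threshold: float = 3.0) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through (row, col) points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (row, col) points")
    r, c = pts[:, 0], pts[:, 1]
    A = np.column_stack([2.0 * r, 2.0 * c, np.ones(len(pts))])
    b = r * r + c * c
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("collinear points: circle fit is singular")
    cr, cc, k = sol
    rad2 = k + cr * cr + cc * cc
    if rad2 <= 0:
        raise ValueError("circle fit degenerate (non-positive radius)")
    return CircleFit((float(cr), float(cc)), float(np.sqrt(rad2)),
                     outlier_threshold)


def endo_with_lvot(binary_roi: np.ndarray, previous_pool: np.ndarray,
                   previous_center: tuple[float, float],
                   dilation_px: int = 3, outlier_px: float = 3.0,
                   smoothing: SmoothingParams | None = None) -> Contour:
    """Endocardial contour of an LVOT slice via previous-slice context.

    ``previous_center`` is (row, col) of the previous blood pool's center in
    the current ROI frame.
    """
    binary_roi = np.asarray(binary_roi, dtype=bool)
    previous_pool = np.asarray(previous_pool, dtype=bool)
    if not previous_pool.any():
        raise SegmentationError("previous blood pool is empty",
                                stage="endocardium-lvot")
    masked = binary_roi & ndimage.binary_dilation(previous_pool,
                                                  structure=disk(dilation_px))
    pts = boundary_pixels(masked)
    if len(pts) < 3:
        raise SegmentationError("too few boundary points after masking",
                                stage="endocardium-lvot")
    circle = fit_circle(pts, outlier_px)
    dr = pts[:, 0] - previous_center[0]
    dc = pts[:, 1] - previous_center[1]
    radius = np.hypot(dr, dc)
    survivors = pts[radius <= circle.radius + outlier_px]
    if len(survivors) < 3:
        raise SegmentationError("fewer than 3 points survived circle pruning",
                                stage="endocardium-lvot")
    theta = np.arctan2(survivors[:, 0] - previous_center[0],
                       survivors[:, 1] - previous_center[1])
    closed = survivors[np.argsort(theta)]
    xy = closed[:, ::-1].astype(float)
    try:
        hull = ConvexHull(xy)
    except QhullError as exc:
        raise SegmentationError(f"degenerate survivor set: {exc}",
                                stage="endocardium-lvot") from exc
    contour = Contour(xy[hull.vertices])
    smoothed = bezier_smooth(contour, smoothing)
    # honor the pruning contract after smoothing: clamp radii about the pole
    cx, cy = previous_center[1], previous_center[0]
    d = smoothed.points - np.array([cx, cy])
    r = np.hypot(d[:, 0], d[:, 1])
    rmax = circle.radius + outlier_px
    over = r > rmax
    if np.any(over):
        scale = rmax / r[over]
        pts_out = smoothed.points.copy()
        pts_out[over] = np.array([cx, cy]) + d[over] * scale[:, None]
        smoothed = Contour(pts_out)
    return smoothed
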