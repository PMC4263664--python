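"""Epicardial boundary by region-constrained dynamic programming in polar
coordinates.

The ROI is resampled onto an (angle, radius) rectangle about the endocardial
center so the closed epicardial boundary becomes a left-to-right path: one
row index per angle column.  A non-maxima-suppressed gradient map F in [0, 1]
scores edges; admissible positions are limited by a binary search mask B
(outside the endocardium, away from bright structures such as the right
ventricle and pericardial/abdominal fat, and inside the dilated previous
epicardial region when available).  The step cost of an admissible cell is
w * (1 - F); inadmissible cells carry an infinite barrier.  The column-wise
recursion C(i, j) = min_{|k-i|<=delta} C(k, j-1) + cost(i, j) is run once per
admissible first-column row so the closure penalty gamma * |i_last - i_first|
added in the last column is exact per chain; the path must also close with
|i_last - i_first| <= delta.  Every minimum breaks ties toward the smaller
row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SegmentationError
from .imaging_io import Contour

__all__ = ["PolarMap", "EdgeFeature", "SearchMask", "DPParams", "CostMap",
           "polar_transform", "edge_feature", "build_search_mask",
           "dp_optimal_path", "epicardial_contour"]


@dataclass
class PolarMap:
    """M (radius) x N (angle) resampling of an ROI disk.

    Row i maps radius ``i * radial_step`` (row 0 is the pole, the last row is
    ``r_max``); column j maps angle ``2 pi j / N``, increasing
    counter-clockwise with x = cx + r cos(theta), y = cy + r sin(theta).
    """

    values: np.ndarray
    center: tuple[float, float]  # (row, col) pole in ROI coordinates
    r_max: float

    def __post_init__(self) -> None:
        if self.values.shape[1] < 36:
            raise ValueError("polar map needs >= 36 angle columns")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def radial_step(self) -> float:
        return self.r_max / (self.values.shape[0] - 1)

    @property
    def angles(self) -> np.ndarray:
        n = self.values.shape[1]
        return 2.0 * np.pi * np.arange(n) / n


@dataclass
class EdgeFeature:
    F: np.ndarray  # in [0, 1], larger = stronger suppressed-gradient edge


@dataclass
class SearchMask:
    B: np.ndarray  # True = admissible epicardial position


@dataclass
class DPParams:
    delta: int = 2
    w: float = 1.0
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.delta < 1 or int(self.delta) != self.delta:
            raise ValueError("delta must be an integer >= 1")
        if self.w <= 0:
            raise ValueError("w must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class CostMap:
    C: np.ndarray            # accumulated costs of the winning sweep (M x N)
    predecessor: np.ndarray  # backtracking row indices of the winning sweep
    path: np.ndarray         # per-column row index of the optimum (length N)
    start_row: int
    total_cost: float


# ---------------------------------------------------------------------------
# polar resampling
# ---------------------------------------------------------------------------

def polar_transform(roi_image: np.ndarray, center: tuple[float, float],
                    r_max: float, M: int, N: int) -> PolarMap:
    """Bilinear polar resampling; samples outside the ROI take the boundary
    value (replicate)."""
    roi_image = np.asarray(roi_image, dtype=float)
    cr, cc = center
    if not (0 <= cr < roi_image.shape[0] and 0 <= cc < roi_image.shape[1]):
        raise ValueError(f"pole {center} lies outside the ROI {roi_image.shape}")
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    radii = np.linspace(0.0, r_max, M)
    theta = 2.0 * np.pi * np.arange(N) / N
    rr = cr + radii[:, None] * np.sin(theta)[None, :]
    cc_ = cc + radii[:, None] * np.cos(theta)[None, :]
    values = ndimage.map_coordinates(roi_image, [rr, cc_], order=1,
                                     mode="nearest")
    return PolarMap(values, (float(cr), float(cc)), float(r_max))


# ---------------------------------------------------------------------------
# edge map
# ---------------------------------------------------------------------------

def edge_feature(polar: PolarMap, smooth_sigma: float = 1.0) -> EdgeFeature:
    """Non-maxima-suppressed gradient magnitude, min-max normalized to [0, 1].

    The gradient is estimated on a lightly smoothed polar image
    (``smooth_sigma`` pixels; 0 disables smoothing); the angular axis is
    treated as periodic.  A pixel survives if its magnitude is strictly
    greater than the neighbor along +gradient and >= the neighbor along
    -gradient, which thins ridges to single rows and erases constant-slope
    ramps.  The first and last radius rows are boundary artifacts of the
    resampling and are masked out.
    """
    v = polar.values
    if v.shape[0] < 3:
        raise ValueError("polar map needs >= 3 radius rows")
    if smooth_sigma > 0:
        v = ndimage.gaussian_filter(v, smooth_sigma, mode=("nearest", "wrap"))
    gy = np.gradient(v, axis=0)                              # radial
    gx = (np.roll(v, -1, axis=1) - np.roll(v, 1, axis=1)) / 2.0  # angular
    mag = np.hypot(gx, gy)

    t = np.mod(np.arctan2(gy, gx), np.pi)
    bins = np.zeros(v.shape, dtype=np.uint8)
    bins[(t >= np.pi / 8) & (t < 3 * np.pi / 8)] = 1   # diagonal (+1,+1)
    bins[(t >= 3 * np.pi / 8) & (t < 5 * np.pi / 8)] = 2  # radial
    bins[(t >= 5 * np.pi / 8) & (t < 7 * np.pi / 8)] = 3  # diagonal (+1,-1)
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}

    keep = np.zeros(v.shape, dtype=bool)
    for b, (dr, dc) in offsets.items():
        n_plus = np.roll(np.roll(mag, -dr, axis=0), -dc, axis=1)
        n_minus = np.roll(np.roll(mag, dr, axis=0), dc, axis=1)
        sel = bins == b
        keep |= sel & (mag > n_plus) & (mag >= n_minus)

    sup = np.where(keep, mag, 0.0)
    sup[0, :] = 0.0
    sup[-1, :] = 0.0
    hi = sup.max()
    lo = sup.min()
    if hi > lo:
        sup = (sup - lo) / (hi - lo)
    return EdgeFeature(sup)


# ---------------------------------------------------------------------------
# search mask
# ---------------------------------------------------------------------------

def build_search_mask(shape: tuple[int, int], endo_radius_rows: np.ndarray,
                      bright_mask_polar: np.ndarray | None = None,
                      previous_epi_polar: np.ndarray | None = None,
                      margin: int = 1, prev_dilation: int = 3) -> SearchMask:
    """Admissible epicardial positions per (radius row, angle column).

    B = rows at least ``endo_radius + margin``, not bright, and (when a
    previous epicardial region is given) inside its dilation.  A fully
    blocked column is reopened to the rows adjacent to the endocardial radius
    so a feasible path always exists.
    """
    M, N = shape
    endo = np.asarray(endo_radius_rows, dtype=float)
    if endo.shape != (N,):
        raise ValueError("need one endocardial radius per angle column")
    rows = np.arange(M)[:, None]
    B = rows >= (endo[None, :] + margin)
    if bright_mask_polar is not None:
        B &= ~np.asarray(bright_mask_polar, dtype=bool)
    if previous_epi_polar is not None:
        allowed = ndimage.binary_dilation(
            np.asarray(previous_epi_polar, dtype=bool),
            structure=np.ones((3, 3), bool), iterations=prev_dilation)
        B &= allowed
    blocked = ~B.any(axis=0)
    for j in np.flatnonzero(blocked):
        e = int(np.clip(round(endo[j] + margin), 0, M - 1))
        B[e, j] = True
        if e + 1 < M:
            B[e + 1, j] = True
    return SearchMask(B)


# ---------------------------------------------------------------------------
# dynamic programming
# ---------------------------------------------------------------------------

def dp_optimal_path(feature: EdgeFeature, mask: SearchMask,
                    params: DPParams) -> CostMap:
    """Minimal-cost delta-feasible closed path through the cost table.

    One DP sweep per admissible first-column row makes the closure penalty
    gamma * |i_last - i_first| exact; closure also requires
    |i_last - i_first| <= delta.  Tie-breaks: smaller row index at every
    minimum (predecessor choice, final row, then start row).
    """
    F, B = feature.F, mask.B
    if F.shape != B.shape:
        raise ValueError("feature and mask shapes differ")
    M, N = F.shape
    delta, w, gamma = params.delta, params.w, params.gamma
    step = np.where(B, w * (1.0 - F), np.inf)

    starts = np.flatnonzero(np.isfinite(step[:, 0]))
    if starts.size == 0:
        raise SegmentationError("epicardium search infeasible", stage="dp")
    S = starts.size

    C = np.full((S, M), np.inf)
    C[np.arange(S), starts] = step[starts, 0]
    pred = np.full((S, M, N), -1, dtype=np.int32)
    hist = np.empty((S, M, N))
    hist[:, :, 0] = C

    row_idx = np.arange(M)
    for j in range(1, N):
        best = np.full((S, M), np.inf)
        bestk = np.full((S, M), -1, dtype=np.int32)
        for off in range(-delta, delta + 1):  # ascending k -> smaller row wins ties
            cand = np.full((S, M), np.inf)
            if off >= 0:
                cand[:, :M - off or None] = C[:, off:]
            else:
                cand[:, -off:] = C[:, :M + off]
            krows = row_idx + off
            valid = (krows >= 0) & (krows < M)
            upd = (cand < best) & valid[None, :]
            best[upd] = cand[upd]
            bestk[upd] = np.broadcast_to(krows, (S, M))[upd]
        C = best + step[:, j][None, :]
        pred[:, :, j] = bestk
        hist[:, :, j] = C

    # closure: final row within delta of the chain's first row, plus penalty
    closure_ok = np.abs(row_idx[None, :] - starts[:, None]) <= delta
    total = C + gamma * np.abs(row_idx[None, :] - starts[:, None])
    total[~closure_ok] = np.inf
    if not np.isfinite(total).any():
        raise SegmentationError("epicardium search infeasible", stage="dp")
    tmin = total.min()
    cand = np.argwhere(total == tmin)  # (s_idx, final_row) pairs
    # tie-break: smaller final row, then smaller start row
    order = np.lexsort((starts[cand[:, 0]], cand[:, 1]))
    s_idx, i_last = cand[order[0]]
    path = np.empty(N, dtype=int)
    path[N - 1] = i_last
    for j in range(N - 1, 0, -1):
        path[j - 1] = pred[s_idx, path[j], j]
    if path[0] != starts[s_idx]:  # pragma: no cover - internal consistency
        raise AssertionError("backtracking did not reach the sweep's start row")
    return CostMap(C=hist[s_idx], predecessor=pred[s_idx], path=path,
                   start_row=int(starts[s_idx]), total_cost=float(tmin))


def epicardial_contour(costmap: CostMap, polar: PolarMap,
                       offset: tuple[float, float] = (0.0, 0.0)) -> Contour:
    """Inverse polar mapping of the DP path to a closed Cartesian contour.

    ``offset`` is the (row, col) origin of the ROI in full-image coordinates.
    """
    r = costmap.path * polar.radial_step
    theta = polar.angles
    cr, cc = polar.center
    x = cc + offset[1] + r * np.cos(theta)
    y = cr + offset[0] + r * np.sin(theta)
    return Contour(np.column_stack([x, y]))
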