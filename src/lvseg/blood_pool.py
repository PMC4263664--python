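"""Refine the LBF region into a blood-pool mask.

The LBF result is used as a *contour mask*: the ROI is binarized at a grid of
candidate thresholds and, for each, the 8-connected component overlapping the
LBF region most is scored by its pixel-count overlap.  The threshold with
maximal overlap wins (a plateau is broken toward the Otsu threshold of the
ROI, which is the usual but potentially biased single-threshold choice).
Holes in the selected component are filled after selection so papillary
muscles end up inside the cavity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import SegmentationError

__all__ = ["ROISpec", "ThresholdSearch", "make_contour_mask",
           "optimal_threshold", "extract_blood_pool", "default_candidates"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class ROISpec:
    """Square ROI in full-image coordinates, clamped to lie inside the image."""

    center: tuple[int, int]   # (row, col)
    half_size: int

    def __post_init__(self) -> None:
        if self.half_size < 16:
            raise ValueError("ROI half_size must be >= 16")

    def clamped(self, shape: tuple[int, int]) -> "ROISpec":
        h = self.half_size
        if 2 * h + 1 > min(shape):
            raise ValueError(f"ROI of half size {h} does not fit image {shape}")
        r = int(np.clip(self.center[0], h, shape[0] - 1 - h))
        c = int(np.clip(self.center[1], h, shape[1] - 1 - h))
        return ROISpec((r, c), h)

    @property
    def origin(self) -> tuple[int, int]:
        """Top-left (row, col) of the ROI window."""
        return self.center[0] - self.half_size, self.center[1] - self.half_size

    @property
    def size(self) -> int:
        return 2 * self.half_size + 1

    def extract(self, image: np.ndarray) -> np.ndarray:
        r0, c0 = self.origin
        return image[r0:r0 + self.size, c0:c0 + self.size]


@dataclass
class ThresholdSearch:
    candidates: np.ndarray
    chosen: float
    overlap_curve: np.ndarray


def make_contour_mask(shape: tuple[int, int],
                      init_radius: float = 15.0,
                      previous_region: np.ndarray | None = None,
                      center: tuple[float, float] | None = None) -> np.ndarray:
    """Binary mask seeding the LBF model inside an ROI window.

    Mid slice (no ``previous_region``): a filled circle of ``init_radius`` at
    the ROI center.  Other slices: the previous slice's endocardial region,
    re-centered so its centroid sits at the ROI center.
    """
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    if previous_region is None:
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= init_radius ** 2
    prev = np.asarray(previous_region, dtype=bool)
    if not prev.any():
        raise SegmentationError("previous endocardial region is empty",
                                stage="contour-mask")
    rows, cols = np.nonzero(prev)
    dr = int(round(center[0] - rows.mean()))
    dc = int(round(center[1] - cols.mean()))
    out = np.zeros(shape, dtype=bool)
    nr = rows + dr
    nc = cols + dc
    ok = (nr >= 0) & (nr < shape[0]) & (nc >= 0) & (nc < shape[1])
    out[nr[ok], nc[ok]] = True
    if not out.any():
        raise SegmentationError("previous endocardial region fell outside ROI",
                                stage="contour-mask")
    return out


def select_lbf_component(lbf_region: np.ndarray,
                         contour_mask: np.ndarray) -> np.ndarray:
    """The LBF object overlapping the contour mask most = the LBF blood pool.

    The raw level-set region may contain other locally bright structures
    (right ventricle, fat); the binary circle / previous-endocardium mask
    disambiguates them by maximal overlap area.
    """
    overlap, comp = _best_component(np.asarray(lbf_region, bool),
                                    np.asarray(contour_mask, bool))
    if comp is None:
        raise SegmentationError("no LBF component overlaps the contour mask",
                                stage="lbf")
    return comp


def default_candidates(roi_image: np.ndarray, n_thresholds: int = 24) -> np.ndarray:
    """Evenly spaced thresholds between the 5th and 95th intensity percentiles."""
    lo, hi = np.percentile(roi_image, [5.0, 95.0])
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_thresholds)


def _best_component(bw: np.ndarray, reference: np.ndarray):
    """(overlap, component mask) of the 8-connected component overlapping most."""
    labels, n = ndimage.label(bw, structure=_STRUCT8)
    if n == 0:
        return 0, None
    counts = np.bincount(labels[reference], minlength=n + 1)
    counts[0] = 0
    best = int(np.argmax(counts))
    if counts[best] == 0:
        return 0, None
    return int(counts[best]), labels == best


def optimal_threshold(roi_image: np.ndarray, lbf_region: np.ndarray,
                      candidates: np.ndarray | None = None,
                      n_thresholds: int = 24) -> ThresholdSearch:
    """Overlap-maximizing threshold search against the LBF region.

    Ties on the overlap plateau are broken toward the candidate nearest the
    Otsu threshold of the ROI (lower candidate on a distance tie).
    """
    roi_image = np.asarray(roi_image, dtype=float)
    lbf_region = np.asarray(lbf_region, dtype=bool)
    if roi_image.shape != lbf_region.shape:
        raise ValueError("roi_image and lbf_region shapes differ")
    if not lbf_region.any():
        raise SegmentationError("empty LBF region", stage="threshold")
    if candidates is None:
        candidates = default_candidates(roi_image, n_thresholds)
    candidates = np.asarray(candidates, dtype=float)
    if candidates.size == 0 or np.any(np.diff(candidates) < 0):
        raise ValueError("candidates must be a non-empty ascending sequence")

    overlaps = np.empty(len(candidates))
    for i, t in enumerate(candidates):
        overlaps[i], _ = _best_component(roi_image >= t, lbf_region)
    if overlaps.max() == 0:
        raise SegmentationError("blood pool not found (all overlaps zero)",
                                stage="threshold")
    try:
        otsu = float(threshold_otsu(roi_image))
    except ValueError:  # constant image
        otsu = float(roi_image.mean())
    ties = np.flatnonzero(overlaps == overlaps.max())
    chosen = candidates[ties[np.argmin(np.abs(candidates[ties] - otsu))]]
    return ThresholdSearch(candidates, float(chosen), overlaps)


def extract_blood_pool(roi_image: np.ndarray, lbf_region: np.ndarray,
                       candidates: np.ndarray | None = None,
                       n_thresholds: int = 24):
    """Blood-pool mask: best-overlap component at the optimal threshold.

    Returns ``(mask, ThresholdSearch)``; the mask is a single 8-connected,
    hole-free component.
    """
    search = optimal_threshold(roi_image, lbf_region, candidates, n_thresholds)
    _, comp = _best_component(np.asarray(roi_image, float) >= search.chosen,
                              np.asarray(lbf_region, bool))
    if comp is None:  # cannot happen: search guarantees a positive overlap
        raise SegmentationError("blood pool not found", stage="threshold")
    mask = ndimage.binary_fill_holes(comp, structure=None)
    return mask, search
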