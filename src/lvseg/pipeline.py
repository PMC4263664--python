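"""Slice-by-slice study segmentation.

The mid-ventricular slice is segmented first, seeded by a binary circle; two
independent marches then proceed toward the base (with LVOT detection) and
toward the apex (without), each passing the previous slice's result forward
as context: its endocardial center places the next ROI, its endocardial
region seeds the LBF model, its blood pool provides the LVOT-slice mask and
its epicardial region restricts the next slice's DP search scope.  A failed
slice keeps the march alive by forwarding the last successful context.

Per-slice stage order: ROI placement -> LBF evolution -> overlap-guided
thresholding -> LVOT branch -> endocardial contour (+ FFT smoothing) ->
polar resampling, edge map, search mask, DP -> epicardial contour (+ Bezier
smoothing).  Everything is deterministic: identical input and config give
bit-identical contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import convex_hull_image

from .blood_pool import (ROISpec, extract_blood_pool, make_contour_mask,
                         select_lbf_component)
from .config import PipelineConfig
from .endocardium import (LvotDecision, detect_lvot, endo_with_lvot,
                          endo_without_lvot, major_axis_length)
from .epicardium import (DPParams, build_search_mask, dp_optimal_path,
                         edge_feature, epicardial_contour, polar_transform)
from .errors import LvsegError, SegmentationError
from .imaging_io import Contour, SliceImage, Study, contour_to_mask
from .lbf import LBFParams, run_lbf
from .smoothing import (SmoothingParams, bezier_smooth, contour_from_radii,
                        fft_smooth, radii_at_angles)

__all__ = ["SliceResult", "StudyResult", "segment_slice", "segment_study"]

_CONTAIN_MARGIN_PX = 0.75  # radial clearance enforced between endo and epi


@dataclass
class SliceResult:
    slice_index: int
    phase: str
    status: str                      # "ok" | "failed" | "skipped_small_pool"
    endo: Contour | None = None
    epi: Contour | None = None
    blood_pool: np.ndarray | None = None   # full-image frame
    roi: ROISpec | None = None
    lvot: LvotDecision | None = None
    major_axis: float | None = None        # hull major axis, px
    threshold: float | None = None
    stage_failed: str | None = None
    message: str | None = None


@dataclass
class StudyResult:
    results: dict[str, list[SliceResult]]
    config: PipelineConfig
    log: list[str] = field(default_factory=list)

    def ok_results(self, phase: str) -> list[SliceResult]:
        return [r for r in self.results[phase] if r.status == "ok"]


def _lbf_params(cfg: PipelineConfig) -> LBFParams:
    return LBFParams(lambda1=cfg.lbf_lambda1, lambda2=cfg.lbf_lambda2,
                     sigma=cfg.lbf_sigma, nu=cfg.lbf_nu, mu=cfg.lbf_mu,
                     timestep=cfg.lbf_timestep, epsilon=cfg.lbf_epsilon,
                     max_iter=cfg.lbf_max_iter, tol=cfg.lbf_tol)


def _smoothing_params(cfg: PipelineConfig) -> SmoothingParams:
    return SmoothingParams(keep_harmonics=cfg.keep_harmonics,
                           bezier_segments=cfg.bezier_segments,
                           bezier_samples=cfg.bezier_samples)


def segment_slice(slice_img: SliceImage, context: SliceResult | None,
                  config: PipelineConfig | None = None,
                  direction: str | None = None) -> SliceResult:
    """Segment one slice; per-slice failures become status='failed'.

    ``direction`` is "base", "apex" or None (mid slice); LVOT detection runs
    only while marching toward the base.
    """
    if not isinstance(slice_img, SliceImage):
        raise TypeError("slice_img must be a SliceImage")
    cfg = config or PipelineConfig()
    res = SliceResult(slice_img.slice_index, slice_img.phase, "failed")
    stage = "roi"
    try:
        image = slice_img.pixels
        if context is not None and context.endo is not None:
            cx, cy = context.endo.centroid
            center = (int(round(cy)), int(round(cx)))
        else:
            center = (image.shape[0] // 2, image.shape[1] // 2)
        roi = ROISpec(center, cfg.roi_half_size).clamped(image.shape)
        res.roi = roi
        roi_img = roi.extract(image)
        r0, c0 = roi.origin

        stage = "contour-mask"
        if context is None:
            init_mask = make_contour_mask(roi_img.shape,
                                          init_radius=cfg.init_circle_radius)
        else:
            prev_endo_full = contour_to_mask(context.endo, image.shape)
            prev_roi = roi.extract(prev_endo_full)
            init_mask = make_contour_mask(roi_img.shape,
                                          previous_region=prev_roi)

        stage = "lbf"
        lbf_region = run_lbf(roi_img, init_mask, _lbf_params(cfg))
        lbf_pool = select_lbf_component(lbf_region, init_mask)

        stage = "blood-pool"
        pool, search = extract_blood_pool(roi_img, lbf_pool,
                                          n_thresholds=cfg.n_thresholds)
        res.threshold = search.chosen
        if int(pool.sum()) > cfg.max_pool_fraction * pool.size:
            raise SegmentationError(
                f"degenerate blood pool fills {int(pool.sum())} of "
                f"{pool.size} ROI pixels", stage="blood-pool")
        if int(pool.sum()) < cfg.min_pool_area:
            res.status = "skipped_small_pool"
            res.message = f"pool area {int(pool.sum())} px < {cfg.min_pool_area}"
            return res

        stage = "lvot"
        hull = convex_hull_image(pool)
        res.major_axis = major_axis_length(hull)
        lvot = None
        if (direction == "base" and context is not None
                and context.major_axis is not None):
            lvot = detect_lvot(res.major_axis, context.major_axis,
                               cfg.lvot_ratio_threshold)
        res.lvot = lvot

        stage = "endocardium"
        smoothing = _smoothing_params(cfg)
        if lvot is not None and lvot.has_lvot:
            binary_roi = roi_img >= search.chosen
            prev_pool_roi = roi.extract(context.blood_pool).astype(bool)
            if not prev_pool_roi.any():
                raise SegmentationError("previous blood pool outside ROI",
                                        stage="endocardium-lvot")
            rows, cols = np.nonzero(prev_pool_roi)
            prev_center = (float(rows.mean()), float(cols.mean()))
            endo = endo_with_lvot(binary_roi, prev_pool_roi, prev_center,
                                  dilation_px=cfg.pool_dilation_px,
                                  outlier_px=cfg.circle_outlier_px,
                                  smoothing=smoothing)
        else:
            endo = endo_without_lvot(pool)
            if cfg.fft_smooth_endo:
                cxy = endo.centroid
                radii = radii_at_angles(endo, cxy, cfg.n_angles)
                endo = contour_from_radii(
                    fft_smooth(radii, cfg.keep_harmonics), cxy)

        stage = "polar"
        ex, ey = endo.centroid
        pole = (ey, ex)  # (row, col)
        endo_radii = radii_at_angles(endo, (ex, ey), cfg.n_angles)
        r_eq = float(np.sqrt(endo.area / np.pi))
        edge_dist = min(pole[0], pole[1],
                        roi_img.shape[0] - 1 - pole[0],
                        roi_img.shape[1] - 1 - pole[1])
        r_max = cfg.r_max_factor * r_eq
        if context is not None and context.epi is not None:
            prev_epi_roi = context.epi.translated(-c0, -r0)
            prev_rmax = float(radii_at_angles(prev_epi_roi, (ex, ey),
                                              cfg.n_angles).max())
            r_max = max(r_max, prev_rmax
                        + (cfg.prev_epi_dilation + 4.0) * cfg.radial_step)
        r_max = max(r_max, float(endo_radii.max()) + 6.0 * cfg.radial_step)
        r_max = min(r_max, edge_dist - 1.0)
        M = int(round(r_max / cfg.radial_step)) + 1
        polar = polar_transform(roi_img, pole, r_max, M, cfg.n_angles)

        stage = "edge-map"
        feat = edge_feature(polar, cfg.edge_smooth_sigma)

        stage = "search-mask"
        from scipy import ndimage as _ndi
        bright_polar = polar_transform((roi_img >= search.chosen).astype(float),
                                       pole, r_max, M, cfg.n_angles).values >= 0.5
        if cfg.bright_dilation_rows > 0:
            bright_polar = _ndi.binary_dilation(
                bright_polar, structure=np.ones((3, 3), bool),
                iterations=cfg.bright_dilation_rows)
        prev_epi_polar = None
        if context is not None and context.epi is not None:
            prev_epi_full = contour_to_mask(context.epi, image.shape)
            prev_epi_roi = roi.extract(prev_epi_full).astype(float)
            prev_epi_polar = polar_transform(prev_epi_roi, pole, r_max, M,
                                             cfg.n_angles).values >= 0.5
        mask = build_search_mask((M, cfg.n_angles),
                                 endo_radii / polar.radial_step,
                                 bright_polar, prev_epi_polar,
                                 margin=cfg.endo_margin_rows,
                                 prev_dilation=cfg.prev_epi_dilation)

        stage = "dp"
        costmap = dp_optimal_path(feat, mask,
                                  DPParams(cfg.delta, cfg.dp_weight,
                                           cfg.dp_gamma))
        epi = epicardial_contour(costmap, polar)

        stage = "epi-smoothing"
        epi = bezier_smooth(epi, smoothing)
        # enforce strict epi-contains-endo with a small radial clearance
        epi_radii = radii_at_angles(epi, (ex, ey), cfg.n_angles)
        epi_radii = np.maximum(epi_radii, endo_radii + _CONTAIN_MARGIN_PX)
        epi = contour_from_radii(epi_radii, (ex, ey))

        stage = "finalize"
        res.endo = endo.translated(c0, r0)
        res.epi = epi.translated(c0, r0)
        pool_full = np.zeros(image.shape, dtype=bool)
        pool_full[r0:r0 + roi.size, c0:c0 + roi.size] = pool
        res.blood_pool = pool_full
        res.status = "ok"
        res.stage_failed = None
        return res
    except (SegmentationError, ValueError) as exc:
        res.status = "failed"
        res.stage_failed = getattr(exc, "stage", None) or stage
        res.message = str(exc)
        return res


def segment_study(study: Study, config: PipelineConfig | None = None) -> StudyResult:
    """Segment every phase of a study, mid slice outward.

    ED and ES stacks are processed independently with identical parameters;
    the basal and apical marches share only the mid-slice result.  A
    mid-slice failure is a study-level error (there is nothing to propagate).
    """
    if not isinstance(study, Study):
        raise TypeError("study must be a Study")
    if study.n_slices < 3:
        raise ValueError("need at least 3 slices to segment a study")
    cfg = config or PipelineConfig()
    mid = cfg.mid_slice_index if cfg.mid_slice_index is not None else study.mid_index
    if not (0 <= mid < study.n_slices):
        raise ValueError(f"mid slice index {mid} out of range")

    results: dict[str, list[SliceResult]] = {}
    log: list[str] = []
    for phase in study.phases:
        slices = study.get_phase(phase)
        mid_res = segment_slice(slices[mid], None, cfg, direction=None)
        if mid_res.status != "ok":
            raise LvsegError(
                f"mid-slice segmentation failed in phase {phase} at stage "
                f"{mid_res.stage_failed}: {mid_res.message}")
        out: list[SliceResult | None] = [None] * study.n_slices
        out[mid] = mid_res
        log.append(f"{phase}: mid slice {mid} ok")
        ctx = mid_res
        for i in range(mid - 1, -1, -1):          # toward the base
            r = segment_slice(slices[i], ctx, cfg, direction="base")
            out[i] = r
            log.append(f"{phase}: slice {i} {r.status}"
                       + (f" ({r.stage_failed}: {r.message})"
                          if r.status == "failed" else "")
                       + (" LVOT" if r.lvot is not None and r.lvot.has_lvot
                          else ""))
            if r.status == "ok":
                ctx = r
        ctx = mid_res
        for i in range(mid + 1, study.n_slices):  # toward the apex
            r = segment_slice(slices[i], ctx, cfg, direction="apex")
            out[i] = r
            log.append(f"{phase}: slice {i} {r.status}"
                       + (f" ({r.stage_failed}: {r.message})"
                          if r.status == "failed" else ""))
            if r.status == "ok":
                ctx = r
        results[phase] = out  # type: ignore[assignment]
    return StudyResult(results, cfg, log)
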