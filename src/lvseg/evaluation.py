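"""Challenge-style evaluation metrics and clinical indices.

* average perpendicular distance (APD): mean over the automatic contour's
  points of the minimal distance to the expert polyline, in mm; a contour is
  "good" when its APD is strictly below 5 mm, and percentage of good contours
  is reported over all evaluated contours;
* Dice overlap 2|A n B| / (|A| + |B|) of the enclosed regions;
* cavity/epicardial volumes by slice summation (enclosed area x pixel area x
  slice spacing), ejection fraction EF = (EDV - ESV) / EDV x 100 and LV mass
  LVM = (epicardial ED volume - cavity ED volume) x myocardial density
  (default 1.05 g/mL);
* ordinary-least-squares regression and Bland-Altman agreement between
  automatic and expert values.

APD is one-directional (automatic -> expert) by default, matching the
challenge wording; pass ``symmetric=True`` for the average of both
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import Contour, contour_to_mask

__all__ = ["ContourPair", "VolumeSet", "average_perpendicular_distance",
           "good_contour", "percent_good", "dice", "dice_contours",
           "cavity_volume", "ejection_fraction", "lv_mass",
           "agreement_stats", "GOOD_CONTOUR_MM", "MYO_DENSITY_G_PER_ML"]

GOOD_CONTOUR_MM = 5.0
MYO_DENSITY_G_PER_ML = 1.05


@dataclass
class ContourPair:
    auto: Contour
    manual: Contour
    pixel_spacing_mm: float = 1.0


@dataclass
class VolumeSet:
    endo_ED: float   # mL
    epi_ED: float
    endo_ES: float

    def __post_init__(self) -> None:
        if not (self.epi_ED >= self.endo_ED >= 0):
            raise ValueError("need epi_ED >= endo_ED >= 0")


def _min_dist_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance of each point to the closed polyline through `poly`."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a                                  # (S, 2)
    ap = points[:, None, :] - a[None, :, :]     # (P, S, 2)
    denom = np.einsum("sd,sd->s", ab, ab)
    denom = np.where(denom < 1e-12, 1.0, denom)
    t = np.clip(np.einsum("psd,sd->ps", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def average_perpendicular_distance(pair: ContourPair,
                                   symmetric: bool = False) -> float:
    """Mean distance (mm) from the automatic contour to the expert polyline."""
    d1 = _min_dist_to_polyline(pair.auto.points, pair.manual.points).mean()
    if symmetric:
        d2 = _min_dist_to_polyline(pair.manual.points, pair.auto.points).mean()
        d1 = 0.5 * (d1 + d2)
    return float(d1 * pair.pixel_spacing_mm)


def good_contour(pair: ContourPair) -> bool:
    """Good iff APD < 5 mm (strict)."""
    return average_perpendicular_distance(pair) < GOOD_CONTOUR_MM


def percent_good(pairs: list[ContourPair]) -> float:
    if not pairs:
        raise ValueError("no contour pairs to evaluate")
    return 100.0 * sum(good_contour(p) for p in pairs) / len(pairs)


def dice(region_a: np.ndarray, region_b: np.ndarray) -> float:
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("regions must share a frame")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("both regions are empty")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def dice_contours(auto: Contour, manual: Contour,
                  shape: tuple[int, int]) -> float:
    """Dice of the filled regions of two contours rasterized on `shape`."""
    return dice(contour_to_mask(auto, shape), contour_to_mask(manual, shape))


def cavity_volume(contours: list[Contour],
                  pixel_spacing_mm: tuple[float, float],
                  slice_spacing_mm: float) -> float:
    """Slice-summation volume in mL: sum of enclosed area x spacing."""
    if not contours:
        raise ValueError("need at least one contour")
    if min(pixel_spacing_mm) <= 0 or slice_spacing_mm <= 0:
        raise ValueError("spacings must be strictly positive")
    px_area = pixel_spacing_mm[0] * pixel_spacing_mm[1]
    area_px = sum(c.area for c in contours)
    return float(area_px * px_area * slice_spacing_mm / 1000.0)


def ejection_fraction(vols: VolumeSet) -> float:
    if vols.endo_ED <= 0:
        raise ValueError("end-diastolic cavity volume must be positive")
    return 100.0 * (vols.endo_ED - vols.endo_ES) / vols.endo_ED


def lv_mass(vols: VolumeSet,
            density_g_per_ml: float = MYO_DENSITY_G_PER_ML) -> float:
    myo = vols.epi_ED - vols.endo_ED
    if myo < 0:
        raise ValueError("negative myocardial volume")
    return myo * density_g_per_ml


def agreement_stats(auto_values, expert_values) -> dict:
    """OLS regression of auto on expert plus Bland-Altman agreement."""
    a = np.asarray(auto_values, dtype=float)
    e = np.asarray(expert_values, dtype=float)
    if a.shape != e.shape or a.size < 3:
        raise ValueError("need equal-length value lists with >= 3 entries")
    if np.var(e) == 0:
        raise ValueError("expert values have zero variance")
    slope, intercept = np.polyfit(e, a, 1)
    fitted = slope * e + intercept
    ss_res = float(np.sum((a - fitted) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    diff = a - e
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r2),
        "bias": bias,
        "limits_of_agreement": (bias - 1.96 * sd, bias + 1.96 * sd),
    }
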