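"""Deterministic synthetic cine-MR phantom of the left ventricle.

Each slice contains a bright circular blood pool inside a darker myocardial
annulus, a moderately bright background (myocardium/background contrast is
deliberately lower than myocardium/pool contrast), an adjacent bright
right-ventricle pool, and a bright pericardial-fat arc outside the wall.
Radii taper linearly from base (slice 0) to apex; end-systole scales the
cavity radius by ``es_scale`` while the epicardial outline is shared between
phases (the wall thickens in systole).  Optionally the basal slice opens a
left-ventricular-outflow-tract (LVOT) channel: a bright wedge of pool
intensity breaching the wall, sized so the blood pool's convex-hull major
axis exceeds the next slice's by construction.

Seeded additive Gaussian noise and a smooth multiplicative polynomial bias
field are applied after the ground-truth masks/contours are drawn.  Analytic
volumes use the same slice-summation quadrature as the evaluation module
(sum of pi r^2 times pixel area times slice spacing), so the phantom's
ejection fraction and mass have closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_io import Contour, SliceImage, Study

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom_study"]

_N_TRUTH_POINTS = 180


@dataclass
class PhantomSpec:
    n_slices: int = 8
    image_size: int = 128
    endo_radius_base: float = 22.0
    endo_radius_apex: float = 10.0
    wall_thickness: float = 8.0
    intensities: dict = field(default_factory=lambda: {
        "pool": 200.0, "myocardium": 60.0, "background": 80.0,
        "rv_pool": 180.0, "fat": 220.0})
    noise_sd: float = 8.0
    bias_field_amplitude: float = 0.1
    lvot: bool = False
    lvot_arc_deg: float = 40.0
    lvot_reach: float = 18.0          # channel extent beyond the epicardium, px
    es_scale: float = 0.7
    center_drift: tuple[float, float] = (0.5, 0.3)   # (row, col) px per slice
    pixel_spacing: tuple[float, float] = (1.25, 1.25)
    slice_spacing_mm: float = 9.0
    phases: tuple[str, ...] = ("ED", "ES")
    seed: int = 0

    def __post_init__(self) -> None:
        it = self.intensities
        if not (it["pool"] > it["background"] > it["myocardium"]):
            raise ValueError("phantom requires pool > background > myocardium "
                             "intensities")
        if self.wall_thickness < 2:
            raise ValueError("wall_thickness must be >= 2 px "
                             "(degenerate annulus)")
        if not (0 < self.endo_radius_apex <= self.endo_radius_base):
            raise ValueError("radii must taper monotonically to the apex")
        if self.n_slices < 3:
            raise ValueError("need at least 3 slices")

    def endo_radius(self, slice_index: int, phase: str = "ED") -> float:
        f = slice_index / (self.n_slices - 1)
        r = self.endo_radius_base + f * (self.endo_radius_apex
                                         - self.endo_radius_base)
        return r * (self.es_scale if phase == "ES" else 1.0)

    def epi_radius(self, slice_index: int) -> float:
        # outer outline shared by both phases (wall thickens in systole)
        return self.endo_radius(slice_index, "ED") + self.wall_thickness

    def center(self, slice_index: int) -> tuple[float, float]:
        c = (self.image_size - 1) / 2.0
        return (c + self.center_drift[0] * slice_index,
                c + self.center_drift[1] * slice_index)


@dataclass
class PhantomTruth:
    """Per-phase ground truth: contours, masks and analytic volumes."""

    endo_contours: dict        # phase -> list[Contour], base -> apex
    epi_contours: dict
    endo_masks: dict           # phase -> list[np.ndarray]
    epi_masks: dict
    pool_masks: dict
    analytic_endo_ml: dict     # phase -> closed-form cavity volume, mL
    analytic_epi_ml: dict


def _circle_contour(center_rc, radius, n=_N_TRUTH_POINTS) -> Contour:
    theta = 2.0 * np.pi * np.arange(n) / n
    x = center_rc[1] + radius * np.cos(theta)
    y = center_rc[0] + radius * np.sin(theta)
    return Contour(np.column_stack([x, y]))


def _disk(shape, center_rc, radius) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius ** 2


def _bias_field(shape, amplitude) -> np.ndarray:
    """Smooth multiplicative low-order polynomial bias in [1-a, 1+a]."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    xn = 2.0 * cc / (shape[1] - 1) - 1.0
    yn = 2.0 * rr / (shape[0] - 1) - 1.0
    poly = 0.5 * xn + 0.3 * yn + 0.2 * xn * yn
    return 1.0 + amplitude * poly


def _render_slice(spec: PhantomSpec, i: int, phase: str) -> np.ndarray:
    it = spec.intensities
    shape = (spec.image_size, spec.image_size)
    center = spec.center(i)
    r_endo = spec.endo_radius(i, phase)
    r_epi = spec.epi_radius(i)

    img = np.full(shape, it["background"])
    img[_disk(shape, center, r_epi)] = it["myocardium"]
    img[_disk(shape, center, r_endo)] = it["pool"]

    # right-ventricle crescent: bright disk left of the LV, clipped outside it
    rv_center = (center[0], center[1] - (r_epi + 11.0))
    rv = _disk(shape, rv_center, 9.0) & ~_disk(shape, center, r_epi + 2.0)
    img[rv] = it["rv_pool"]

    # pericardial-fat arc outside the wall (lower-right sector)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    rad = np.hypot(rr - center[0], cc - center[1])
    ang = np.mod(np.arctan2(rr - center[0], cc - center[1]), 2 * np.pi)
    fat = ((rad >= r_epi + 6.0) & (rad <= r_epi + 11.0)
           & (ang >= np.deg2rad(20)) & (ang <= np.deg2rad(80)))
    img[fat] = it["fat"]

    if spec.lvot and i == 0:
        # bright wedge breaching the wall upward (negative y direction)
        half = np.deg2rad(spec.lvot_arc_deg) / 2.0
        ang_c = np.mod(ang - np.deg2rad(270), 2 * np.pi)
        wedge = ((rad <= r_epi + spec.lvot_reach)
                 & ((ang_c <= half) | (ang_c >= 2 * np.pi - half)))
        img[wedge] = it["pool"]
    return img


def _analytic_volume(radii_px, spec: PhantomSpec) -> float:
    """Stacked-disk closed form: sum pi r^2 * pixel area * spacing, in mL."""
    px_area = spec.pixel_spacing[0] * spec.pixel_spacing[1]
    return float(np.sum(np.pi * np.square(radii_px)) * px_area
                 * spec.slice_spacing_mm / 1000.0)


def generate_phantom_study(spec: PhantomSpec | None = None):
    """Generate (Study, PhantomTruth) for the given spec.

    Ground truth is drawn from the noiseless geometry; noise and bias are
    applied afterwards from a generator seeded by ``spec.seed``, so equal
    seeds give bit-identical studies.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_size, spec.image_size)
    bias = _bias_field(shape, spec.bias_field_amplitude)

    slices_by_phase: dict[str, list[SliceImage]] = {}
    endo_c, epi_c = {}, {}
    endo_m, epi_m, pool_m = {}, {}, {}
    vol_endo, vol_epi = {}, {}
    for phase in spec.phases:
        slices, ec, pc, em, pm, bm = [], [], [], [], [], []
        for i in range(spec.n_slices):
            clean = _render_slice(spec, i, phase)
            noisy = clean * bias + rng.normal(0.0, spec.noise_sd, shape)
            noisy = np.clip(noisy, 0.0, None)
            slices.append(SliceImage(noisy, spec.pixel_spacing, i, phase,
                                     spec.slice_spacing_mm))
            center = spec.center(i)
            r_en = spec.endo_radius(i, phase)
            r_ep = spec.epi_radius(i)
            ec.append(_circle_contour(center, r_en))
            pc.append(_circle_contour(center, r_ep))
            em.append(_disk(shape, center, r_en))
            pm.append(_disk(shape, center, r_ep))
            bm.append(_disk(shape, center, r_en))  # true cavity (no LVOT arm)
        slices_by_phase[phase] = slices
        endo_c[phase], epi_c[phase] = ec, pc
        endo_m[phase], epi_m[phase], pool_m[phase] = em, pm, bm
        radii = np.array([spec.endo_radius(i, phase)
                          for i in range(spec.n_slices)])
        vol_endo[phase] = _analytic_volume(radii, spec)
        radii_epi = np.array([spec.epi_radius(i)
                              for i in range(spec.n_slices)])
        vol_epi[phase] = _analytic_volume(radii_epi, spec)

    study = Study(slices_by_phase, mid_index=spec.n_slices // 2)
    truth = PhantomTruth(endo_c, epi_c, endo_m, epi_m, pool_m,
                         vol_endo, vol_epi)
    return study, truth
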