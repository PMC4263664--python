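"""Contour smoothing: ideal low-pass 1-D FFT on polar radii and closed
piecewise-cubic Bezier (periodic B-spline) fitting.

``fft_smooth`` implements rho' = IFFT(H . FFT(rho)) where rho are the
distances of the contour points to their center and H is an ideal (brick
wall) low-pass filter keeping the DC term and the first ``keep_harmonics``
harmonics on both sides of the spectrum.

``bezier_smooth`` fits a closed curve of cubic arcs with C1-continuous joins
by least squares: the curve is parameterized as a periodic uniform cubic
B-spline (every span of which is exactly a cubic Bezier segment), the control
points are solved from an arc-length resampling of the input polygon, and the
result is resampled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import Contour

__all__ = ["SmoothingParams", "fft_smooth", "bezier_smooth", "radii_at_angles",
           "contour_from_radii"]


@dataclass
class SmoothingParams:
    keep_harmonics: int = 8
    bezier_segments: int = 16
    bezier_samples: int = 180

    def __post_init__(self) -> None:
        if self.keep_harmonics < 1:
            raise ValueError("keep_harmonics must be >= 1")
        if self.bezier_samples < 16:
            raise ValueError("bezier_samples must be >= 16")
        if self.bezier_segments < 4:
            raise ValueError("bezier_segments must be >= 4")


def fft_smooth(radii: np.ndarray, keep_harmonics: int = 8) -> np.ndarray:
    """Ideal low-pass filter of a periodic radius sequence.

    Harmonics with two-sided index above ``keep_harmonics`` are zeroed; the DC
    coefficient (mean radius) is always preserved exactly.
    """
    rho = np.asarray(radii, dtype=float)
    n = rho.size
    if n < 4:
        raise ValueError("need at least 4 radii")
    if np.any(rho <= 0):
        raise ValueError("radii must be strictly positive")
    spectrum = np.fft.fft(rho)
    harmonic = np.minimum(np.arange(n), n - np.arange(n))  # two-sided index
    spectrum[harmonic > keep_harmonics] = 0.0
    out = np.fft.ifft(spectrum)
    if np.max(np.abs(out.imag)) > 1e-9:
        raise AssertionError("unexpected imaginary residue in inverse FFT")
    out = out.real
    if np.any(out <= 0):
        raise ValueError("over-aggressive cutoff produced non-positive radii")
    return out


# ---------------------------------------------------------------------------
# periodic cubic B-spline least squares ("Bezier fitting")
# ---------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    """Uniform cubic B-spline bump with support [0, 4)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    m = (t >= 0) & (t < 1)
    u = t[m]
    out[m] = u ** 3 / 6.0
    m = (t >= 1) & (t < 2)
    u = t[m] - 1.0
    out[m] = (-3 * u ** 3 + 3 * u ** 2 + 3 * u + 1) / 6.0
    m = (t >= 2) & (t < 3)
    u = t[m] - 2.0
    out[m] = (3 * u ** 3 - 6 * u ** 2 + 4) / 6.0
    m = (t >= 3) & (t < 4)
    u = t[m] - 3.0
    out[m] = (1.0 - u) ** 3 / 6.0
    return out


def _periodic_basis(u: np.ndarray, n_ctrl: int) -> np.ndarray:
    """(len(u), n_ctrl) design matrix of the periodic uniform cubic B-spline."""
    A = np.zeros((u.size, n_ctrl))
    for k in range(n_ctrl):
        A[:, k] = _bspline3(np.mod(u - k, n_ctrl))
    return A


def _resample_closed_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Uniform arc-length resampling of a closed polygon to n points."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour (zero perimeter)")
    target = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def bezier_smooth(contour: Contour,
                  params: SmoothingParams | None = None) -> Contour:
    """Least-squares closed piecewise-cubic fit of a contour.

    The input polygon is densified by arc length, control points of a closed
    C1 piecewise-cubic curve are fit by least squares over
    ``bezier_segments`` arcs, and the curve is sampled at ``bezier_samples``
    points.
    """
    params = params or SmoothingParams()
    if len(contour) < 4:
        raise ValueError("need at least 4 contour points to smooth")
    n_ctrl = params.bezier_segments
    data = _resample_closed_polyline(contour.points, max(4 * n_ctrl, 64))
    u_data = np.arange(data.shape[0]) * (n_ctrl / data.shape[0])
    A = _periodic_basis(u_data, n_ctrl)
    ctrl, *_ = np.linalg.lstsq(A, data, rcond=None)
    u_out = np.arange(params.bezier_samples) * (n_ctrl / params.bezier_samples)
    out = _periodic_basis(u_out, n_ctrl) @ ctrl
    return Contour(out)


# ---------------------------------------------------------------------------
# polar helpers shared by the pipeline
# ---------------------------------------------------------------------------

def radii_at_angles(contour: Contour, center: tuple[float, float],
                    n_angles: int) -> np.ndarray:
    """Radii of a star-shaped contour about (cx, cy) at n uniform angles.

    Angles follow the package polar convention theta_j = 2 pi j / N with
    x = cx + r cos(theta), y = cy + r sin(theta).
    """
    cx, cy = center
    dx = contour.points[:, 0] - cx
    dy = contour.points[:, 1] - cy
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    r = np.hypot(dx, dy)
    order = np.argsort(theta)
    ts, rs = theta[order], r[order]
    ts_ext = np.concatenate([ts[-1:] - 2 * np.pi, ts, ts[:1] + 2 * np.pi])
    rs_ext = np.concatenate([rs[-1:], rs, rs[:1]])
    target = 2.0 * np.pi * np.arange(n_angles) / n_angles
    return np.interp(target, ts_ext, rs_ext)


def contour_from_radii(radii: np.ndarray,
                       center: tuple[float, float]) -> Contour:
    """Inverse of :func:`radii_at_angles` at uniform angles."""
    cx, cy = center
    n = len(radii)
    theta = 2.0 * np.pi * np.arange(n) / n
    x = cx + radii * np.cos(theta)
    y = cy + radii * np.sin(theta)
    return Contour(np.column_stack([x, y]))
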