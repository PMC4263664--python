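"""Study / contour I/O and the geometric primitives carried through the pipeline.

Coordinate convention (used everywhere in the package): 0-based pixel indices,
a point is ``(x, y) = (column, row)`` with pixel centers at integer
coordinates.  Contour text files store one ``"x y"`` pair per line in that
order, matching the Sunnybrook/MICCAI challenge manual-contour files.  The
challenge never documents whether its coordinates are 0- or 1-based; 0-based
is adopted here.

Two study layouts are readable:

* a DICOM series (one file per slice, sorted by slice-location tags), and
* a plain array-stack fixture: a directory of ``.npy`` 2-D arrays plus a
  ``meta.yaml`` sidecar, so tests and phantom round trips never need DICOM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.draw import polygon2mask

from .errors import StudyReadError

__all__ = [
    "SliceImage",
    "Study",
    "Contour",
    "read_study",
    "read_contour_file",
    "write_contour_file",
    "contour_to_mask",
]

FIXTURE_META = "meta.yaml"
_CONTOUR_FMT = "{:.2f} {:.2f}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SliceImage:
    """One short-axis frame with its acquisition geometry.

    ``slice_index`` counts from the base (0) toward the apex;
    ``slice_spacing_mm`` is the center-to-center distance to the adjacent
    slice.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]  # (row_mm, col_mm)
    slice_index: int
    phase: str = "other"  # "ED", "ES" or "other"
    slice_spacing_mm: float = 8.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 32:
            raise ValueError(
                f"slice pixels must be a 2-D array with >=32 rows and columns, "
                f"got shape {self.pixels.shape}"
            )
        if np.any(self.pixels < 0):
            raise ValueError("slice intensities must be non-negative")
        r_mm, c_mm = self.pixel_spacing
        if r_mm <= 0 or c_mm <= 0:
            raise ValueError("pixel_spacing entries must be strictly positive")
        if self.slice_spacing_mm <= 0:
            raise ValueError("slice_spacing_mm must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Study:
    """Slices ordered base -> apex, grouped by cardiac phase."""

    slices_by_phase: dict[str, list[SliceImage]]
    mid_index: int

    def __post_init__(self) -> None:
        n = {len(v) for v in self.slices_by_phase.values()}
        if len(n) > 1:
            raise ValueError("all phases must contain the same number of slices")
        if not (0 <= self.mid_index < self.n_slices):
            raise ValueError(f"mid_index {self.mid_index} out of range")

    @property
    def phases(self) -> list[str]:
        return list(self.slices_by_phase)

    @property
    def n_slices(self) -> int:
        return len(next(iter(self.slices_by_phase.values())))

    def get_phase(self, phase: str) -> list[SliceImage]:
        return self.slices_by_phase[phase]


class Contour:
    """Closed planar polygon, counter-clockwise in image (x=col, y=row) frame.

    The polygon is implicitly closed (last point connects to the first) and is
    normalized to counter-clockwise orientation, i.e. positive shoelace area
    in the (x, y) frame.
    """

    def __init__(self, points: np.ndarray, orient: bool = True):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("a contour needs >= 3 (x, y) points")
        # drop consecutive duplicates (incl. an explicitly repeated endpoint)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
        if np.all(np.abs(pts[-1] - pts[0]) <= 1e-12) and keep[-1]:
            keep[-1] = False
        pts = pts[keep]
        if len(pts) < 3:
            raise ValueError("contour degenerate after removing duplicate points")
        if orient and _shoelace(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def signed_area(self) -> float:
        return _shoelace(self.points)

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def centroid(self) -> tuple[float, float]:
        """Area centroid as (x, y)."""
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-12:
            return float(x.mean()), float(y.mean())
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return float(cx), float(cy)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + np.array([dx, dy]), orient=False)

    def is_simple(self) -> bool:
        """Exhaustive segment-intersection check (quadratic; fine <= 360 pts)."""
        p = self.points
        n = len(p)
        seg = [(p[i], p[(i + 1) % n]) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if j == i or (j + 1) % n == i or (i + 1) % n == j:
                    continue  # shared endpoint with neighbor
                if _segments_intersect(*seg[i], *seg[j]):
                    return False
        return True


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) / 2.0)


def _segments_intersect(a, b, c, d) -> bool:
    def orient(p, q, r):
        v = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    if o1 != o2 and o3 != o4:
        return True
    return False


def contour_to_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize the enclosed region to a boolean mask of the given shape."""
    # polygon2mask expects (row, col) vertices
    rc = contour.points[:, ::-1]
    return polygon2mask(shape, rc)


# ---------------------------------------------------------------------------
# contour files
# ---------------------------------------------------------------------------

def read_contour_file(path) -> Contour:
    """Read a Sunnybrook-style contour text file (one ``"x y"`` per line)."""
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two numbers, got {line!r}"
                )
            try:
                x, y = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: could not parse {line!r}"
                ) from exc
            pts.append((x, y))
    if len(pts) < 3:
        raise ValueError(f"{path}: a contour needs >= 3 points, got {len(pts)}")
    return Contour(np.array(pts), orient=False)


def write_contour_file(contour: Contour, path) -> None:
    """Write one ``"x y"`` line per point with fixed 2-decimal formatting."""
    with open(path, "w") as fh:
        for x, y in contour.points:
            fh.write(_CONTOUR_FMT.format(x, y) + "\n")


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def read_study(path, phase_selector: str = "all", es_frame: int | None = None) -> Study:
    """Read a study directory (DICOM series or array-stack fixture).

    Slices are sorted base -> apex by their slice-location tag (ascending),
    never by file name.  ``mid_index = n_slices // 2``.

    phase_selector : "ED", "ES" or "all"
        For the fixture format, phases come from the sidecar; ``"all"`` keeps
        every phase present.  For a single-frame-per-location DICOM series the
        frames are labelled with the selected phase; multi-frame series use
        trigger time (earliest = ED, ``es_frame`` index = ES).
    """
    path = Path(path)
    if not path.is_dir():
        raise StudyReadError(f"{path} is not a directory")
    if (path / FIXTURE_META).exists():
        return _read_fixture(path, phase_selector)
    return _read_dicom(path, phase_selector, es_frame)


def _read_fixture(path: Path, phase_selector: str) -> Study:
    with open(path / FIXTURE_META) as fh:
        meta = yaml.safe_load(fh)
    for key in ("pixel_spacing", "slice_spacing_mm", "slices"):
        if key not in meta:
            raise StudyReadError(f"{path}: fixture metadata missing field {key!r}")
    spacing = tuple(float(v) for v in meta["pixel_spacing"])
    slice_spacing = float(meta["slice_spacing_mm"])

    records = []
    for entry in meta["slices"]:
        phase = str(entry.get("phase", "other"))
        if phase_selector != "all" and phase != phase_selector:
            continue
        arr = np.load(path / entry["file"])
        records.append((float(entry["location"]), phase, arr))
    if not records:
        raise StudyReadError(f"{path}: no readable slices for phase {phase_selector!r}")
    shapes = {r[2].shape for r in records}
    if len(shapes) > 1:
        raise StudyReadError(f"{path}: mixed image sizes {sorted(shapes)}")

    by_phase: dict[str, list[SliceImage]] = {}
    for phase in sorted({r[1] for r in records}):
        rec = sorted((r for r in records if r[1] == phase), key=lambda r: r[0])
        by_phase[phase] = [
            SliceImage(arr, spacing, i, phase, slice_spacing)
            for i, (_, _, arr) in enumerate(rec)
        ]
    n = len(next(iter(by_phase.values())))
    return Study(by_phase, mid_index=n // 2)


def _read_dicom(path: Path, phase_selector: str, es_frame: int | None) -> Study:
    import pydicom

    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
            _ = ds.pixel_array
        except Exception:
            continue
        datasets.append(ds)
    if not datasets:
        raise StudyReadError(f"{path}: no readable DICOM images")

    def location(ds) -> float:
        if hasattr(ds, "SliceLocation"):
            return float(ds.SliceLocation)
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        raise StudyReadError(
            f"{path}: DICOM dataset missing slice position metadata "
            "(SliceLocation / ImagePositionPatient)"
        )

    for ds in datasets:
        if not hasattr(ds, "PixelSpacing"):
            raise StudyReadError(f"{path}: DICOM dataset missing field PixelSpacing")

    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) > 1:
        raise StudyReadError(f"{path}: mixed image sizes {sorted(shapes)}")

    # group by slice location, order frames at one location by trigger time
    locs = sorted({round(location(ds), 3) for ds in datasets})
    if len(locs) > 1:
        slice_spacing = float(np.median(np.diff(locs)))
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 8.0))

    def frames_at(loc):
        group = [ds for ds in datasets if round(location(ds), 3) == loc]
        group.sort(key=lambda ds: float(getattr(ds, "TriggerTime", 0.0)))
        return group

    by_phase: dict[str, list[SliceImage]] = {}
    wanted = ["ED", "ES"] if phase_selector == "all" else [phase_selector]
    for phase in wanted:
        slices = []
        for i, loc in enumerate(locs):
            group = frames_at(loc)
            if len(group) == 1:
                ds = group[0]
            elif phase == "ED":
                ds = group[0]
            else:
                if es_frame is None:
                    raise StudyReadError(
                        "multi-frame series: ES frame index must be given "
                        "(automatic phase detection is out of scope)"
                    )
                ds = group[min(es_frame, len(group) - 1)]
            spacing = tuple(float(v) for v in ds.PixelSpacing)
            slices.append(
                SliceImage(
                    np.asarray(ds.pixel_array, dtype=float),
                    spacing,
                    i,
                    phase,
                    abs(slice_spacing) if slice_spacing else 8.0,
                )
            )
        by_phase[phase] = slices
    n = len(locs)
    return Study(by_phase, mid_index=n // 2)


def write_fixture_study(study: Study, path) -> None:
    """Write a Study in the array-stack fixture format (npy + meta.yaml)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    some = next(iter(study.slices_by_phase.values()))[0]
    for phase, slices in study.slices_by_phase.items():
        for sl in slices:
            name = f"{phase}_{sl.slice_index:03d}.npy"
            np.save(path / name, sl.pixels)
            entries.append(
                {"file": name, "phase": phase, "location": float(sl.slice_index)}
            )
    meta = {
        "pixel_spacing": [float(v) for v in some.pixel_spacing],
        "slice_spacing_mm": float(some.slice_spacing_mm),
        "slices": entries,
    }
    with open(path / FIXTURE_META, "w") as fh:
        yaml.safe_dump(meta, fh)
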