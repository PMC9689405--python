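"""Computational geometry for AP-pelvis hip measurements.

All quantities are defined relative to the horizontal reference line through
the most inferior points of the ischial tuberosities, so a tilted radiograph
yields the same angles as an upright one:

* **LCEA** (lateral center edge angle of Wiberg) — angle at the femoral-head
  center (CFH) between the perpendicular to the reference line and the ray
  from the CFH to the lateral sourcil.  Positive when the sourcil lies
  lateral to the perpendicular, negative when medial.
* **AIA** (acetabular index angle) — angle between the reference-line
  parallel through the medial sourcil and the medial→lateral sourcil line.
  Positive when the acetabular roof slopes upward laterally.
* **FOI** (foramen obturator index) — ratio of right to left maximum
  obturator-foramen widths, each measured parallel to the reference line.

Coordinates are image coordinates: x = column, y = row, y increasing
*downward*.  "Superior" therefore means *smaller* y relative to the
reference line.  By radiographic convention the patient's right hip appears
on the image left; ``laterality_convention`` flips this when needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely.geometry as sgeom

__all__ = [
    "Point2D",
    "ReferenceLine",
    "CircleFit",
    "LandmarkSet",
    "HipMeasurements",
    "WidthProfile",
    "DegenerateGeometryError",
    "CircleFitError",
    "MissingLandmarkError",
    "make_reference_line",
    "fit_circle_least_squares",
    "signed_perpendicular_offset",
    "compute_lcea",
    "compute_aia",
    "polygon_width_profile",
    "measure_hips",
]

RIGHT_ON_IMAGE_LEFT = "right_on_left"
RIGHT_ON_IMAGE_RIGHT = "right_on_right"

N_WIDTH_LINES = 13  # foramen widths are sampled on 13 reference-parallel lines


class DegenerateGeometryError(ValueError):
    """Raised when landmarks do not define the requested construction."""


class CircleFitError(ValueError):
    """Raised when a circle cannot be fitted (too few or collinear points)."""


class MissingLandmarkError(KeyError):
    """Raised when mandatory landmarks are absent; lists the missing names."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing mandatory landmarks: {', '.join(self.missing)}")


@dataclass(frozen=True)
class Point2D:
    """Image-coordinate point: x = column, y = row (y grows downward)."""

    x: float
    y: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_point(p) -> Point2D:
    if isinstance(p, Point2D):
        return p
    x, y = p
    return Point2D(float(x), float(y))


@dataclass(frozen=True)
class ReferenceLine:
    """Oriented line with unit direction; canonical direction has x ≥ 0.

    The *superior* unit normal is ``(dy, -dx)``: for the canonical
    near-horizontal direction it points toward smaller image rows.
    """

    anchor: Point2D
    direction: tuple[float, float]

    def __post_init__(self):
        dx, dy = self.direction
        if abs(math.hypot(dx, dy) - 1.0) > 1e-12:
            raise ValueError("reference line direction must be a unit vector")
        if dx < 0 or (dx == 0 and dy < 0):
            raise ValueError("reference line direction must be canonical (x-component ≥ 0)")

    @property
    def normal(self) -> tuple[float, float]:
        """Unit normal pointing superior (toward smaller rows)."""
        dx, dy = self.direction
        return (dy, -dx)

    def to_frame(self, p: Point2D) -> tuple[float, float]:
        """Coordinates of ``p`` in the line frame: (along-line u, superior w)."""
        vx = p.x - self.anchor.x
        vy = p.y - self.anchor.y
        dx, dy = self.direction
        nx, ny = self.normal
        return (vx * dx + vy * dy, vx * nx + vy * ny)


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle; ``center`` is the femoral-head center (CFH)."""

    center: Point2D
    radius: float
    rms_residual: float
    n_points: int

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("circle radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms residual must be non-negative")
        if self.n_points < 3:
            raise ValueError("a circle fit needs at least 3 points")


@dataclass
class WidthProfile:
    """Widths of a foramen on reference-parallel lines, superior first."""

    offsets: np.ndarray  # perpendicular (superior) offsets of the lines, px
    widths: np.ndarray  # caliper width of the outline on each line, px

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.offsets.shape != self.widths.shape:
            raise ValueError("offsets and widths must align")
        if np.any(self.widths < 0):
            raise ValueError("widths must be non-negative")

    @property
    def max_width(self) -> float:
        return float(np.max(self.widths))


@dataclass
class LandmarkSet:
    """Named anatomical landmarks for one AP pelvic radiograph.

    ``femoral_head_contour_*`` may be either an ordered point list (≥3) or a
    precomputed :class:`CircleFit`.  ``foramen_outline_*`` are closed simple
    polygons.  All coordinates are pixels; ``pixel_spacing_mm`` converts
    widths to mm when present (angles and FOI are unit-free).
    """

    tuberosity_inferior_right: Point2D | None = None
    tuberosity_inferior_left: Point2D | None = None
    femoral_head_contour_right: list[Point2D] | CircleFit | None = None
    femoral_head_contour_left: list[Point2D] | CircleFit | None = None
    sourcil_medial_right: Point2D | None = None
    sourcil_medial_left: Point2D | None = None
    sourcil_lateral_right: Point2D | None = None
    sourcil_lateral_left: Point2D | None = None
    foramen_outline_right: list[Point2D] | None = None
    foramen_outline_left: list[Point2D] | None = None
    pixel_spacing_mm: float | None = None
    laterality_convention: str = RIGHT_ON_IMAGE_LEFT
    image_id: str = ""

    def __post_init__(self):
        if self.laterality_convention not in (RIGHT_ON_IMAGE_LEFT, RIGHT_ON_IMAGE_RIGHT):
            raise ValueError(f"unknown laterality convention {self.laterality_convention!r}")


@dataclass
class HipMeasurements:
    """Per-radiograph measurement report.

    Angles in degrees; foramen widths in pixels, or mm when the landmark set
    carried a pixel spacing; FOI unit-free.  Per-side failures leave the
    affected values ``None`` and append a human-readable flag.
    """

    image_id: str = ""
    lcea_right: float | None = None
    lcea_left: float | None = None
    aia_right: float | None = None
    aia_left: float | None = None
    foramen_width_right: float | None = None
    foramen_width_left: float | None = None
    foi: float | None = None
    cfh_right: CircleFit | None = None
    cfh_left: CircleFit | None = None
    reference: ReferenceLine | None = None
    width_unit: str = "px"
    flags: list[str] = field(default_factory=list)


def make_reference_line(right_tub: Point2D, left_tub: Point2D) -> ReferenceLine:
    """Reference line adjoining the most inferior ischial-tuberosity points."""
    right_tub = _as_point(right_tub)
    left_tub = _as_point(left_tub)
    dx = left_tub.x - right_tub.x
    dy = left_tub.y - right_tub.y
    norm = math.hypot(dx, dy)
    if norm == 0.0:
        raise DegenerateGeometryError(
            "ischial tuberosity landmarks coincide "
            f"(tuberosity_inferior_right == tuberosity_inferior_left == ({right_tub.x}, {right_tub.y}))"
        )
    dx, dy = dx / norm, dy / norm
    if dx < 0 or (dx == 0 and dy < 0):
        dx, dy = -dx, -dy
    return ReferenceLine(anchor=right_tub, direction=(dx, dy))


def fit_circle_least_squares(points) -> CircleFit:
    """Algebraic (Kåsa) least-squares circle through ``points``.

    Minimizes Σ(x² + y² + Dx + Ey + F)², the classic linear formulation;
    exact for noiseless circles and deterministic.  The reported residual is
    the RMS of radial deviations |dist − r|.
    """
    pts = np.array([[_as_point(p).x, _as_point(p).y] for p in points], dtype=float)
    n = len(pts)
    if n < 3:
        raise CircleFitError(f"circle fit needs ≥3 points, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    # center the data for conditioning; the Kåsa solution is translation-equivariant
    mx, my = x.mean(), y.mean()
    xc, yc = x - mx, y - my
    A = np.column_stack([2 * xc, 2 * yc, np.ones(n)])
    b = xc**2 + yc**2
    svals = np.linalg.svd(np.column_stack([xc, yc]), compute_uv=False)
    if svals[-1] <= 1e-9 * max(svals[0], 1.0):
        raise CircleFitError("points are collinear; no circle fits them")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx**2 + cy**2
    if r2 <= 0:
        raise CircleFitError("degenerate circle fit (non-positive radius)")
    r = math.sqrt(r2)
    dist = np.hypot(xc - cx, yc - cy)
    rms = float(np.sqrt(np.mean((dist - r) ** 2)))
    return CircleFit(center=Point2D(cx + mx, cy + my), radius=float(r), rms_residual=rms, n_points=n)


def signed_perpendicular_offset(p: Point2D, ref: ReferenceLine) -> float:
    """Perpendicular offset of ``p`` from ``ref``; positive = superior."""
    return ref.to_frame(_as_point(p))[1]


def _lateral_sign(side: str, convention: str) -> float:
    """Sign of the along-reference coordinate pointing *lateral* for a side."""
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    right_on_left = convention == RIGHT_ON_IMAGE_LEFT
    if side == "right":
        return -1.0 if right_on_left else 1.0
    return 1.0 if right_on_left else -1.0


def compute_lcea(
    cfh: Point2D,
    lateral_sourcil: Point2D,
    ref: ReferenceLine,
    side: str,
    convention: str = RIGHT_ON_IMAGE_LEFT,
) -> float:
    """Lateral center edge angle in degrees.

    Angle at the CFH between the superior perpendicular to the reference
    line and the CFH→lateral-sourcil ray; positive when the sourcil is
    lateral to the perpendicular, negative when medial.
    """
    cfh = _as_point(cfh)
    src = _as_point(lateral_sourcil)
    if cfh.x == src.x and cfh.y == src.y:
        raise DegenerateGeometryError("lateral sourcil coincides with the femoral-head center")
    du, dw = _frame_vector(src, cfh, ref)
    lat = _lateral_sign(side, convention) * du
    return math.degrees(math.atan2(lat, dw))


def compute_aia(
    medial_sourcil: Point2D,
    lateral_sourcil: Point2D,
    ref: ReferenceLine,
    side: str,
    convention: str = RIGHT_ON_IMAGE_LEFT,
) -> float:
    """Acetabular index angle in degrees.

    Angle between the reference-parallel through the medial sourcil and the
    medial→lateral sourcil line; positive when the lateral sourcil is
    superior to the medial one (up-sloping roof), negative otherwise.
    """
    med = _as_point(medial_sourcil)
    lat_p = _as_point(lateral_sourcil)
    if med.x == lat_p.x and med.y == lat_p.y:
        raise DegenerateGeometryError("medial and lateral sourcil landmarks coincide")
    du, dw = _frame_vector(lat_p, med, ref)
    lat = _lateral_sign(side, convention) * du
    return math.degrees(math.atan2(dw, lat))


def _frame_vector(p: Point2D, origin: Point2D, ref: ReferenceLine) -> tuple[float, float]:
    """(along-line, superior) components of the vector origin→p."""
    vx = p.x - origin.x
    vy = p.y - origin.y
    dx, dy = ref.direction
    nx, ny = ref.normal
    return (vx * dx + vy * dy, vx * nx + vy * ny)


def polygon_width_profile(outline, ref: ReferenceLine, n_lines: int = N_WIDTH_LINES) -> WidthProfile:
    """Caliper widths of a closed outline on ``n_lines`` reference-parallel lines.

    Lines are equally spaced across the outline's perpendicular extent,
    endpoints inclusive, ordered from the superior extent to the inferior
    one.  Width on a line is the outermost-crossing distance (distance
    between the first and last intersection with the outline), matching how
    a caliper would be read on a non-convex foramen.
    """
    if isinstance(outline, sgeom.Polygon):
        poly_xy = np.asarray(outline.exterior.coords, dtype=float)
    else:
        poly_xy = np.array([[_as_point(p).x, _as_point(p).y] for p in outline], dtype=float)
    if len(poly_xy) < 3:
        raise DegenerateGeometryError("foramen outline needs at least 3 vertices")
    # transform to the reference frame so sampling lines are horizontal
    anchor = np.array([ref.anchor.x, ref.anchor.y])
    d = np.array(ref.direction)
    nvec = np.array(ref.normal)
    rel = poly_xy - anchor
    uw = np.column_stack([rel @ d, rel @ nvec])
    poly = sgeom.Polygon(uw)
    if not poly.is_valid or poly.area == 0:
        raise DegenerateGeometryError("foramen outline is not a simple polygon")
    u_min, w_min, u_max, w_max = poly.bounds
    offsets = np.linspace(w_max, w_min, n_lines)  # superior (largest w) first
    pad = (u_max - u_min) + 1.0
    widths = np.empty(n_lines)
    for i, w in enumerate(offsets):
        line = sgeom.LineString([(u_min - pad, w), (u_max + pad, w)])
        inter = line.intersection(poly)
        widths[i] = 0.0 if inter.is_empty else inter.bounds[2] - inter.bounds[0]
    return WidthProfile(offsets=offsets, widths=widths)


_MANDATORY_GLOBAL = ("tuberosity_inferior_right", "tuberosity_inferior_left")
_MANDATORY_PER_SIDE = ("femoral_head_contour_{s}", "sourcil_medial_{s}", "sourcil_lateral_{s}")


def measure_hips(lm: LandmarkSet) -> HipMeasurements:
    """Measure LCEA, AIA, foramen widths and FOI from a landmark set.

    Deterministic: identical input gives bit-identical output.  A side with
    missing or degenerate landmarks is recorded in ``flags`` while the other
    side is still measured; only a radiograph where nothing can be measured
    raises :class:`MissingLandmarkError`.
    """
    missing_global = [name for name in _MANDATORY_GLOBAL if getattr(lm, name) is None]
    if missing_global:
        raise MissingLandmarkError(missing_global)

    out = HipMeasurements(image_id=lm.image_id)
    ref = make_reference_line(lm.tuberosity_inferior_right, lm.tuberosity_inferior_left)
    out.reference = ref
    conv = lm.laterality_convention

    any_side_ok = False
    for side in ("right", "left"):
        missing = [t.format(s=side) for t in _MANDATORY_PER_SIDE if getattr(lm, t.format(s=side)) is None]
        if missing:
            out.flags.append(f"{side}: missing landmarks: {', '.join(missing)}")
            continue
        try:
            contour = getattr(lm, f"femoral_head_contour_{side}")
            cfh = contour if isinstance(contour, CircleFit) else fit_circle_least_squares(contour)
            setattr(out, f"cfh_{side}", cfh)
            lat_src = getattr(lm, f"sourcil_lateral_{side}")
            med_src = getattr(lm, f"sourcil_medial_{side}")
            if signed_perpendicular_offset(lat_src, ref) < signed_perpendicular_offset(cfh.center, ref):
                out.flags.append(f"{side}: lateral sourcil inferior to femoral-head center")
            setattr(out, f"lcea_{side}", compute_lcea(cfh.center, lat_src, ref, side, conv))
            setattr(out, f"aia_{side}", compute_aia(med_src, lat_src, ref, side, conv))
            any_side_ok = True
        except (DegenerateGeometryError, CircleFitError) as exc:
            out.flags.append(f"{side}: {exc}")

    scale = lm.pixel_spacing_mm if lm.pixel_spacing_mm else 1.0
    out.width_unit = "mm" if lm.pixel_spacing_mm else "px"
    widths = {}
    for side in ("right", "left"):
        outline = getattr(lm, f"foramen_outline_{side}")
        if outline is None:
            continue
        try:
            widths[side] = polygon_width_profile(outline, ref).max_width
            setattr(out, f"foramen_width_{side}", widths[side] * scale)
        except DegenerateGeometryError as exc:
            out.flags.append(f"{side}: foramen outline: {exc}")
    if "right" in widths and "left" in widths:
        if widths["left"] <= 0:
            out.flags.append("left foramen width is zero; FOI undefined")
        else:
            out.foi = widths["right"] / widths["left"]
        any_side_ok = any_side_ok or out.foi is not None

    if not any_side_ok:
        raise MissingLandmarkError(
            [t.format(s=s) for s in ("right", "left") for t in _MANDATORY_PER_SIDE if getattr(lm, t.format(s=s)) is None]
            or ["<no measurable structures>"]
        )
    return out


def transform_landmarks(lm: LandmarkSet, matrix: np.ndarray, offset=(0.0, 0.0)) -> LandmarkSet:
    """Apply an affine map ``p ↦ M p + t`` to every landmark (testing aid)."""
    M = np.asarray(matrix, dtype=float)
    t = np.asarray(offset, dtype=float)

    def _tp(p: Point2D) -> Point2D:
        v = M @ p.as_array() + t
        return Point2D(float(v[0]), float(v[1]))

    def _tmany(obj):
        if obj is None:
            return None
        if isinstance(obj, CircleFit):
            raise ValueError("cannot transform a precomputed CircleFit; supply contour points")
        return [_tp(_as_point(p)) for p in obj]

    return replace(
        lm,
        tuberosity_inferior_right=_tp(lm.tuberosity_inferior_right) if lm.tuberosity_inferior_right else None,
        tuberosity_inferior_left=_tp(lm.tuberosity_inferior_left) if lm.tuberosity_inferior_left else None,
        femoral_head_contour_right=_tmany(lm.femoral_head_contour_right),
        femoral_head_contour_left=_tmany(lm.femoral_head_contour_left),
        sourcil_medial_right=_tp(lm.sourcil_medial_right) if lm.sourcil_medial_right else None,
        sourcil_medial_left=_tp(lm.sourcil_medial_left) if lm.sourcil_medial_left else None,
        sourcil_lateral_right=_tp(lm.sourcil_lateral_right) if lm.sourcil_lateral_right else None,
        sourcil_lateral_left=_tp(lm.sourcil_lateral_left) if lm.sourcil_lateral_left else None,
        foramen_outline_right=_tmany(lm.foramen_outline_right),
        foramen_outline_left=_tmany(lm.foramen_outline_left),
    )
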