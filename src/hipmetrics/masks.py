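"""Landmark extraction from per-structure binary segmentation masks.

The upstream segmentation (a deep model in the clinical tool this package
mirrors) is deliberately *not* part of the package: masks are an input
contract.  This module turns binary rasters — pelvis, femoral heads,
sourcils, obturator foramina — into the named landmarks that the geometry
engine consumes:

* tuberosity points: per side, the most inferior pelvis-foreground pixel;
* femoral-head contour: sub-pixel outer boundary, sub-sampled evenly;
* sourcil extents: extremal foreground pixels toward/away from the pelvic
  midline measured *along the reference line*, so a tilted image selects
  the same anatomical pixels;
* foramen widths: caliper widths on 13 reference-parallel lines spanning
  the foramen's perpendicular extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure

from .geometry import (
    RIGHT_ON_IMAGE_LEFT,
    LandmarkSet,
    Point2D,
    ReferenceLine,
    WidthProfile,
    make_reference_line,
    polygon_width_profile,
)

__all__ = [
    "MaskSet",
    "WidthProfile",
    "ExtractionError",
    "extract_tuberosity_points",
    "extract_head_contour",
    "extract_sourcil_extents",
    "foramen_width_profile",
    "compute_foi",
    "masks_to_landmarks",
    "measure_from_masks",
]

STRUCTURES = (
    "pelvis",
    "femoral_head_right",
    "femoral_head_left",
    "sourcil_right",
    "sourcil_left",
    "foramen_right",
    "foramen_left",
)


class ExtractionError(ValueError):
    """Raised when a landmark cannot be extracted from a mask."""


@dataclass
class MaskSet:
    """Per-structure binary masks sharing one image shape.

    Any structure may be ``None``; the corresponding measurements are then
    skipped (and flagged) downstream.  ``pelvis`` is mandatory for the
    reference line.
    """

    pelvis: np.ndarray | None = None
    femoral_head_right: np.ndarray | None = None
    femoral_head_left: np.ndarray | None = None
    sourcil_right: np.ndarray | None = None
    sourcil_left: np.ndarray | None = None
    foramen_right: np.ndarray | None = None
    foramen_left: np.ndarray | None = None
    image_id: str = ""
    pixel_spacing_mm: float | None = None
    laterality_convention: str = RIGHT_ON_IMAGE_LEFT

    def __post_init__(self):
        shapes = {name: getattr(self, name).shape for name in STRUCTURES if getattr(self, name) is not None}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"masks disagree on image shape: {shapes}")
        for name in STRUCTURES:
            m = getattr(self, name)
            if m is not None:
                setattr(self, name, np.asarray(m) > 0)

    @property
    def shape(self) -> tuple[int, int]:
        for name in STRUCTURES:
            m = getattr(self, name)
            if m is not None:
                return m.shape
        raise ValueError("empty MaskSet")


def extract_tuberosity_points(
    pelvis_mask: np.ndarray,
    midline_col: float,
    convention: str = RIGHT_ON_IMAGE_LEFT,
) -> tuple[Point2D, Point2D]:
    """Most inferior pelvis pixel on each side of the midline.

    Ties on the lowest row are broken toward the most medial pixel (closest
    to the midline column), then toward the lowest column index.  Returns
    ``(right, left)`` in patient terms per ``convention``.
    """
    mask = np.asarray(pelvis_mask) > 0
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ExtractionError("pelvis mask is empty")
    out = {}
    for img_side, sel in (("img_left", cols < midline_col), ("img_right", cols >= midline_col)):
        if not np.any(sel):
            raise ExtractionError(f"pelvis mask has no foreground on the {img_side.split('_')[1]} of the midline")
        r, c = rows[sel], cols[sel]
        low = r == r.max()
        r, c = r[low], c[low]
        med = np.abs(c - midline_col)
        best = np.lexsort((c, med))[0]
        out[img_side] = Point2D(float(c[best]), float(r[best]))
    if convention == RIGHT_ON_IMAGE_LEFT:
        return out["img_left"], out["img_right"]
    return out["img_right"], out["img_left"]


def _largest_contour(mask: np.ndarray, flags: list[str] | None, what: str) -> np.ndarray:
    """Sub-pixel outer boundary (x, y columns) of the largest component."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ExtractionError(f"{what} mask is empty")
    labels, n_comp = skmeasure.label(mask, return_num=True)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
        if flags is not None:
            flags.append(f"{what}: {n_comp} components, largest used")
    padded = np.pad(mask, 1).astype(float)
    contours = skmeasure.find_contours(padded, 0.5)
    contour = max(contours, key=len)  # (row, col) vertices in padded frame
    xy = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])
    return xy


def extract_head_contour(head_mask: np.ndarray, n_points: int = 64, flags: list[str] | None = None) -> list[Point2D]:
    """Evenly spaced sub-pixel points along the femoral-head boundary."""
    xy = _largest_contour(head_mask, flags, "femoral head")
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    if arclen[-1] == 0:
        raise ExtractionError("femoral head boundary is degenerate")
    targets = np.linspace(0.0, arclen[-1], n_points, endpoint=False)
    xs = np.interp(targets, arclen, xy[:, 0])
    ys = np.interp(targets, arclen, xy[:, 1])
    return [Point2D(float(x), float(y)) for x, y in zip(xs, ys)]


def extract_sourcil_extents(
    sourcil_mask: np.ndarray,
    ref: ReferenceLine,
    side: str,
    convention: str = RIGHT_ON_IMAGE_LEFT,
    flags: list[str] | None = None,
) -> tuple[Point2D, Point2D]:
    """(medial, lateral) extremes of the sourcil measured along ``ref``.

    Medial is the foreground pixel extremal *toward* the pelvic midline in
    the along-reference direction, lateral the one extremal away from it —
    tilt-safe because the comparison uses the reference frame, not raw x.
    """
    mask = np.asarray(sourcil_mask) > 0
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ExtractionError(f"sourcil mask ({side}) is empty")
    dx, dy = ref.direction
    u = (cols - ref.anchor.x) * dx + (rows - ref.anchor.y) * dy
    # direction of increasing u that points toward the midline for this side
    right_on_left = convention == RIGHT_ON_IMAGE_LEFT
    on_image_left = (side == "right") == right_on_left
    toward_mid = 1.0 if on_image_left else -1.0  # canonical direction has dx ≥ 0
    order = np.lexsort((cols, rows, toward_mid * u))
    lateral_i, medial_i = order[0], order[-1]
    medial = Point2D(float(cols[medial_i]), float(rows[medial_i]))
    lateral = Point2D(float(cols[lateral_i]), float(rows[lateral_i]))
    if medial == lateral and flags is not None:
        flags.append(f"{side}: sourcil degenerate (single extremal pixel); AIA undefined")
    return medial, lateral


def _sharpen_half_pixel_corners(xy: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Restore right-angle corners clipped by marching squares.

    The iso-contour of a binary mask cuts every right-angle corner with a
    half-pixel diagonal.  Where a short diagonal joins a horizontal and a
    vertical edge, replace it by the exact corner point so rectangular
    openings keep their full caliper width at the extreme sampling lines.
    """
    pts = xy[:-1] if np.allclose(xy[0], xy[-1]) else xy
    n = len(pts)
    if n < 4:
        return xy
    keep = []
    i = 0
    while i < n:
        v0, v1, v2, v3 = pts[(i - 1) % n], pts[i], pts[(i + 1) % n], pts[(i + 2) % n]
        seg = v2 - v1
        prev, nxt = v1 - v0, v3 - v2
        diag = abs(seg[0]) > tol and abs(seg[1]) > tol and np.hypot(*seg) < 0.9
        prev_v = abs(prev[0]) < tol and abs(prev[1]) > tol
        prev_h = abs(prev[1]) < tol and abs(prev[0]) > tol
        nxt_v = abs(nxt[0]) < tol and abs(nxt[1]) > tol
        nxt_h = abs(nxt[1]) < tol and abs(nxt[0]) > tol
        if diag and ((prev_v and nxt_h) or (prev_h and nxt_v)):
            corner = np.array([v1[0], v2[1]]) if prev_v else np.array([v2[0], v1[1]])
            keep.append(corner)
            i += 2  # consumed v1 and v2
        else:
            keep.append(v1)
            i += 1
    out = np.asarray(keep)
    return np.vstack([out, out[:1]])


def foramen_outline(foramen_mask: np.ndarray, flags: list[str] | None = None) -> list[Point2D]:
    """Sub-pixel closed outline of the (largest) foramen component."""
    xy = _sharpen_half_pixel_corners(_largest_contour(foramen_mask, flags, "foramen"))
    return [Point2D(float(x), float(y)) for x, y in xy]


def foramen_width_profile(foramen_mask: np.ndarray, ref: ReferenceLine, flags: list[str] | None = None) -> WidthProfile:
    """Widths of the foramen on 13 reference-parallel lines (superior first)."""
    return polygon_width_profile(foramen_outline(foramen_mask, flags), ref)


def compute_foi(right: WidthProfile, left: WidthProfile) -> float:
    """Foramen obturator index: right max width over left max width."""
    if left.max_width <= 0:
        raise ExtractionError("left foramen maximum width is zero; FOI undefined")
    if right.max_width <= 0:
        raise ExtractionError("right foramen maximum width is zero; FOI undefined")
    return right.max_width / left.max_width


def _midline_column(masks: MaskSet) -> float:
    """Pelvic midline column: mean femoral-head centroid column if both heads
    are present, else the image center column."""
    cols = []
    for name in ("femoral_head_right", "femoral_head_left"):
        m = getattr(masks, name)
        if m is not None and m.any():
            cols.append(float(np.nonzero(m)[1].mean()))
    if len(cols) == 2:
        return 0.5 * (cols[0] + cols[1])
    return masks.shape[1] / 2.0


def masks_to_landmarks(masks: MaskSet, n_contour_points: int = 64) -> tuple[LandmarkSet, list[str]]:
    """Full mask → landmark extraction; returns the set and warning flags."""
    flags: list[str] = []
    if masks.pelvis is None:
        raise ExtractionError("pelvis mask is required for the reference line")
    midline = _midline_column(masks)
    tub_r, tub_l = extract_tuberosity_points(masks.pelvis, midline, masks.laterality_convention)
    ref = make_reference_line(tub_r, tub_l)
    lm = LandmarkSet(
        tuberosity_inferior_right=tub_r,
        tuberosity_inferior_left=tub_l,
        pixel_spacing_mm=masks.pixel_spacing_mm,
        laterality_convention=masks.laterality_convention,
        image_id=masks.image_id,
    )
    for side in ("right", "left"):
        head = getattr(masks, f"femoral_head_{side}")
        if head is not None and head.any():
            try:
                setattr(lm, f"femoral_head_contour_{side}", extract_head_contour(head, n_contour_points, flags))
            except ExtractionError as exc:
                flags.append(f"{side}: {exc}")
        sourcil = getattr(masks, f"sourcil_{side}")
        if sourcil is not None and sourcil.any():
            med, lat = extract_sourcil_extents(sourcil, ref, side, masks.laterality_convention, flags)
            setattr(lm, f"sourcil_medial_{side}", med)
            setattr(lm, f"sourcil_lateral_{side}", lat)
        foramen = getattr(masks, f"foramen_{side}")
        if foramen is not None and foramen.any():
            try:
                setattr(lm, f"foramen_outline_{side}", foramen_outline(foramen, flags))
            except ExtractionError as exc:
                flags.append(f"{side}: {exc}")
    return lm, flags


def measure_from_masks(masks: MaskSet, n_contour_points: int = 64):
    """Convenience: masks → landmarks → :func:`hipmetrics.geometry.measure_hips`."""
    from .geometry import measure_hips

    lm, flags = masks_to_landmarks(masks, n_contour_points)
    hm = measure_hips(lm)
    hm.flags = flags + hm.flags
    return hm
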