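"""Synthetic pelvic phantoms with known ground-truth measurements.

A :class:`PhantomSpec` states the *true* LCEA/AIA per side, the true FOI and
the scene geometry; :func:`landmarks_from_truth` places landmarks by closed-
form inverse geometry so that the measurement engine returns exactly the
specified angles, and :func:`rasterize_phantom` renders the corresponding
binary masks so the full mask→measurement pipeline can be exercised without
clinical radiographs.

The phantom is geometric, not photorealistic: filled discs for femoral
heads, tapered strips for sourcils, ellipses for the obturator foramina and
disc-capped blobs for the ischial tuberosities.  It emulates the *landmark
geometry* of an AP pelvis — not bone texture, occlusion or segmentation
failure modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw as skdraw

from .geometry import (
    RIGHT_ON_IMAGE_LEFT,
    LandmarkSet,
    Point2D,
    _lateral_sign,
)
from .masks import MaskSet

__all__ = ["PhantomSpec", "landmarks_from_truth", "rasterize_phantom", "random_phantom_specs"]

# Default truth distributions for phantom batches, matching the measured
# clinical distribution of the population this phantom emulates:
# LCEA ≈ N(25.4, 7.0²) deg, AIA ≈ N(4.7, 5.7²) deg, FOI ≈ N(1, 0.05²).
LCEA_MEAN, LCEA_SD = 25.4, 7.0
AIA_MEAN, AIA_SD = 4.7, 5.7
FOI_MEAN, FOI_SD = 1.0, 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth parameters of one synthetic pelvis.

    Angles in degrees, lengths in pixels.  Geometry defaults scale with the
    canvas so the same spec can be rendered at several resolutions.
    ``rotation_deg`` tilts the whole scene (|rotation| < 45°) — all angle
    truths are invariant to it by construction.
    """

    true_lcea_right: float = 25.43
    true_lcea_left: float = 25.91
    true_aia_right: float = 4.69
    true_aia_left: float = 4.03
    true_foi: float = 1.0
    canvas: tuple[int, int] = (1024, 1024)  # rows, cols
    head_radius: float | None = None  # default 0.115 * rows
    rotation_deg: float = 0.0
    boundary_jitter_px: float = 0.0
    seed: int = 0
    image_id: str = "phantom"
    laterality_convention: str = RIGHT_ON_IMAGE_LEFT

    def __post_init__(self):
        for name in ("true_lcea_right", "true_lcea_left", "true_aia_right", "true_aia_left"):
            if abs(getattr(self, name)) >= 90.0:
                raise ValueError(f"{name} = {getattr(self, name)}° is geometrically impossible (|angle| < 90° required)")
        if not self.true_foi > 0:
            raise ValueError("true_foi must be positive")
        if abs(self.rotation_deg) >= 45.0:
            raise ValueError("scene rotation must stay below 45° to keep the reference line orientable")
        if self.head_radius is not None and not self.head_radius > 0:
            raise ValueError("head_radius must be positive")

    @property
    def radius(self) -> float:
        return self.head_radius if self.head_radius is not None else 0.115 * self.canvas[0]


@dataclass
class _Scene:
    """Analytic shapes of a phantom, all in rotated image coordinates."""

    lm: LandmarkSet
    head_centers: dict  # side -> (x, y)
    head_radius: float
    tub_points: dict  # side -> (x, y); most inferior point, pre-rotation frame... (rotated)
    sourcil_pts: dict  # side -> (medial_xy, lateral_xy)
    foramen: dict  # side -> (center_xy, a, b) with axes along the rotated frame
    rot: np.ndarray
    center: np.ndarray


def _rotation(deg: float, about: np.ndarray):
    th = math.radians(deg)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])

    def apply(p):
        p = np.asarray(p, dtype=float)
        return R @ (p - about) + about

    return R, apply


def _build_scene(spec: PhantomSpec) -> _Scene:
    rows, cols = spec.canvas
    cx = cols / 2.0
    r = spec.radius
    conv = spec.laterality_convention
    img_x = {  # image-x position sign of each patient side relative to midline
        "right": -1.0 if conv == RIGHT_ON_IMAGE_LEFT else 1.0,
    }
    img_x["left"] = -img_x["right"]

    tub_y = 0.74 * rows
    tub_dx = 0.17 * cols
    head_y = 0.40 * rows
    head_dx = 0.22 * cols
    rho = 1.45 * r  # CFH → lateral-sourcil distance
    span = 1.50 * r  # medial–lateral sourcil separation along the reference line
    for_y = 0.585 * rows
    for_dx = 0.085 * cols
    a_left = 0.055 * cols  # foramen semi-axis parallel to the reference line
    b_for = 0.045 * rows

    head_centers, tubs, sourcils, foramina = {}, {}, {}, {}
    for side in ("right", "left"):
        sx = img_x[side]
        lat = _lateral_sign(side, conv)  # sign of along-ref axis pointing lateral
        hc = np.array([cx + sx * head_dx, head_y])
        head_centers[side] = hc
        tubs[side] = np.array([cx + sx * tub_dx, tub_y])
        lcea = math.radians(getattr(spec, f"true_lcea_{side}"))
        aia = math.radians(getattr(spec, f"true_aia_{side}"))
        # pre-rotation frame: reference line is horizontal, superior = -y,
        # along-ref coordinate u = +x; lateral for this side = lat * u.
        lateral = hc + np.array([lat * rho * math.sin(lcea), -rho * math.cos(lcea)])
        medial = lateral + np.array([-lat * span, span * math.tan(aia)])
        sourcils[side] = (medial, lateral)
        a = a_left * (spec.true_foi if side == "right" else 1.0)
        foramina[side] = (np.array([cx + sx * for_dx, for_y]), a, b_for)

    R, apply = _rotation(spec.rotation_deg, np.array([cols / 2.0, rows / 2.0]))

    def pt(v) -> Point2D:
        w = apply(v)
        return Point2D(float(w[0]), float(w[1]))

    n_circle, n_ellipse = 64, 256
    th_c = 2 * np.pi * np.arange(n_circle) / n_circle
    lm = LandmarkSet(image_id=spec.image_id, laterality_convention=conv)
    lm.tuberosity_inferior_right = pt(tubs["right"])
    lm.tuberosity_inferior_left = pt(tubs["left"])
    th_e = 2 * np.pi * np.arange(n_ellipse) / n_ellipse
    for side in ("right", "left"):
        hc = head_centers[side]
        contour = np.column_stack([hc[0] + r * np.cos(th_c), hc[1] + r * np.sin(th_c)])
        setattr(lm, f"femoral_head_contour_{side}", [pt(v) for v in contour])
        med, lat_p = sourcils[side]
        setattr(lm, f"sourcil_medial_{side}", pt(med))
        setattr(lm, f"sourcil_lateral_{side}", pt(lat_p))
        fc, a, b = foramina[side]
        ell = np.column_stack([fc[0] + a * np.cos(th_e), fc[1] + b * np.sin(th_e)])
        setattr(lm, f"foramen_outline_{side}", [pt(v) for v in ell])

    scene = _Scene(
        lm=lm,
        head_centers={s: apply(head_centers[s]) for s in head_centers},
        head_radius=r,
        tub_points={s: apply(tubs[s]) for s in tubs},
        sourcil_pts={s: (apply(sourcils[s][0]), apply(sourcils[s][1])) for s in sourcils},
        foramen={s: (apply(foramina[s][0]), foramina[s][1], foramina[s][2]) for s in foramina},
        rot=R,
        center=np.array([cols / 2.0, rows / 2.0]),
    )
    _check_on_canvas(scene, spec)
    return scene


def _check_on_canvas(scene: _Scene, spec: PhantomSpec) -> None:
    rows, cols = spec.canvas
    pts = [scene.tub_points[s] for s in scene.tub_points]
    pts += [scene.head_centers[s] + d for s in scene.head_centers for d in ([spec.radius, 0], [-spec.radius, 0], [0, spec.radius], [0, -spec.radius])]
    pts += [p for s in scene.sourcil_pts for p in scene.sourcil_pts[s]]
    for p in pts:
        if not (0 <= p[0] < cols and 0 <= p[1] < rows):
            raise ValueError(f"phantom geometry falls off the canvas at ({p[0]:.1f}, {p[1]:.1f}); enlarge the canvas or shrink the spec")


def landmarks_from_truth(spec: PhantomSpec) -> LandmarkSet:
    """Landmark set whose measured angles/FOI equal the spec's truths.

    Closed-form inverse of the angle definitions: the lateral sourcil is
    placed on the ray at the true LCEA from the superior perpendicular of
    the CFH, the medial sourcil on the line at the true AIA through it, and
    foramen ellipse axes realize the true FOI.  Round-trips through the
    measurement engine to < 1e-9°.
    """
    return _build_scene(spec).lm


def _jitter_polygon(xy: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Radial boundary noise around the centroid, smooth at the seam."""
    if sigma <= 0:
        return xy
    c = xy.mean(axis=0)
    v = xy - c
    rad = np.linalg.norm(v, axis=1)
    noise = rng.normal(0.0, sigma, len(xy))
    # light smoothing so adjacent boundary vertices move coherently
    kernel = np.array([0.25, 0.5, 0.25])
    noise = np.convolve(np.concatenate([noise[-1:], noise, noise[:1]]), kernel, mode="valid")
    scale = np.where(rad > 0, (rad + noise) / np.where(rad > 0, rad, 1.0), 1.0)
    return c + v * scale[:, None]


def _fill_polygon(canvas: np.ndarray, xy: np.ndarray) -> None:
    rr, cc = skdraw.polygon(xy[:, 1], xy[:, 0], shape=canvas.shape)
    canvas[rr, cc] = True


def rasterize_phantom(spec: PhantomSpec, landmarks: LandmarkSet | None = None) -> MaskSet:
    """Render binary structure masks for a phantom.

    Deterministic given ``spec.seed``.  Tuberosity blobs are discs placed so
    their most inferior *image-row* pixel sits at the true tuberosity point,
    matching how the extractor defines the landmark.  Sourcils are thin
    strips tapering to the exact medial/lateral truth points (tip pixels
    snapped), so extremal-pixel extraction lands within one pixel of truth.
    ``boundary_jitter_px`` adds seeded radial noise to every outline.
    """
    scene = _build_scene(spec)
    rows, cols = spec.canvas
    rng = np.random.default_rng(spec.seed)
    sig = spec.boundary_jitter_px

    def blank():
        return np.zeros((rows, cols), dtype=bool)

    n_poly = 180
    th = 2 * np.pi * np.arange(n_poly) / n_poly
    unit = np.column_stack([np.cos(th), np.sin(th)])

    pelvis = blank()
    tub_r = max(6.0, 0.02 * rows)
    for side in ("right", "left"):
        t = scene.tub_points[side]
        # disc body with a pointed inferior tip at the truth point, so the
        # most-inferior-pixel rule has a sharp, unambiguous target
        center = np.array([t[0], t[1] - tub_r - 0.6 * tub_r])
        _fill_polygon(pelvis, _jitter_polygon(center + tub_r * unit, sig, rng))
        tip = np.array([t, t + [-0.45 * tub_r, -1.1 * tub_r], t + [0.45 * tub_r, -1.1 * tub_r]])
        _fill_polygon(pelvis, _jitter_polygon(tip, sig, rng))
        ri, ci = int(round(t[1])), int(round(t[0]))
        if 0 <= ri < rows and 0 <= ci < cols:
            pelvis[ri, ci] = True
    # iliac body: a broad ellipse well above the tuberosities (cosmetic, must
    # never create a more inferior pixel than the tuberosity discs)
    body_c = scene.center + np.array([0.0, -0.22 * rows])
    body = body_c + unit * np.array([0.30 * cols, 0.16 * rows])
    _fill_polygon(pelvis, _jitter_polygon(body, sig, rng))

    masks = MaskSet(
        pelvis=pelvis,
        image_id=spec.image_id,
        laterality_convention=spec.laterality_convention,
    )
    for side in ("right", "left"):
        head = blank()
        hc = scene.head_centers[side]
        _fill_polygon(head, _jitter_polygon(hc + scene.head_radius * unit, sig, rng))
        setattr(masks, f"femoral_head_{side}", head)

        sourcil = blank()
        med, lat = scene.sourcil_pts[side]
        chord = lat - med
        nrm = np.array([-chord[1], chord[0]])
        nrm = nrm / np.linalg.norm(nrm)
        half_t = 3.0
        diamond = np.array([med, 0.5 * (med + lat) + half_t * nrm, lat, 0.5 * (med + lat) - half_t * nrm])
        _fill_polygon(sourcil, _jitter_polygon(diamond, sig, rng))
        for tip in (med, lat):  # snap tip pixels so extrema sit within 1 px of truth
            ri, ci = int(round(tip[1])), int(round(tip[0]))
            if 0 <= ri < rows and 0 <= ci < cols:
                sourcil[ri, ci] = True
        setattr(masks, f"sourcil_{side}", sourcil)

        foramen = blank()
        fc, a, b = scene.foramen[side]
        # ellipse axes follow the scene rotation (rotate offsets about the center)
        ell = fc + (unit * np.array([a, b])) @ scene.rot.T
        _fill_polygon(foramen, _jitter_polygon(ell, sig, rng))
        setattr(masks, f"foramen_{side}", foramen)
    return masks


def random_phantom_specs(n: int, seed: int = 0, canvas=(1024, 1024), rotation_sd_deg: float = 2.0) -> list[PhantomSpec]:
    """Batch of phantom specs with truths drawn from the default population.

    LCEA ~ N(25.4, 7.0²), AIA ~ N(4.7, 5.7²) per side (truncated to feasible
    geometry), FOI ~ N(1, 0.05²) truncated positive, mild scene tilt.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        lcea = np.clip(rng.normal(LCEA_MEAN, LCEA_SD, 2), -35.0, 55.0)
        aia = np.clip(rng.normal(AIA_MEAN, AIA_SD, 2), -25.0, 35.0)
        foi = max(0.5, rng.normal(FOI_MEAN, FOI_SD))
        specs.append(
            PhantomSpec(
                true_lcea_right=float(lcea[0]),
                true_lcea_left=float(lcea[1]),
                true_aia_right=float(aia[0]),
                true_aia_left=float(aia[1]),
                true_foi=float(foi),
                canvas=tuple(canvas),
                rotation_deg=float(np.clip(rng.normal(0.0, rotation_sd_deg), -20.0, 20.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
                image_id=f"phantom_{i:04d}",
            )
        )
    return specs
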