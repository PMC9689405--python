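import numpy as np
import pytest

from hipmetrics.geometry import LandmarkSet, Point2D, make_reference_line


@pytest.fixture
def horizontal_ref():
    """Reference line along y = 100."""
    return make_reference_line(Point2D(0, 100), Point2D(200, 100))


def simple_landmarks(
    lcea_right=25.0,
    lcea_left=25.0,
    aia_right=5.0,
    aia_left=5.0,
    head_radius=90.0,
) -> LandmarkSet:
    """Hand-built landmark set with analytically known angles.

    Patient right on image left (default convention); reference line
    horizontal at y = 700.  Lateral sourcils sit on the exact LCEA ray from
    each head center, medial sourcils on the exact AIA line.
    """
    lm = LandmarkSet(image_id="simple")
    lm.tuberosity_inferior_right = Point2D(330.0, 700.0)
    lm.tuberosity_inferior_left = Point2D(670.0, 700.0)
    rho, span = 1.4 * head_radius, 1.5 * head_radius
    for side, hx, lat_sign, lcea, aia in (
        ("right", 280.0, -1.0, lcea_right, aia_right),
        ("left", 720.0, 1.0, lcea_left, aia_left),
    ):
        hc = np.array([hx, 400.0])
        th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        contour = [Point2D(hc[0] + head_radius * np.cos(t), hc[1] + head_radius * np.sin(t)) for t in th]
        setattr(lm, f"femoral_head_contour_{side}", contour)
        lat = hc + [lat_sign * rho * np.sin(np.radians(lcea)), -rho * np.cos(np.radians(lcea))]
        med = lat + [-lat_sign * span, span * np.tan(np.radians(aia))]
        setattr(lm, f"sourcil_lateral_{side}", Point2D(*lat))
        setattr(lm, f"sourcil_medial_{side}", Point2D(*med))
        fx = 500.0 + lat_sign * 90.0
        ell = [Point2D(fx + 55 * np.cos(t), 580.0 + 40 * np.sin(t)) for t in th]
        setattr(lm, f"foramen_outline_{side}", ell)
    return lm


@pytest.fixture
def landmarks():
    return simple_landmarks()
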