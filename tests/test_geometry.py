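"""Angle and circle-fit geometry, including frame-invariance properties."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipmetrics.geometry import (
    CircleFitError,
    DegenerateGeometryError,
    MissingLandmarkError,
    Point2D,
    compute_aia,
    compute_lcea,
    fit_circle_least_squares,
    make_reference_line,
    measure_hips,
    signed_perpendicular_offset,
    transform_landmarks,
)
from hipmetrics.io import measurements_to_records

from conftest import simple_landmarks


class TestReferenceLine:
    def test_horizontal(self):
        ref = make_reference_line(Point2D(0, 100), Point2D(200, 100))
        assert ref.anchor == Point2D(0, 100)
        assert ref.direction == (1.0, 0.0)

    def test_tilted_direction_is_normalized(self):
        ref = make_reference_line(Point2D(0, 100), Point2D(200, 110))
        expect = np.array([200.0, 10.0]) / np.hypot(200.0, 10.0)
        assert ref.direction == pytest.approx(tuple(expect), abs=1e-12)

    def test_canonical_orientation_for_swapped_points(self):
        a, b = Point2D(0, 100), Point2D(200, 110)
        assert make_reference_line(a, b).direction == make_reference_line(b, a).direction

    def test_coincident_points_raise_naming_landmarks(self):
        with pytest.raises(DegenerateGeometryError, match="tuberosity"):
            make_reference_line(Point2D(50, 50), Point2D(50, 50))


class TestCircleFit:
    def test_exact_three_points(self):
        fit = fit_circle_least_squares([(1, 0), (0, 1), (-1, 0)])
        assert fit.center.x == pytest.approx(0, abs=1e-12)
        assert fit.center.y == pytest.approx(0, abs=1e-12)
        assert fit.radius == pytest.approx(1, abs=1e-12)
        assert fit.rms_residual == pytest.approx(0, abs=1e-12)

    def test_exact_recovery_on_noiseless_circle(self):
        th = 2 * np.pi * np.arange(8) / 8
        pts = np.column_stack([120 + 55 * np.cos(th), 340 + 55 * np.sin(th)])
        fit = fit_circle_least_squares(pts)
        assert fit.center.x == pytest.approx(120, abs=1e-9)
        assert fit.center.y == pytest.approx(340, abs=1e-9)
        assert fit.radius == pytest.approx(55, abs=1e-9)
        assert fit.n_points == 8

    def test_matches_grid_search_oracle_on_noisy_points(self):
        # independent oracle: coarse-to-fine grid search over (cx, cy, r)
        # minimizing the sum of squared *radial* deviations
        rng = np.random.default_rng(42)
        th = 2 * np.pi * np.arange(20) / 20
        r_true, c_true = 50.0, np.array([210.0, 330.0])
        pts = c_true + np.column_stack([np.cos(th), np.sin(th)]) * (r_true + rng.uniform(-1, 1, 20))[:, None]

        def sse(cx, cy, r):
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            return np.sum((d - r) ** 2)

        best = (c_true[0], c_true[1], r_true)
        for step in (1.0, 0.2, 0.04, 0.008):
            cx0, cy0, r0 = best
            grid = [
                (cx, cy, r)
                for cx in np.arange(cx0 - 5 * step, cx0 + 5 * step + step / 2, step)
                for cy in np.arange(cy0 - 5 * step, cy0 + 5 * step + step / 2, step)
                for r in np.arange(r0 - 5 * step, r0 + 5 * step + step / 2, step)
            ]
            best = min(grid, key=lambda g: sse(*g))

        fit = fit_circle_least_squares(pts)
        # Kåsa minimizes the algebraic residual; at this noise level it must
        # agree with the geometric grid optimum to well within grid resolution
        assert fit.center.x == pytest.approx(best[0], abs=0.1)
        assert fit.center.y == pytest.approx(best[1], abs=0.1)
        assert fit.radius == pytest.approx(best[2], abs=0.1)

    @pytest.mark.parametrize("pts", [[(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2), (3, 3)]])
    def test_too_few_or_collinear_raise(self, pts):
        with pytest.raises(CircleFitError):
            fit_circle_least_squares(pts)


class TestPerpendicularOffset:
    def test_point_on_line_is_zero(self, horizontal_ref):
        assert signed_perpendicular_offset(Point2D(57, 100), horizontal_ref) == 0.0

    def test_superior_is_positive_in_y_down_coordinates(self, horizontal_ref):
        assert signed_perpendicular_offset(Point2D(10, 40), horizontal_ref) == pytest.approx(60.0)

    def test_tilted_line_matches_rotated_frame_oracle(self):
        ref = make_reference_line(Point2D(0, 100), Point2D(200, 110))
        p = Point2D(100, 80)
        d = np.array([200.0, 10.0]) / np.hypot(200, 10)
        v = np.array([100.0, -20.0])
        expected = float(v @ np.array([d[1], -d[0]]))
        assert signed_perpendicular_offset(p, ref) == pytest.approx(expected, abs=1e-12)


class TestAngles:
    def test_lcea_zero_on_perpendicular(self, horizontal_ref):
        assert compute_lcea(Point2D(100, 100), Point2D(100, 20), horizontal_ref, "right") == pytest.approx(0.0)

    def test_lcea_45_right_hip(self, horizontal_ref):
        # right hip on image left: lateral = -x; sourcil 10 px lateral, 10 superior
        assert compute_lcea(Point2D(100, 100), Point2D(90, 90), horizontal_ref, "right") == pytest.approx(45.0)

    def test_lcea_rotation_invariance(self, horizontal_ref):
        base = compute_lcea(Point2D(100, 100), Point2D(90, 90), horizontal_ref, "right")
        th = np.radians(10)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

        def rot(p):
            v = R @ np.array([p.x, p.y])
            return Point2D(*v)

        ref2 = make_reference_line(rot(Point2D(0, 100)), rot(Point2D(200, 100)))
        rotated = compute_lcea(rot(Point2D(100, 100)), rot(Point2D(90, 90)), ref2, "right")
        assert rotated == pytest.approx(base, abs=1e-9)

    def test_lcea_medial_sourcil_is_negative(self, horizontal_ref):
        assert compute_lcea(Point2D(100, 100), Point2D(110, 90), horizontal_ref, "right") == pytest.approx(-45.0)

    def test_lcea_coincident_raises(self, horizontal_ref):
        with pytest.raises(DegenerateGeometryError):
            compute_lcea(Point2D(1, 2), Point2D(1, 2), horizontal_ref, "right")

    def test_aia_zero_when_sourcils_level(self, horizontal_ref):
        assert compute_aia(Point2D(100, 50), Point2D(80, 50), horizontal_ref, "right") == pytest.approx(0.0)

    def test_aia_sign_follows_lateral_sourcil_elevation(self, horizontal_ref):
        up = compute_aia(Point2D(100, 100), Point2D(90, 90), horizontal_ref, "right")
        down = compute_aia(Point2D(100, 100), Point2D(90, 110), horizontal_ref, "right")
        assert up == pytest.approx(45.0)
        assert down == pytest.approx(-45.0)

    def test_aia_coincident_raises(self, horizontal_ref):
        with pytest.raises(DegenerateGeometryError):
            compute_aia(Point2D(5, 5), Point2D(5, 5), horizontal_ref, "left")


class TestMeasureHips:
    def test_known_angles_round_trip(self):
        lm = simple_landmarks(lcea_right=25.4, aia_right=4.7, lcea_left=31.0, aia_left=-3.5)
        hm = measure_hips(lm)
        assert hm.lcea_right == pytest.approx(25.4, abs=1e-9)
        assert hm.aia_right == pytest.approx(4.7, abs=1e-9)
        assert hm.lcea_left == pytest.approx(31.0, abs=1e-9)
        assert hm.aia_left == pytest.approx(-3.5, abs=1e-9)

    def test_symmetric_scene_gives_unit_foi(self, landmarks):
        assert measure_hips(landmarks).foi == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_serialized_output(self, landmarks):
        r1 = json.dumps(measurements_to_records(measure_hips(landmarks)))
        r2 = json.dumps(measurements_to_records(measure_hips(landmarks)))
        assert r1 == r2

    def test_missing_tuberosity_raises_with_names(self, landmarks):
        landmarks.tuberosity_inferior_left = None
        with pytest.raises(MissingLandmarkError) as exc:
            measure_hips(landmarks)
        assert "tuberosity_inferior_left" in str(exc.value)

    def test_one_bad_side_still_measures_other(self, landmarks):
        landmarks.sourcil_lateral_left = None
        hm = measure_hips(landmarks)
        assert hm.lcea_right is not None
        assert hm.lcea_left is None
        assert any("left" in f and "sourcil_lateral_left" in f for f in hm.flags)

    def test_sourcil_inferior_to_cfh_flags_but_computes(self, landmarks):
        landmarks.sourcil_lateral_right = Point2D(250.0, 520.0)
        hm = measure_hips(landmarks)
        assert hm.lcea_right is not None
        assert any("inferior" in f for f in hm.flags)

    def test_widths_in_mm_when_spacing_given(self, landmarks):
        px = measure_hips(landmarks)
        landmarks.pixel_spacing_mm = 0.2
        mm = measure_hips(landmarks)
        assert mm.width_unit == "mm"
        assert mm.foramen_width_right == pytest.approx(0.2 * px.foramen_width_right)
        assert mm.foi == pytest.approx(px.foi)  # FOI is unit-free


angle_st = st.floats(min_value=-30, max_value=50)
rot_st = st.floats(min_value=-20, max_value=20)


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lcea=angle_st, aia=st.floats(-20, 30), rot=rot_st, tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_rigid_motion_preserves_angles_and_foi(self, lcea, aia, rot, tx, ty):
        lm = simple_landmarks(lcea_right=lcea, aia_right=aia)
        base = measure_hips(lm)
        th = math.radians(rot)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        moved = measure_hips(transform_landmarks(lm, R, (tx, ty)))
        assert moved.lcea_right == pytest.approx(base.lcea_right, abs=1e-9)
        assert moved.aia_right == pytest.approx(base.aia_right, abs=1e-9)
        assert moved.lcea_left == pytest.approx(base.lcea_left, abs=1e-9)
        assert moved.aia_left == pytest.approx(base.aia_left, abs=1e-9)
        assert moved.foi == pytest.approx(base.foi, abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(lcea=angle_st, scale=st.floats(min_value=0.25, max_value=4.0))
    def test_uniform_scaling_preserves_angles_scales_widths(self, lcea, scale):
        lm = simple_landmarks(lcea_right=lcea)
        base = measure_hips(lm)
        scaled = measure_hips(transform_landmarks(lm, scale * np.eye(2)))
        assert scaled.lcea_right == pytest.approx(base.lcea_right, abs=1e-9)
        assert scaled.aia_right == pytest.approx(base.aia_right, abs=1e-9)
        assert scaled.foi == pytest.approx(base.foi, abs=1e-9)
        assert scaled.foramen_width_right == pytest.approx(scale * base.foramen_width_right, rel=1e-9)

    def test_mirror_swaps_sides_and_inverts_foi(self):
        lm = simple_landmarks(lcea_right=22.0, lcea_left=31.0, aia_right=3.0, aia_left=-2.0)
        # make the scene asymmetric in FOI too: widen the right foramen 25%
        lm.foramen_outline_right = [Point2D(410.0 + 1.25 * (p.x - 410.0), p.y) for p in lm.foramen_outline_right]
        base = measure_hips(lm)
        # reflect across the perpendicular bisector of the tuberosity segment (x = 500)
        mirrored = transform_landmarks(lm, np.array([[-1.0, 0.0], [0.0, 1.0]]), (1000.0, 0.0))
        # after reflection the patient's right structures lie on the image
        # right: swap the name assignments to keep the convention
        swapped = simple_landmarks()
        for attr in (
            "tuberosity_inferior",
            "femoral_head_contour",
            "sourcil_medial",
            "sourcil_lateral",
            "foramen_outline",
        ):
            setattr(swapped, f"{attr}_right", getattr(mirrored, f"{attr}_left"))
            setattr(swapped, f"{attr}_left", getattr(mirrored, f"{attr}_right"))
        res = measure_hips(swapped)
        assert res.lcea_right == pytest.approx(base.lcea_left, abs=1e-9)
        assert res.lcea_left == pytest.approx(base.lcea_right, abs=1e-9)
        assert res.aia_right == pytest.approx(base.aia_left, abs=1e-9)
        assert res.aia_left == pytest.approx(base.aia_right, abs=1e-9)
        assert res.foi == pytest.approx(1.0 / base.foi, rel=1e-9)
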