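"""Phantom inverse geometry, rasterization, and the reader-study simulator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hipmetrics.geometry import measure_hips
from hipmetrics.masks import measure_from_masks
from hipmetrics.phantom import PhantomSpec, landmarks_from_truth, random_phantom_specs, rasterize_phantom
from hipmetrics.simulate import ReaderSimSpec, simulate_reader_study


class TestInverseGeometry:
    def test_round_trip_representative_truths(self):
        spec = PhantomSpec(true_lcea_right=25.43, true_aia_right=4.69)
        hm = measure_hips(landmarks_from_truth(spec))
        assert hm.lcea_right == pytest.approx(25.43, abs=1e-9)
        assert hm.aia_right == pytest.approx(4.69, abs=1e-9)

    @pytest.mark.parametrize("lcea,aia,foi", [(0.0, 0.0, 1.0), (-10.0, -8.0, 0.8), (42.0, 20.0, 1.3)])
    def test_round_trip_across_truth_range(self, lcea, aia, foi):
        spec = PhantomSpec(
            true_lcea_right=lcea, true_lcea_left=lcea, true_aia_right=aia, true_aia_left=aia, true_foi=foi
        )
        hm = measure_hips(landmarks_from_truth(spec))
        for v in (hm.lcea_right, hm.lcea_left):
            assert v == pytest.approx(lcea, abs=1e-9)
        for v in (hm.aia_right, hm.aia_left):
            assert v == pytest.approx(aia, abs=1e-9)
        assert hm.foi == pytest.approx(foi, rel=1e-9)

    def test_zero_lcea_puts_sourcil_on_perpendicular(self):
        spec = PhantomSpec(true_lcea_right=0.0)
        lm = landmarks_from_truth(spec)
        cfh = measure_hips(lm).cfh_right.center
        assert lm.sourcil_lateral_right.x == pytest.approx(cfh.x, abs=1e-9)

    def test_scene_rotation_leaves_measured_angles(self):
        base = measure_hips(landmarks_from_truth(PhantomSpec()))
        rot = measure_hips(landmarks_from_truth(PhantomSpec(rotation_deg=7.0)))
        assert rot.lcea_right == pytest.approx(base.lcea_right, abs=1e-9)
        assert rot.aia_left == pytest.approx(base.aia_left, abs=1e-9)
        assert rot.foi == pytest.approx(base.foi, abs=1e-12)

    @pytest.mark.parametrize("bad", [{"true_lcea_right": 95.0}, {"true_aia_left": -90.0}, {"true_foi": 0.0}])
    def test_impossible_specs_raise(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**bad)


class TestRasterization:
    def test_head_mask_area_matches_disc(self):
        spec = PhantomSpec()
        masks = rasterize_phantom(spec)
        area = masks.femoral_head_right.sum()
        assert area == pytest.approx(np.pi * spec.radius**2, rel=0.02)

    def test_same_seed_identical_masks(self):
        spec = PhantomSpec(seed=9, boundary_jitter_px=1.5)
        m1, m2 = rasterize_phantom(spec), rasterize_phantom(spec)
        for name in ("pelvis", "femoral_head_right", "sourcil_left", "foramen_right"):
            assert np.array_equal(getattr(m1, name), getattr(m2, name))

    def test_mask_pipeline_recovers_truth_at_1024(self):
        for spec in random_phantom_specs(4, seed=21):
            hm = measure_from_masks(rasterize_phantom(spec))
            assert hm.lcea_right == pytest.approx(spec.true_lcea_right, abs=0.5)
            assert hm.lcea_left == pytest.approx(spec.true_lcea_left, abs=0.5)
            assert hm.aia_right == pytest.approx(spec.true_aia_right, abs=0.5)
            assert hm.aia_left == pytest.approx(spec.true_aia_left, abs=0.5)
            assert hm.foi == pytest.approx(spec.true_foi, abs=0.02)

    def test_error_decreases_with_resolution(self):
        # mean absolute angle error should shrink as the canvas grows
        def mean_err(canvas):
            errs = []
            for spec in random_phantom_specs(4, seed=33, canvas=canvas):
                hm = measure_from_masks(rasterize_phantom(spec))
                errs += [
                    abs(hm.lcea_right - spec.true_lcea_right),
                    abs(hm.aia_right - spec.true_aia_right),
                ]
            return np.mean(errs)

        assert mean_err((2048, 2048)) < mean_err((512, 512))

    def test_off_canvas_geometry_raises(self):
        with pytest.raises(ValueError, match="canvas"):
            landmarks_from_truth(PhantomSpec(canvas=(256, 256), head_radius=200.0))


class TestReaderSimulation:
    def test_zero_variances_reproduce_fixed_part_exactly(self):
        spec = ReaderSimSpec(
            n_patients=8,
            n_readers=3,
            var_patient=0.0,
            var_reader=0.0,
            var_repeat=0.0,
            var_residual=0.0,
            grand_mean=20.0,
            fixed_effects={"age": 0.1},
            seed=4,
        )
        tab = simulate_reader_study(spec)
        expected = 20.0 + 0.1 * tab["age"]
        assert tab["value"].to_numpy() == pytest.approx(expected.to_numpy(), abs=1e-12)

    def test_same_seed_identical_tables(self):
        spec = ReaderSimSpec(n_patients=10, seed=77)
        pd.testing.assert_frame_equal(simulate_reader_study(spec), simulate_reader_study(spec))

    def test_replicate_design_matches_study_layout(self):
        spec = ReaderSimSpec(n_patients=78, n_readers=5, n_replicate_patients=5, n_replicates=3, seed=1)
        tab = simulate_reader_study(spec)
        per_patient = tab.groupby("patient_id")["replicate"].max()
        assert (per_patient == 3).sum() == 5
        assert (per_patient == 1).sum() == 73
        assert len(tab) == 78 * 5 + 5 * 5 * 2

    def test_method_of_moments_recovery_at_scale(self):
        # balanced 500 x 5 x 3 design; estimate components by the classical
        # expected-mean-squares identities and compare with generator truth
        truth = dict(var_patient=39.46, var_reader=11.88, var_repeat=7.44, var_residual=17.80)
        spec = ReaderSimSpec(
            n_patients=500, n_readers=5, n_replicate_patients=500, n_replicates=3, seed=123, **truth
        )
        tab = simulate_reader_study(spec)
        P, R, K = 500, 5, 3
        piv = tab.pivot_table(index=["patient_id", "replicate"], columns="reader_id", values="value")
        y = piv.to_numpy().reshape(P, K, R)
        gm = y.mean()
        ybar_p = y.mean(axis=(1, 2))
        ybar_r = y.mean(axis=(0, 1))
        ybar_pk = y.mean(axis=2)
        MS_p = R * K * np.sum((ybar_p - gm) ** 2) / (P - 1)
        MS_r = P * K * np.sum((ybar_r - gm) ** 2) / (R - 1)
        MS_c = R * np.sum((ybar_pk - ybar_p[:, None]) ** 2) / (P * (K - 1))
        resid = y - ybar_pk[:, :, None] - ybar_r[None, None, :] + gm
        MS_e = np.sum(resid**2) / (P * K * R - P * K - R + 1)
        s2e = MS_e
        s2c = (MS_c - s2e) / R
        s2r = (MS_r - s2e) / (P * K)
        s2p = (MS_p - s2e - R * s2c) / (R * K)
        # patient/repeat/residual have hundreds of df: 15% sampling band
        assert s2p == pytest.approx(truth["var_patient"], rel=0.15)
        assert s2c == pytest.approx(truth["var_repeat"], rel=0.15)
        assert s2e == pytest.approx(truth["var_residual"], rel=0.15)
        # the reader component has R-1 = 4 df; its MoM estimate scatters with
        # a chi-square_4 spread, so check the 95% sampling interval instead
        from scipy.stats import chi2

        lo, hi = chi2.ppf([0.025, 0.975], R - 1) / (R - 1)
        approx_truth = truth["var_reader"] + s2e / (P * K)
        assert lo * approx_truth * 0.5 < s2r < hi * approx_truth * 1.5

    def test_variance_of_patient_means_follows_total_variance_law(self):
        spec = ReaderSimSpec(n_patients=2000, n_readers=4, n_replicate_patients=0, seed=5)
        tab = simulate_reader_study(spec)
        pm = tab.groupby("patient_id")["value"].mean()
        # Var(patient mean) = s2p + s2c + s2e / R (reader effects are shared
        # across patients and do not add between-patient variance)
        expect = spec.var_patient + spec.var_repeat + spec.var_residual / 4
        assert pm.var(ddof=1) == pytest.approx(expect, rel=0.12)

    def test_invalid_specs_raise(self):
        with pytest.raises(ValueError):
            ReaderSimSpec(var_patient=-1.0)
        with pytest.raises(ValueError):
            ReaderSimSpec(fixed_effects={"height": 1.0})
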