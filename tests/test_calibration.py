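"""Empirical-line calibration fits, application and evaluation."""

import numpy as np
import pytest

from uavcal.calibration import (
    CalibrationFit,
    CalibrationPanel,
    ELRecord,
    PELRecord,
    apply_calibration,
    evaluate_calibration,
    extract_panel_dn,
    fit_el,
    fit_pel,
    fit_sel,
)

PANEL_REFL = np.array([0.03, 0.06, 0.12, 0.24, 0.36, 0.48, 0.56, 0.80])


def ols_oracle(x, y):
    """Normal-equations least squares, independent of the implementation."""
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[0], beta[1]


class TestExtractPanelDN:
    def test_uniform_roi(self):
        img = np.full((20, 20), 500.0)
        p = CalibrationPanel("p", (5, 5, 10, 10), 0.12)
        assert extract_panel_dn(img, p) == 500.0

    def test_small_roi_mean(self):
        img = np.zeros((4, 4))
        img[1:3, 1:3] = [[100, 200], [300, 400]]
        p = CalibrationPanel("p", (1, 1, 3, 3), 0.12)
        assert extract_panel_dn(img, p) == 250.0

    def test_roi_outside_image_errors(self):
        p = CalibrationPanel("p", (0, 0, 10, 10), 0.12)
        with pytest.raises(ValueError, match="exceeds image"):
            extract_panel_dn(np.zeros((5, 5)), p)

    def test_invalid_roi_rejected_at_construction(self):
        with pytest.raises(ValueError, match="ROI"):
            CalibrationPanel("p", (5, 5, 5, 10), 0.12)


class TestFitEL:
    def test_two_point_line_is_analytic(self):
        fit = fit_el(np.array([[100.0], [1000.0]]), np.array([0.03, 0.80]))
        rec = fit.records[1]
        assert rec.a1 == pytest.approx(0.77 / 900.0, abs=1e-12)
        assert rec.b1 == pytest.approx(0.03 - 100 * 0.77 / 900, abs=1e-12)

    def test_exact_line_recovered(self):
        dn = np.linspace(50, 900, 8)[:, None]
        refl = 0.001 * dn[:, 0] + 0.01
        fit = fit_el(dn, refl)
        assert fit.records[1].a1 == pytest.approx(0.001, abs=1e-12)
        assert fit.records[1].b1 == pytest.approx(0.01, abs=1e-12)
        assert fit.panel_rmse[1] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        dn = np.linspace(50, 900, 8)
        refl = 0.001 * dn + 0.01 + rng.normal(0, 0.002, 8)
        fit = fit_el(dn[:, None], refl)
        a, b = ols_oracle(dn, refl)
        assert fit.records[1].a1 == pytest.approx(a, abs=1e-10)
        assert fit.records[1].b1 == pytest.approx(b, abs=1e-10)

    def test_identical_dn_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_el(np.array([[5.0], [5.0]]), np.array([0.1, 0.2]))


class TestFitSEL:
    def test_power_law_recovered_in_low_bands(self):
        dn = np.linspace(40, 800, 8)
        refl = 0.001 * dn ** 1.2
        fit = fit_sel(np.tile(dn[:, None], (1, 12)),
                      np.tile(refl[:, None], (1, 12)))
        rec = fit.records[1]
        assert rec.kind == "power"
        assert rec.a == pytest.approx(0.001, abs=1e-9)
        assert rec.b == pytest.approx(1.2, abs=1e-9)

    def test_linear_recovered_in_high_bands(self):
        dn = np.linspace(40, 800, 8)
        refl = 0.0009 * dn + 0.002
        fit = fit_sel(np.tile(dn[:, None], (1, 12)),
                      np.tile(refl[:, None], (1, 12)))
        rec = fit.records[12]
        assert rec.kind == "linear"
        assert rec.a == pytest.approx(0.0009, abs=1e-12)
        assert rec.b == pytest.approx(0.002, abs=1e-12)

    def test_unit_exponent_degenerates_to_proportional(self):
        dn = np.linspace(40, 800, 8)
        refl = 0.0007 * dn  # exponent exactly 1
        fit = fit_sel(np.tile(dn[:, None], (1, 12)),
                      np.tile(refl[:, None], (1, 12)))
        rec = fit.records[1]
        slope = (dn @ refl) / (dn @ dn)  # through-origin least squares
        np.testing.assert_allclose(rec.apply(dn), slope * dn, atol=1e-9)

    def test_nonpositive_low_group_values_rejected(self):
        dn = np.array([[0.0], [100.0]] * 4).reshape(8, 1)
        with pytest.raises(ValueError, match="positive"):
            fit_sel(np.tile(dn, (1, 12)), np.tile(PANEL_REFL[:, None], (1, 12)))


class TestFitPEL:
    def test_through_origin_slope_exact(self):
        # dark panels on y = 5e-4 x, bright panels on y = 9e-4 x - 0.02
        refl = PANEL_REFL
        dn = np.where(refl <= 0.06, refl / 5e-4, (refl + 0.02) / 9e-4)
        fit = fit_pel(dn[:, None], refl)
        rec = fit.records[1]
        assert rec.a4 == pytest.approx(5e-4, abs=1e-12)
        assert rec.a5 == pytest.approx(9e-4, abs=1e-12)
        assert rec.b5 == pytest.approx(-0.02, abs=1e-12)

    def test_affine_truth_gives_el_high_segment(self):
        dn = np.linspace(50, 900, 8)
        refl = 8e-4 * dn - 0.005
        pel = fit_pel(dn[:, None], refl)
        el = fit_el(dn[:, None], refl)
        assert pel.records[1].a5 == pytest.approx(el.records[1].a1, abs=1e-12)
        assert pel.records[1].b5 == pytest.approx(el.records[1].b1, abs=1e-12)

    def test_sensor_floor_slope_matches_through_origin_oracle(self):
        rng = np.random.default_rng(11)
        refl = PANEL_REFL
        dn = (refl + 0.02) / 9e-4
        dn[:2] = refl[:2] / 5e-4 + rng.normal(0, 0.5, 2)  # noisy dark floor
        fit = fit_pel(dn[:, None], refl)
        xl, yl = dn[:2], refl[:2]
        assert fit.records[1].a4 == pytest.approx(
            (xl @ yl) / (xl @ xl), abs=1e-10
        )

    def test_no_dark_panel_falls_back_with_warning(self, caplog):
        dn = np.linspace(200, 900, 6)
        refl = 9e-4 * dn - 0.02
        with caplog.at_level("WARNING", logger="uavcal"):
            fit = fit_pel(dn[:, None], refl)
        assert "falling back" in caplog.text
        assert np.isfinite(fit.records[1].a4)


class TestApplyCalibration:
    def test_pel_branch_arithmetic(self):
        fit = CalibrationFit("PEL", {1: PELRecord(5e-4, 9e-4, -0.02, 0.03)})
        out, _ = apply_calibration(np.array([[[40.0, 200.0]]]), fit)
        # DN 40: y_lin = 0.016 <= 0.03 -> 5e-4*40 = 0.020; DN 200 -> 0.16
        np.testing.assert_allclose(out[0, 0], [0.020, 0.16], atol=1e-12)

    def test_el_preserves_negative_and_counts_it(self):
        fit = CalibrationFit("EL", {1: ELRecord(0.77 / 900, -0.055556)})
        out, diag = apply_calibration(np.array([[[0.0]]]), fit)
        assert out[0, 0, 0] == pytest.approx(-0.055556, abs=1e-9)
        assert diag.n_negative == 1
        assert diag.per_band_negative[1] == 1

    def test_identity_fit_is_identity(self):
        fit = CalibrationFit("EL", {1: ELRecord(1.0, 0.0)})
        img = np.arange(12.0).reshape(1, 3, 4)
        out, _ = apply_calibration(img, fit)
        np.testing.assert_array_equal(out, img)

    def test_clamp_option(self):
        fit = CalibrationFit("EL", {1: ELRecord(1.0, -0.5)})
        out, _ = apply_calibration(np.array([[[0.0, 2.0]]]), fit,
                                   clamp=(0.0, 1.0))
        np.testing.assert_array_equal(out[0, 0], [0.0, 1.0])

    def test_band_count_mismatch(self):
        fit = CalibrationFit("EL", {1: ELRecord(1.0, 0.0)})
        with pytest.raises(ValueError, match="bands"):
            apply_calibration(np.zeros((2, 3, 3)), fit)

    @pytest.mark.parametrize("method_fit", [
        fit_el, fit_pel,
        lambda d, r: fit_sel(np.tile(d, (1, 12)), np.tile(r[:, None], (1, 12))),
    ])
    def test_monotone_in_dn_for_positive_slopes(self, method_fit):
        dn_p = PANEL_REFL * 1100.0
        fit = method_fit(dn_p[:, None], PANEL_REFL)
        dn = np.linspace(10.0, 1000.0, 200)
        rec = fit.records[1]
        out = rec.apply(dn)
        assert np.all(np.diff(out) >= -1e-12)


class TestRecoveryInvariants:
    def test_affine_sensor_recovered_by_el(self):
        rng = np.random.default_rng(5)
        truth = rng.uniform(0.01, 0.9, (1, 40, 40))
        a, b = 9e-4, -0.02
        dn = (truth - b) / a
        panel_dn = ((PANEL_REFL - b) / a)[:, None]
        fit = fit_el(panel_dn, PANEL_REFL)
        out, _ = apply_calibration(dn, fit)
        assert np.abs(out - truth).max() <= 1e-9

    def test_affine_sensor_recovered_by_pel(self):
        # general affine map: exact wherever the linear branch applies
        rng = np.random.default_rng(5)
        bright = rng.uniform(0.08, 0.9, (1, 40, 40))
        a, b = 9e-4, -0.02
        fit = fit_pel(((PANEL_REFL - b) / a)[:, None], PANEL_REFL)
        out, _ = apply_calibration((bright - b) / a, fit)
        assert np.abs(out - bright).max() <= 1e-9
        # proportional map (b = 0): both branches coincide, exact everywhere
        truth = rng.uniform(0.005, 0.9, (1, 40, 40))
        fit0 = fit_pel((PANEL_REFL / a)[:, None], PANEL_REFL)
        out0, _ = apply_calibration(truth / a, fit0)
        assert np.abs(out0 - truth).max() <= 1e-9

    def test_piecewise_truth_pel_exact_el_biased(self):
        rng = np.random.default_rng(6)
        a4, a5, b5, floor = 5e-4, 9e-4, -0.08, 0.06
        truth = rng.uniform(0.002, 0.9, (1, 50, 50))
        dn = np.where(truth <= floor, truth / a4, (truth - b5) / a5)
        panel_dn = np.where(PANEL_REFL <= floor, PANEL_REFL / a4,
                            (PANEL_REFL - b5) / a5)[:, None]
        pel = fit_pel(panel_dn, PANEL_REFL)
        out, _ = apply_calibration(dn, pel)
        assert np.abs(out - truth).max() <= 1e-6
        el = fit_el(panel_dn, PANEL_REFL)
        out_el, _ = apply_calibration(dn, el)
        low = truth < 0.03
        assert np.abs(out_el - truth)[low].min() > 1e-4  # systematic bias

    def test_pel_equals_el_above_threshold_with_same_panels(self):
        dn_p = np.linspace(50, 900, 8)
        refl = 9e-4 * dn_p - 0.02  # purely affine: high segment == EL line
        pel = fit_pel(dn_p[:, None], refl)
        el = fit_el(dn_p[:, None], refl)
        dn = np.linspace(0, 1000, 500)
        rec_p, rec_e = pel.records[1], el.records[1]
        y_lin = rec_p.a5 * dn + rec_p.b5
        above = y_lin > rec_p.tau
        np.testing.assert_allclose(
            rec_p.apply(dn)[above], rec_e.apply(dn)[above], atol=1e-12
        )


class TestEvaluateCalibration:
    def test_perfect_estimate(self):
        table = evaluate_calibration([[0.1, 0.2]], [[0.1, 0.2]])
        assert table[1]["MRPE"] == 0.0 and table[2]["RMSE"] == 0.0

    def test_hand_arithmetic(self):
        table = evaluate_calibration(
            np.array([[0.11], [0.18]]), np.array([[0.1], [0.2]])
        )
        assert table[1]["MRPE"] == pytest.approx(10.0, abs=1e-9)
        assert table[1]["RMSE"] == pytest.approx(
            np.sqrt((0.0001 + 0.0004) / 2), abs=1e-9
        )

    def test_single_pair(self):
        table = evaluate_calibration([[0.2]], [[0.1]])
        assert table[1]["MRPE"] == pytest.approx(100.0)
        assert table[1]["RMSE"] == pytest.approx(0.1)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            evaluate_calibration([[0.1]], [[0.0]])
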