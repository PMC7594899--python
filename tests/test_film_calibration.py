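"""HD calibration: fitting, interpolation guards, inter-curve deviation."""

import numpy as np
import pytest

from sarjdose.film_calibration import (
    HD_DOSE_GRID_GY,
    CalibrationError,
    CalibrationPoint,
    ExtrapolationError,
    build_hd_curve,
    curve_from_json,
    curve_set_deviation,
    curve_to_json,
    dose_from_pixel,
    load_calibration_csv,
    select_order,
)
from sarjdose.synthetic_data import FilmResponseModel, simulate_hd_response


class TestBuildHDCurve:
    def test_noiseless_cubic_recovered_to_machine_precision(self, exact_cubic):
        coeffs, _, _, points = exact_cubic
        curve = build_hd_curve(points, 3)
        assert np.allclose(curve.coefficients, coeffs, rtol=1e-8)
        assert curve.fit_residual < 1e-10

    def test_noisy_quartic_interpolates_within_propagated_noise(self):
        """10 points + 1% pixel noise: errors bounded by noise propagation.

        Pixel noise maps to dose error through the inverse response slope,
        sigma_D = sigma_p / |p'(D)|, so the admissible relative error is
        dose-dependent: large where the curve is steep in pixel but the dose
        small (low doses), tight on the shoulder.  Each recovered dose must
        sit within the propagated 3-sigma band, or within the 2.5% film
        variability scale where propagation is tighter than that.
        """
        model = FilmResponseModel()
        doses = np.array([1.0, 2.5, 4.0, 6.0, 8.0, 10.0, 14.0, 18.0, 26.0, 33.0])
        rng = np.random.default_rng(42)
        sigma_rel = 0.01
        pixels = model.forward(doses) * (1.0 + sigma_rel * rng.standard_normal(doses.size))
        points = [CalibrationPoint(float(d), float(p)) for d, p in zip(doses, pixels)]
        curve = build_hd_curve(points, 4)
        clean_pixels = model.forward(doses)
        dd_dp = np.polyval(np.polyder(np.asarray(model.dose_of_pixel_coeffs)), clean_pixels)
        prop_rel_3sigma = 3 * sigma_rel * clean_pixels * np.abs(dd_dp) / doses
        for d, p, bound in zip(doses, clean_pixels, prop_rel_3sigma):
            p = min(max(p, curve.pixel_span[0]), curve.pixel_span[1])
            rel_err = abs(dose_from_pixel(curve, p) - d) / d
            assert rel_err < max(0.025, bound)

    def test_too_few_points_for_order(self):
        points = [CalibrationPoint(d, 60000 - 1000 * d) for d in (1.0, 2.0, 3.0)]
        with pytest.raises(CalibrationError, match="at least"):
            build_hd_curve(points, 4)

    def test_mixed_film_models_rejected(self, exact_cubic):
        _, _, _, points = exact_cubic
        bad = points[:-1] + [CalibrationPoint(5.0, 30000.0, "RTQA2")]
        with pytest.raises(CalibrationError, match="mix film models"):
            build_hd_curve(bad, 3)

    def test_dose_outside_dynamic_range_rejected(self):
        points = [CalibrationPoint(d, 60000 - 5000 * d, "RTQA2") for d in range(6)]
        points.append(CalibrationPoint(9.0, 10000.0, "RTQA2"))  # > 8 Gy limit
        with pytest.raises(CalibrationError, match="dynamic range"):
            build_hd_curve(points, 3)

    def test_non_monotone_fit_rejected(self):
        # a V-shaped dose/pixel relation cannot yield a monotone polynomial
        pixels = np.array([1e4, 2e4, 3e4, 4e4, 5e4, 6e4])
        doses = np.array([6.0, 3.0, 1.0, 1.0, 3.0, 6.0])
        points = [CalibrationPoint(float(d), float(p)) for d, p in zip(doses, pixels)]
        with pytest.raises(CalibrationError, match="monotone"):
            build_hd_curve(points, 3)

    def test_auto_order_picks_generating_degree(self, exact_cubic):
        _, _, _, cubic_points = exact_cubic
        assert select_order(cubic_points) == 3
        # strictly decreasing quartic dose-of-pixel relation
        coeffs = np.array([-1e-19, 0.0, 0.0, -6e-4, 50.0])
        pixels = np.linspace(20000.0, 62000.0, 9)
        points = [
            CalibrationPoint(float(np.polyval(coeffs, p)), float(p)) for p in pixels
        ]
        assert select_order(points) == 4


class TestDoseFromPixel:
    def test_identity_at_calibration_knot(self, exact_cubic, exact_cubic_curve):
        _, pixels, doses, _ = exact_cubic
        assert dose_from_pixel(exact_cubic_curve, pixels[3]) == pytest.approx(doses[3], abs=1e-9)

    def test_round_trip_median_error_within_batch_scale(self, film_model):
        """Simulate -> fit -> invert on 100 random doses: median error < 2.5%."""
        rng = np.random.default_rng(7)
        points = simulate_hd_response(model=film_model, seed=7)
        curve = build_hd_curve(points, 4)
        sheet = points[0].mean_pixel / film_model.forward(points[0].dose_gy)
        doses = rng.uniform(0.5, 33.0, 100)
        rel = []
        for d in doses:
            p = film_model.forward(d) * sheet
            p = min(max(p, curve.pixel_span[0]), curve.pixel_span[1])
            rel.append(abs(dose_from_pixel(curve, p) - d) / d)
        assert np.median(rel) < 0.025

    def test_extrapolation_beyond_guard_band_refused(self, exact_cubic_curve):
        lo, hi = exact_cubic_curve.pixel_span
        with pytest.raises(ExtrapolationError):
            dose_from_pixel(exact_cubic_curve, hi * 1.10)
        with pytest.raises(ExtrapolationError):
            dose_from_pixel(exact_cubic_curve, lo * 0.90)

    def test_within_guard_band_clips_and_warns(self, exact_cubic_curve):
        lo, hi = exact_cubic_curve.pixel_span
        edge = hi + 0.005 * (hi - lo)  # inside the 1% guard band
        with pytest.warns(UserWarning, match="clipped"):
            dose = dose_from_pixel(exact_cubic_curve, edge)
        assert dose == exact_cubic_curve.dose_range_gy[0]

    def test_parameter_recovery_is_unbiased(self, film_model):
        """Mean recovered dose over 200 seeded replicates matches truth."""
        true_dose = 5.0
        from sarjdose.film_calibration import CalibrationError

        recovered = []
        for seed in range(200):
            points = simulate_hd_response(model=film_model, seed=seed)
            try:
                curve = build_hd_curve(points, 4)
            except CalibrationError:  # rare non-monotone order-4 fit
                curve = build_hd_curve(points, 3)
            sheet = points[0].mean_pixel / film_model.forward(points[0].dose_gy)
            p = film_model.forward(true_dose) * sheet
            p = min(max(p, curve.pixel_span[0]), curve.pixel_span[1])
            recovered.append(dose_from_pixel(curve, p))
        recovered = np.asarray(recovered)
        sem = recovered.std(ddof=1) / np.sqrt(recovered.size)
        assert abs(recovered.mean() - true_dose) < 3 * sem + 0.01


class TestCurveSetDeviation:
    def test_identical_curves_deviate_zero(self):
        pts = [CalibrationPoint(d, 60000 - 1500 * d) for d in (1.0, 5.0, 10.0)]
        out = curve_set_deviation([pts, pts], min_curves=2)
        for dev in out:
            assert all(v == pytest.approx(0.0) for v in dev.per_curve_deviation_pct.values())

    def test_hand_computed_two_curve_deviation(self):
        a = [CalibrationPoint(5.0, 100.0)]
        b = [CalibrationPoint(5.0, 102.0)]
        (dev,) = curve_set_deviation([a, b], min_curves=2)
        assert dev.per_curve_deviation_pct[0] == pytest.approx(-100 / 101, rel=1e-12)
        assert dev.per_curve_deviation_pct[1] == pytest.approx(+100 / 101, rel=1e-12)

    def test_doses_with_too_few_curves_excluded(self):
        a = [CalibrationPoint(1.0, 100.0), CalibrationPoint(5.0, 80.0)]
        b = [CalibrationPoint(1.0, 101.0), CalibrationPoint(5.0, 81.0)]
        c = [CalibrationPoint(1.0, 102.0)]  # dose 5 has n = 2 only
        out = curve_set_deviation([a, b, c])  # default min_curves=3
        assert [d.dose_gy for d in out] == [1.0]

    def test_deviations_sum_to_zero_at_every_dose(self):
        rng = np.random.default_rng(3)
        curves = [
            [CalibrationPoint(float(d), float(50000 * (1 + 0.02 * rng.standard_normal())))
             for d in (1.0, 5.0, 10.0)]
            for _ in range(5)
        ]
        for dev in curve_set_deviation(curves):
            assert sum(dev.per_curve_deviation_pct.values()) == pytest.approx(0.0, abs=1e-9)

    def test_no_common_dose_is_an_error(self):
        a = [CalibrationPoint(1.0, 100.0)]
        b = [CalibrationPoint(2.0, 100.0)]
        with pytest.raises(CalibrationError, match="no dose shared"):
            curve_set_deviation([a, b], min_curves=2)


class TestIO:
    def test_csv_round_trip_groups_by_experiment(self, tmp_path):
        path = tmp_path / "points.csv"
        path.write_text(
            "dose_gy,mean_pixel,film_model,experiment_id\n"
            "0,60000,EBT-XD,exp1\n5,45000,EBT-XD,exp1\n5,45100,EBT-XD,exp2\n"
        )
        groups = load_calibration_csv(path)
        assert set(groups) == {"exp1", "exp2"}
        assert groups["exp1"][1].dose_gy == 5.0

    def test_curve_json_round_trip(self, exact_cubic_curve, tmp_path):
        path = tmp_path / "curve.json"
        curve_to_json(exact_cubic_curve, path)
        back = curve_from_json(path)
        assert np.allclose(back.coefficients, exact_cubic_curve.coefficients)
        assert back.pixel_span == exact_cubic_curve.pixel_span
        assert back.order == 3

    def test_dose_grid_matches_standard_protocol(self):
        assert len(HD_DOSE_GRID_GY) == 20
        assert HD_DOSE_GRID_GY[0] == 0 and HD_DOSE_GRID_GY[-1] == 33
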