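"""Generators: ground-truth contracts, determinism, recovery round trips."""

import numpy as np
import pytest

from sarjdose.film_calibration import build_hd_curve, curve_set_deviation
from sarjdose.sarj_physics import DepthDoseParams, Prescription, SarjConfig, ShieldSpec
from sarjdose.synthetic_data import (
    ERF_80_20_FACTOR,
    FieldModel,
    FilmResponseModel,
    GrowthModel,
    render_film,
    simulate_beam_field,
    simulate_hd_response,
    simulate_phantom_exposure,
    simulate_tumour_growth,
)


class TestFilmResponse:
    def test_noiseless_points_lie_on_forward_curve(self, film_model):
        points = simulate_hd_response(model=film_model)
        for p in points:
            assert p.mean_pixel == pytest.approx(film_model.forward(p.dose_gy))

    def test_fixed_seed_is_bit_reproducible(self, film_model):
        a = simulate_hd_response(model=film_model, seed=99)
        b = simulate_hd_response(model=film_model, seed=99)
        c = simulate_hd_response(model=film_model, seed=100)
        assert [p.mean_pixel for p in a] == [p.mean_pixel for p in b]
        assert [p.mean_pixel for p in a] != [p.mean_pixel for p in c]

    def test_dose_beyond_film_range_rejected(self, film_model):
        with pytest.raises(ValueError, match="span"):
            simulate_hd_response([40.0], model=film_model)

    def test_non_monotone_truth_rejected(self):
        # a parabola in pixel is not monotone over the pixel span
        with pytest.raises(ValueError, match="monotone"):
            FilmResponseModel(dose_of_pixel_coeffs=(1e-8, -7.5e-4, 20.0))

    def test_batch_noise_spread_matches_configured_scale(self, film_model):
        """Nine noisy curves deviate on the +/-2.5% batch scale."""
        curves = [simulate_hd_response(model=film_model, seed=s) for s in range(9)]
        devs = curve_set_deviation(curves)
        pooled = np.concatenate([list(d.per_curve_deviation_pct.values()) for d in devs])
        assert 1.2 < pooled.std(ddof=1) < 3.8


class TestBeamField:
    def test_ground_truth_penumbra_closed_form(self):
        model = FieldModel(leakage_fraction=0.0)
        _, truth = simulate_beam_field(model)
        assert truth["penumbra_80_20_mm"] == pytest.approx(ERF_80_20_FACTOR * 1.188)

    def test_leakage_plateau_product(self):
        model = FieldModel(plateau_dose_gy=30.0, leakage_fraction=0.008)
        dose, truth = simulate_beam_field(model)
        assert truth["leakage_dose_gy"] == pytest.approx(0.24)
        assert dose[5, 5] == pytest.approx(0.24, rel=0.05)  # far corner at the floor

    def test_zero_size_field_is_all_leakage(self):
        model = FieldModel(field_span_mm=0.0, plateau_dose_gy=5.0, leakage_fraction=0.008)
        dose, _ = simulate_beam_field(model, extent_mm=(5.0, 5.0))
        assert np.allclose(dose, 5.0 * 0.008, rtol=1e-6)

    def test_centre_dose_reaches_plateau(self):
        dose, truth = simulate_beam_field(FieldModel())
        h, w = dose.shape
        assert dose[h // 2, w // 2] == pytest.approx(5.0, rel=1e-3)


class TestRenderFilm:
    def test_uniform_noiseless_render_is_constant_forward_value(self, film_model):
        scan = render_film(np.full((10, 10), 5.0), film_model)
        expected = film_model.forward(5.0)
        assert np.all(np.abs(scan.red.astype(float) - expected) <= 1.0)  # uint16 rounding

    def test_seeded_render_is_bit_reproducible(self, film_model):
        a = render_film(np.full((10, 10), 5.0), film_model, seed=3)
        b = render_film(np.full((10, 10), 5.0), film_model, seed=3)
        assert np.array_equal(a.pixels, b.pixels)

    def test_writes_tiff_with_dpi(self, tmp_path, film_model):
        from sarjdose.film_image import load_scan

        path = tmp_path / "render.tif"
        render_film(np.full((10, 10), 5.0), film_model, dpi=600, path=path)
        assert load_scan(path).dpi == 600.0


class TestPhantomExposure:
    def test_no_attenuation_no_leakage_limit(self):
        cfg = SarjConfig(
            depth=DepthDoseParams(mu_eff_per_mm=0.0, body_thickness_mm=7.0),
            shield=ShieldSpec(layers=[("lead", 42.0, 0.7)]),  # 60 HVLs: ~zero leakage
        )
        _, truth = simulate_phantom_exposure(cfg, Prescription(total_dose_gy=12.0))
        for angle in (15.0, 195.0):
            sites = truth[angle]
            assert sites["tumour-dorsal"] == sites["tumour-mid"] == sites["tumour-ventral"]
            assert sites["head"] < 1e-12

    def test_shielded_sites_bounded_by_transmission_plus_scatter(self):
        cfg = SarjConfig()
        rx = Prescription(total_dose_gy=30.0)
        _, truth = simulate_phantom_exposure(cfg, rx)
        for angle in (15.0, 195.0):
            per_beam = 15.0
            pct = 100.0 * truth[angle]["head"] / per_beam
            assert pct <= 0.8 + 100.0 * cfg.scatter_fraction
        total_shielded = truth[15.0]["body"] + truth[195.0]["body"]
        assert total_shielded / 30.0 * 100.0 <= 1.3

    def test_entry_to_mid_drop_in_band(self):
        _, truth = simulate_phantom_exposure()
        drop = 1.0 - truth[15.0]["tumour-mid"] / truth[15.0]["tumour-dorsal"]
        assert 0.05 < drop < 0.10

    def test_opposed_beam_totals_more_uniform_than_single(self):
        frame, _ = simulate_phantom_exposure(seed=31)
        mid = frame[frame["site"] == "tumour-mid"]
        single = mid[mid["beam_deg"] == 15.0].set_index("restraint")["dose_gy"]
        total = mid.groupby("restraint")["dose_gy"].sum()
        def max_dev(d):
            return np.abs(d - d.mean()).max() / d.mean()
        assert max_dev(total) < max_dev(single)


class TestTumourGrowth:
    def test_untreated_model_groups_match_in_distribution(self):
        model = GrowthModel(kill_fraction_per_fraction=0.0)
        rec = simulate_tumour_growth(model, n_per_group=6, seed=5)
        day = rec[rec["day"] == 12]
        ctrl = day[day["group"] == "control"]["volume_mm3"]
        trt = day[day["group"] == "irradiated"]["volume_mm3"]
        from sarjdose.treatment_analysis import rank_sum_exact

        assert rank_sum_exact(ctrl, trt).p_value > 0.01

    def test_effective_treatment_shrinks_tumours_reliably(self):
        """Treated group mean below control at day 14 in >= 95% of replicates."""
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            rec = simulate_tumour_growth(n_per_group=3, seed=seed)
            day = rec[rec["day"] == 14]
            ctrl = day[day["group"] == "control"]["volume_mm3"].mean()
            trt = day[day["group"] == "irradiated"]["volume_mm3"].mean()
            wins += trt < ctrl
        assert wins / n_rep >= 0.95

    def test_endpoint_event_day_semantics(self):
        model = GrowthModel(
            v0_mm3=900.0,
            growth_rate_per_day=0.1,
            growth_rate_cv=0.0,
            measurement_noise_rel=0.0,
            endpoint_volume_mm3=1000.0,
        )
        rec = simulate_tumour_growth(model, n_per_group=2, seed=1)
        ctrl = rec[rec["group"] == "control"]
        # v(8) = 900 < 1000; v(10) = 900 e^0.2 ~ 1099 >= 1000 -> event at day 10
        assert (ctrl.groupby("animal_id")["event_day"].first() == 10).all()
        assert ctrl["event"].all()
        assert ctrl["day"].max() == 10  # no measurements past the event

    def test_censoring_at_study_end(self):
        model = GrowthModel(endpoint_volume_mm3=1e9)  # unreachable
        rec = simulate_tumour_growth(model, n_per_group=2, seed=2)
        assert (~rec["event"]).all()
        assert (rec["event_day"] == 35).all()

    def test_fixed_seed_reproducible(self):
        a = simulate_tumour_growth(seed=7)
        b = simulate_tumour_growth(seed=7)
        assert a.equals(b)
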