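"""Ionization model, mixture spectra and ratiometric pKa fitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from fpdyn import titration as ti
from fpdyn.synthetic import TitrationSpec, gen_titration


@pytest.fixture(scope="module")
def mcoral():
    return ti.default_mcoral_model(), ti.default_mcoral_basis()


@pytest.fixture(scope="module")
def noiseless_series(mcoral):
    model, basis = mcoral
    series, _ = gen_titration(TitrationSpec(model=model, basis=basis))
    return series


class TestSpeciesFractions:
    def test_acid_limit_is_fully_protonated(self, mcoral):
        model, _ = mcoral
        f = ti.species_fractions(1.0, model)
        assert f["SH/OH"] == pytest.approx(1.0, abs=1e-4)

    def test_equal_population_at_the_first_midpoint(self, mcoral):
        model, _ = mcoral
        f = ti.species_fractions(model.pkas[0], model)
        assert f["SH/OH"] == pytest.approx(f["SH/O-"], rel=1e-12)

    def test_neutral_ph_dominated_by_thiol_phenolate(self, mcoral):
        model, _ = mcoral
        f = ti.species_fractions(7.0, model)
        assert f["SH/O-"] > max(f["SH/OH"], f["S-/O-"])
        assert f["SH/O-"] > 0.9

    @settings(deadline=None, max_examples=60)
    @given(ph=st_.floats(0.0, 14.0))
    def test_fractions_sum_to_one(self, ph):
        model = ti.default_mcoral_model()
        f = ti.species_fractions(ph, model)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)

    def test_end_species_are_monotone_in_ph(self, mcoral):
        model, _ = mcoral
        ph = np.linspace(0, 14, 200)
        f = ti.species_fractions(ph, model)
        assert (np.diff(f["SH/OH"]) <= 1e-15).all()
        assert (np.diff(f["S-/O-"]) >= -1e-15).all()

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            ti.IonizationModel(pkas=(8.8, 5.7))
        with pytest.raises(ValueError):
            ti.IonizationModel(pkas=(1.0, 2.0, 3.0))


class TestPredictSpectrum:
    def test_extreme_ph_gives_pure_species_band(self, mcoral):
        model, basis = mcoral
        wl = ti.DEFAULT_WAVELENGTHS
        spec = ti.predict_spectrum(1.0, model, basis, wl)
        pure = np.asarray(basis[0].absorbance(wl))
        # residual anion population at pH 1 is 10^(1 - 5.7) ~ 2e-5
        np.testing.assert_allclose(spec, pure, atol=5e-5)
        assert wl[np.argmax(spec)] == pytest.approx(420.0, abs=1.0)

    def test_high_ph_peak_blue_shifts_toward_543(self, mcoral):
        model, basis = mcoral
        wl = ti.DEFAULT_WAVELENGTHS
        spec10 = ti.predict_spectrum(10.0, model, basis, wl)
        assert wl[np.argmax(spec10)] == pytest.approx(543.0, abs=1.5)
        spec12 = ti.predict_spectrum(12.0, model, basis, wl)
        assert wl[np.argmax(spec12)] == pytest.approx(543.0, abs=0.5)

    def test_neutral_ph_peak_at_566(self, mcoral):
        model, basis = mcoral
        wl = ti.DEFAULT_WAVELENGTHS
        assert wl[np.argmax(ti.predict_spectrum(7.0, model, basis, wl))] == 566.0

    def test_mixture_bounded_by_basis_maximum(self, mcoral):
        model, basis = mcoral
        wl = ti.DEFAULT_WAVELENGTHS
        upper = np.max([np.asarray(s.absorbance(wl)) for s in basis], axis=0)
        for ph in (3.0, 6.0, 7.5, 9.0, 12.0):
            assert (ti.predict_spectrum(ph, model, basis, wl) <= upper + 1e-12).all()

    def test_missing_species_rejected(self, mcoral):
        model, basis = mcoral
        with pytest.raises(ValueError, match="missing species"):
            ti.predict_spectrum(7.0, model, basis[:2])


class TestRatioCurve:
    def test_identical_spectra_give_constant_ratio(self):
        wl = np.array([400.0, 500.0])
        ab = np.tile([0.4, 0.8], (5, 1))
        series = ti.TitrationSeries(np.linspace(4, 8, 5), wl, ab)
        curve = ti.ratio_curve(series, 500.0, 400.0)
        np.testing.assert_allclose(curve.ratio, 2.0)

    def test_zero_denominator_points_dropped_with_warning(self):
        wl = np.array([400.0, 500.0])
        ab = np.array([[0.5, 1.0], [0.0, 1.0], [0.5, 1.0], [0.5, 1.0]])
        series = ti.TitrationSeries(np.array([4.0, 5.0, 6.0, 7.0]), wl, ab)
        with pytest.warns(UserWarning, match="dropping"):
            curve = ti.ratio_curve(series, 500.0, 400.0)
        assert len(curve.ph) == 3 and 5.0 not in curve.ph

    def test_wavelength_outside_grid_rejected(self, noiseless_series):
        with pytest.raises(ValueError, match="outside"):
            ti.ratio_curve(noiseless_series, 900.0, 425.0)

    def test_window_restricts_ph_points(self, noiseless_series):
        curve = ti.ratio_curve(noiseless_series, 566.0, 425.0, window=(4.5, 8.0))
        assert curve.ph.min() >= 4.5 and curve.ph.max() <= 8.0


class TestFitPka:
    def test_self_consistency_on_exact_sigmoid(self):
        ph = np.linspace(4, 10, 13)
        r = 0.2 + (1.4 - 0.2) / (1 + 10 ** (6.35 - ph))
        fit = ti.fit_pka(ti.RatioCurve(ph, r, 0, 0))
        assert fit.pka == pytest.approx(6.35, abs=0.01)
        assert fit.residual_norm < 1e-10

    def test_three_state_titration_recovers_both_planted_pkas(self, noiseless_series):
        low = ti.fit_pka(ti.ratio_curve(
            noiseless_series, ti.MAIN_PEAK_MCORAL, ti.LOW_REF_WAVELENGTH,
            window=ti.LOW_RANGE_WINDOW))
        high = ti.fit_pka(ti.ratio_curve(
            noiseless_series, ti.MAIN_PEAK_MCORAL, ti.HIGH_REF_WAVELENGTH,
            window=ti.HIGH_RANGE_WINDOW))
        assert low.pka == pytest.approx(5.7, abs=0.1)
        assert high.pka == pytest.approx(8.8, abs=0.1)

    def test_one_site_titration_recovers_planted_pka(self):
        series, model = gen_titration(TitrationSpec(
            model=ti.default_mcherry_model(), basis=ti.default_mcherry_basis()))
        fit = ti.fit_pka(ti.ratio_curve(series, ti.MAIN_PEAK_MCHERRY,
                                        ti.LOW_REF_WAVELENGTH))
        assert fit.pka == pytest.approx(4.4, abs=0.1)

    def test_flat_curve_rejected(self):
        curve = ti.RatioCurve(np.linspace(4, 9, 6), np.full(6, 1.5), 0, 0)
        with pytest.raises(ValueError, match="no transition"):
            ti.fit_pka(curve)

    def test_too_few_points_rejected(self):
        curve = ti.RatioCurve(np.array([4.0, 5, 6]), np.array([0.1, 0.5, 0.9]), 0, 0)
        with pytest.raises(ValueError, match="4 points"):
            ti.fit_pka(curve)

    def test_invariant_to_affine_rescaling_of_the_ratio(self):
        ph = np.linspace(4, 10, 10)
        r = 0.3 + 1.1 / (1 + 10 ** (7.2 - ph))
        a = ti.fit_pka(ti.RatioCurve(ph, r, 0, 0))
        b = ti.fit_pka(ti.RatioCurve(ph, 5.0 * r - 0.7, 0, 0))
        assert a.pka == pytest.approx(b.pka, abs=1e-6)

    def test_free_hill_variant_recovers_unit_hill(self):
        ph = np.linspace(4, 10, 13)
        r = 0.1 + 0.9 / (1 + 10 ** (6.8 - ph))
        fit = ti.fit_pka(ti.RatioCurve(ph, r, 0, 0), free_hill=True)
        assert fit.hill == pytest.approx(1.0, abs=0.01)
        assert fit.pka == pytest.approx(6.8, abs=0.02)

    def test_noisy_replicates_recover_planted_pka(self):
        # ratio noise sd = 2% of the dynamic range; median error < 0.1 pH
        rng = np.random.default_rng(17)
        ph = np.array(ti.DEFAULT_PH_POINTS)
        errors = []
        for _ in range(100):
            true = rng.uniform(5.0, 9.5)
            r = 0.2 + 1.2 / (1 + 10 ** (true - ph))
            noisy = r + rng.normal(0, 0.02 * np.ptp(r), size=r.shape)
            fit = ti.fit_pka(ti.RatioCurve(ph, noisy, 0, 0))
            errors.append(abs(fit.pka - true))
        assert np.median(errors) < 0.1


class TestGenerator:
    def test_same_seed_reproduces_series(self):
        a, _ = gen_titration(TitrationSpec(noise_sd=0.01, seed=3))
        b, _ = gen_titration(TitrationSpec(noise_sd=0.01, seed=3))
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_absorbance_clipped_non_negative(self):
        series, _ = gen_titration(TitrationSpec(noise_sd=0.2, seed=5))
        assert (series.absorbance >= 0).all()

    def test_csv_round_trip(self, noiseless_series, tmp_path):
        p = tmp_path / "titr.csv"
        noiseless_series.to_csv(p)
        back = ti.TitrationSeries.from_csv(p)
        np.testing.assert_allclose(back.absorbance, noiseless_series.absorbance)
        np.testing.assert_allclose(back.ph, noiseless_series.ph)
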