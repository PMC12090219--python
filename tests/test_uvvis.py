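"""Spectral analytics: baselines, PSS kinetics, deconvolution, E:Z estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photoxen import (Spectrum, baseline_correct, build_fE_standard_curve,
                      deconvolute_bands, estimate_E_fraction,
                      fit_isomerization_kinetics, analyze_cycles_spectra)
from photoxen.synthetic_data import (SimConfig, band_spectrum, gen_pss_timecourse,
                                     gen_switch_spectra, DEFAULT_GRID,
                                     E_TEMPLATE_BANDS, Z_TEMPLATE_BANDS)

GRID = DEFAULT_GRID


def pure_E(noise_seed=None, sd=0.0):
    cfg = SimConfig(seed=noise_seed or 0, spectral_sd=sd)
    return gen_switch_spectra(1.0, config=cfg, state="AIS")


class TestBaseline:
    def test_constant_offset_removed(self):
        s = Spectrum(GRID, np.full_like(GRID, 0.05))
        out = baseline_correct(s)
        assert np.allclose(out.absorbance, 0.0)

    def test_band_preserved_offset_removed(self):
        band = band_spectrum(E_TEMPLATE_BANDS, GRID)
        s = Spectrum(GRID, band + 0.07)
        out = baseline_correct(s)
        # 600 nm carries a ~1e-8 band tail; offset removal is pointwise exact
        assert np.allclose(out.absorbance, band - band[GRID == 600.0], atol=1e-12)
        assert out.at(600.0) == pytest.approx(0.0, abs=1e-12)

    def test_reference_outside_grid_rejected(self):
        s = Spectrum(GRID, np.zeros_like(GRID))
        with pytest.raises(ValueError, match="outside grid"):
            baseline_correct(s, ref_wavelength=800.0)


class TestIsomerizationKinetics:
    def test_half_time_identity_t_half_times_k_is_ln2(self):
        t = np.linspace(0, 5, 40)
        for k in (np.log(2.0), 0.8664, 2.0):
            y = 0.8 - 0.5 * (1 - np.exp(-k * t))
            res = fit_isomerization_kinetics(t, y, "decreasing")
            assert res.t_half * res.k == pytest.approx(np.log(2.0), rel=1e-12)

    def test_known_rate_gives_known_half_time(self):
        t = np.linspace(0, 5, 40)
        y = 0.8 - 0.5 * (1 - np.exp(-np.log(2.0) * t))
        assert fit_isomerization_kinetics(t, y, "decreasing").t_half == \
            pytest.approx(1.0, rel=1e-9)
        # the E-enriching photostationary state forms with t1/2 ~ 0.8 s
        y2 = 0.2 + 0.6 * (1 - np.exp(-0.8664 * t))
        assert fit_isomerization_kinetics(t, y2, "increasing").t_half == \
            pytest.approx(np.log(2.0) / 0.8664, rel=1e-9)

    def test_noisy_rate_within_3se(self):
        rng = np.random.default_rng(9)
        t = np.linspace(0, 4, 60)
        y = 0.3 + 0.5 * np.exp(-2.0 * t) + rng.normal(0, 0.004, t.shape)
        res = fit_isomerization_kinetics(t, y, "decreasing")
        assert abs(res.k - 2.0) < 3 * res.k_se

    def test_direction_mismatch_rejected(self):
        t = np.linspace(0, 5, 20)
        y = 0.2 + 0.6 * (1 - np.exp(-t))
        with pytest.raises(ValueError, match="direction"):
            fit_isomerization_kinetics(t, y, "decreasing")


class TestDeconvolution:
    def test_exact_two_gaussian_recovery(self):
        s = Spectrum(GRID, band_spectrum({"pipi": (330.0, 0.8, 20.0),
                                          "npi": (430.0, 0.1, 30.0)}, GRID))
        fit = deconvolute_bands(s)
        assert fit.bands["pipi"]["center"] == pytest.approx(330.0, abs=1e-6)
        assert fit.bands["pipi"]["amplitude"] == pytest.approx(0.8, abs=1e-6)
        assert fit.bands["pipi"]["width"] == pytest.approx(20.0, abs=1e-6)
        assert fit.bands["npi"]["center"] == pytest.approx(430.0, abs=1e-5)
        assert fit.rss < 1e-12

    def test_cumulative_equals_band_sum_pointwise(self):
        s = gen_switch_spectra(0.6)
        fit = deconvolute_bands(s)
        assert np.allclose(fit.cumulative,
                           fit.band_curve("pipi") + fit.band_curve("npi"),
                           atol=1e-12)

    def test_one_percent_noise_centers_within_1nm(self):
        s = gen_switch_spectra(1.0, config=SimConfig(seed=13, spectral_sd=0.008))
        fit = deconvolute_bands(s)
        assert abs(fit.bands["pipi"]["center"] - 330.0) < 1.0
        assert abs(fit.bands["npi"]["center"] - 430.0) < 1.0


class TestEFraction:
    def ref_fit(self):
        return deconvolute_bands(pure_E())

    def test_reference_against_itself_is_pure_E(self):
        ref = self.ref_fit()
        assert estimate_E_fraction(ref, ref).f_E == 1.0

    def test_zero_pipi_mixture_is_pure_Z(self):
        ref = self.ref_fit()
        z = Spectrum(GRID, band_spectrum(Z_TEMPLATE_BANDS, GRID))
        est = estimate_E_fraction(deconvolute_bands(z), ref)
        assert est.f_E == pytest.approx(0.0, abs=1e-3)

    def test_known_mixture_of_cumulatives_recovered_to_1e3(self):
        # A_i built directly as 0.29 A_E + 0.71 A_Z with A_Z free of ππ*
        # intensity: the root-finder must hit the mixing fraction exactly
        from dataclasses import replace
        ref = self.ref_fit()
        mask = (GRID >= 310.0) & (GRID <= 600.0)
        A_Z = band_spectrum(Z_TEMPLATE_BANDS, GRID)[mask]
        mix = replace(ref, cumulative=0.29 * ref.cumulative + 0.71 * A_Z)
        est = estimate_E_fraction(mix, ref)
        assert est.f_E == pytest.approx(0.29, abs=1e-3)

    def test_full_pipeline_recovers_mixture_within_1pp(self):
        ref = self.ref_fit()
        est = estimate_E_fraction(deconvolute_bands(gen_switch_spectra(0.29)),
                                  ref)
        assert est.f_E == pytest.approx(0.29, abs=0.01)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.floats(min_value=0.05, max_value=0.9))
    def test_estimate_strictly_monotone_in_mixing_fraction(self, f):
        ref = self.ref_fit()
        lo = estimate_E_fraction(deconvolute_bands(gen_switch_spectra(f)), ref)
        hi = estimate_E_fraction(
            deconvolute_bands(gen_switch_spectra(min(f + 0.05, 0.98))), ref)
        assert hi.f_E > lo.f_E

    def test_round_trip_across_fraction_range(self):
        ref = self.ref_fit()
        for f in np.arange(0.1, 0.91, 0.1):
            est = estimate_E_fraction(
                deconvolute_bands(gen_switch_spectra(float(f))), ref)
            assert abs(est.f_E - f) < 0.02

    def test_cumulative_at_centers_dominated_by_own_band(self):
        fit = deconvolute_bands(gen_switch_spectra(0.8))
        for name in ("pipi", "npi"):
            b = fit.bands[name]
            idx = int(np.argmin(np.abs(fit.wavelength - b["center"])))
            assert fit.cumulative[idx] >= b["amplitude"] * (1 - 0.05)


class TestStandardCurve:
    def test_two_exact_points(self):
        curve = build_fE_standard_curve([0.2, 0.8], [0.2, 0.8])
        assert curve.a == pytest.approx(1.0, abs=1e-12)
        assert curve.b == pytest.approx(0.0, abs=1e-12)

    def test_prediction_reproduces_fitted_point(self):
        curve = build_fE_standard_curve([0.1, 0.5, 0.9], [0.2, 0.5, 0.8])
        assert curve.predict(0.5) == pytest.approx(0.5, abs=1e-9)

    def test_noisy_recovery_within_3se(self):
        rng = np.random.default_rng(17)
        A330 = np.linspace(0.2, 0.8, 20)
        f = 1.25 * A330 - 0.1 + rng.normal(0, 0.01, A330.shape)
        curve = build_fE_standard_curve(f, A330)
        assert abs(curve.a - 1.25) < 3 * curve.a_se
        assert abs(curve.b - (-0.1)) < 3 * curve.b_se

    def test_prediction_clamped_to_unit_interval(self):
        curve = build_fE_standard_curve([0.2, 0.8], [0.2, 0.8])
        assert curve.predict(5.0) == 1.0
        assert curve.predict(-3.0) == 0.0

    def test_identical_abscissae_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            build_fE_standard_curve([0.2, 0.8], [0.5, 0.5])


class TestSpectralCycles:
    def _series(self, fs):
        out = [gen_switch_spectra(1.0, state="AIS", cycle=0)]
        for i, f in enumerate(fs):
            state = "PSS365" if i % 2 == 0 else "PSS420"
            out.append(gen_switch_spectra(f, state=state, cycle=1 + i // 2))
        return out

    def test_perfect_alternation_gives_zero_width_ranges(self):
        res = analyze_cycles_spectra(self._series([0.28, 0.90] * 4))
        for state in ("PSS365", "PSS420"):
            lo, hi = res.state_ranges[state]
            assert hi - lo < 1e-3
        assert not res.fatigue

    def test_recovered_ranges_contain_generated_truth(self):
        res = analyze_cycles_spectra(self._series([0.28, 0.90] * 5))
        assert res.state_ranges["PSS365"][0] - 1e-2 <= 0.28 <= \
            res.state_ranges["PSS365"][1] + 1e-2
        assert res.state_ranges["PSS420"][0] - 1e-2 <= 0.90 <= \
            res.state_ranges["PSS420"][1] + 1e-2

    def test_linear_fatigue_raises_flag(self):
        fs = []
        for c in range(5):
            fs += [0.28 + 0.03 * c, 0.90 - 0.03 * c]
        res = analyze_cycles_spectra(self._series(fs))
        assert res.fatigue

    def test_missing_reference_rejected(self):
        spectra = [gen_switch_spectra(0.3, state="PSS365", cycle=1)]
        with pytest.raises(ValueError, match="reference"):
            analyze_cycles_spectra(spectra)


def test_pss_timecourse_round_trip_recovers_rate():
    times = np.linspace(0, 6, 30)
    series = gen_pss_timecourse(k=1.2, f_start=0.29, f_end=0.94, times=times)
    a330 = [s.at(330.0) for s in series]
    res = fit_isomerization_kinetics(times, a330, "increasing")
    assert res.k == pytest.approx(1.2, rel=1e-6)
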