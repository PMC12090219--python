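"""Global dummy-constant LRF fits, Michaelis–Menten fits, cycle analysis."""

import numpy as np
import pytest

from photoxen import (GLUTAMINASE_CONSTANTS, LightRegulation, MichaelisMenten,
                      PhotostateDataset, analyze_cycles_activity,
                      fit_lrf_linear, fit_lrf_mm, fit_michaelis_menten)
from photoxen.assay_kinetics import weighted_origin_fit
from photoxen.synthetic_data import (SimConfig, gen_cycle_curve,
                                     gen_linear_activity_dataset,
                                     gen_mm_dataset)

GRID = np.geomspace(0.005, 2.0, 12)   # mM, spans below and above Km = 0.03


class TestLrfLinear:
    def test_identical_datasets_give_unit_lrf(self):
        a = gen_linear_activity_dataset(4.0, [0.1, 0.2, 0.5, 1.0], state="AIS")
        b = gen_linear_activity_dataset(4.0, [0.1, 0.2, 0.5, 1.0], state="PSS365")
        fit = fit_lrf_linear(a, b)
        assert fit.lrf == pytest.approx(1.0, abs=1e-9)
        assert fit.uncertain   # |LRF-1| < SE flags an indistinct comparison

    def test_noise_free_slope_ratio_is_exact(self):
        a = gen_linear_activity_dataset(4.0, [0.1, 0.2, 0.5, 1.0], state="AIS")
        b = gen_linear_activity_dataset(8.0, [0.1, 0.2, 0.5, 1.0], state="PSS365")
        fit = fit_lrf_linear(a, b)
        assert fit.lrf == pytest.approx(2.0, abs=1e-9)
        assert fit.shared_value == pytest.approx(4.0, abs=1e-9)
        assert fit.fast_state.value == "PSS365"

    def test_noisy_ratio_within_3se_and_matches_independent_slopes(self):
        cfg_a, cfg_b = SimConfig(seed=21), SimConfig(seed=22)
        E0 = [0.1, 0.2, 0.5, 1.0]
        a = gen_linear_activity_dataset(2.0, E0, noise_sd=0.03, config=cfg_a,
                                        state="AIS")
        b = gen_linear_activity_dataset(6.0, E0, noise_sd=0.03, config=cfg_b,
                                        state="PSS365")
        # unweighted equal-design case: global fit == ratio of per-state slopes
        a_u = PhotostateDataset(state="AIS", x=a.x, y=a.y)
        b_u = PhotostateDataset(state="PSS365", x=b.x, y=b.y)
        fit = fit_lrf_linear(a_u, b_u)
        assert abs(fit.lrf - 3.0) < 3 * fit.lrf_se
        ma, _ = weighted_origin_fit(a_u.x, a_u.y)
        mb, _ = weighted_origin_fit(b_u.x, b_u.y)
        assert fit.lrf == pytest.approx(mb / ma, rel=1e-6)

    def test_lrf_invariant_under_state_relabeling(self):
        a = gen_linear_activity_dataset(4.0, [0.1, 0.5, 1.0], state="AIS")
        b = gen_linear_activity_dataset(9.0, [0.1, 0.5, 1.0], state="PSS365")
        f1, f2 = fit_lrf_linear(a, b), fit_lrf_linear(b, a)
        assert f1.lrf == pytest.approx(f2.lrf, rel=1e-9)
        assert f1.fast_state == f2.fast_state

    def test_all_zero_activities_unidentifiable(self):
        a = gen_linear_activity_dataset(4.0, [0.1, 0.5], state="AIS")
        zero = PhotostateDataset(state="PSS365", x=np.array([0.1, 0.5]),
                                 y=np.zeros(2))
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_lrf_linear(a, zero)


class TestMichaelisMenten:
    def test_noise_free_recovery_is_exact(self):
        # WT-level asparaginase constants
        ds = gen_mm_dataset(20.0, 0.03, GRID)
        res = fit_michaelis_menten(ds)
        assert res.kcat == pytest.approx(20.0, abs=1e-8)
        assert res.Km == pytest.approx(0.03, abs=1e-10)
        assert res.kcat_over_Km == pytest.approx(20.0 / 0.03 * 1e3, rel=1e-6)

    def test_half_saturation_identity(self):
        ds = gen_mm_dataset(20.0, 0.03, GRID)
        res = fit_michaelis_menten(ds)
        v_at_Km = res.kcat * res.Km / (res.Km + res.Km)
        assert v_at_Km == pytest.approx(res.kcat / 2, rel=1e-12)

    def test_noisy_triplicates_within_3se_and_match_grid_oracle(self):
        ds = gen_mm_dataset(20.0, 0.03, GRID, replicates=3, noise_sd=0.02,
                            config=SimConfig(seed=42))
        res = fit_michaelis_menten(ds)
        assert abs(res.kcat - 20.0) < 3 * res.kcat_se
        assert abs(res.Km - 0.03) < 3 * res.Km_se
        # brute-force 2-D weighted grid search oracle
        w = 1.0 / ds.y_se**2
        kcats = np.linspace(0.9 * res.kcat, 1.1 * res.kcat, 201)
        Kms = np.linspace(0.9 * res.Km, 1.1 * res.Km, 201)
        chi = np.array([[np.sum(w * (ds.y - kc * ds.x / (Km + ds.x)) ** 2)
                         for Km in Kms] for kc in kcats])
        i, j = np.unravel_index(np.argmin(chi), chi.shape)
        assert res.kcat == pytest.approx(kcats[i], rel=0.01)
        assert res.Km == pytest.approx(Kms[j], rel=0.01)

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            MichaelisMenten(gen_mm_dataset(20.0, 0.03, [0.01, 0.1, 1.0]))


class TestLrfMM:
    def test_identical_datasets_unit_lrf_any_target(self):
        a = gen_mm_dataset(10.0, 0.03, GRID, state="AIS")
        b = gen_mm_dataset(10.0, 0.03, GRID, state="PSS365")
        for target in ("kcat", "Km", "kcat_over_Km"):
            assert fit_lrf_mm(a, b, target).lrf == pytest.approx(1.0, abs=1e-7)

    def test_kcat_ratio_exact_on_noise_free_pair(self):
        a = gen_mm_dataset(10.0, 0.03, GRID, state="AIS")
        b = gen_mm_dataset(22.0, 0.03, GRID, state="PSS365")
        fit = fit_lrf_mm(a, b, "kcat")
        assert fit.lrf == pytest.approx(2.2, abs=1e-7)
        assert fit.shared_value == pytest.approx(10.0, abs=1e-6)

    def test_km_ratio_exact_on_noise_free_pair(self):
        a = gen_mm_dataset(10.0, 0.03, GRID, state="AIS")
        b = gen_mm_dataset(10.0, 0.06, GRID, state="PSS365")
        fit = fit_lrf_mm(a, b, "Km")
        assert fit.lrf == pytest.approx(2.0, abs=1e-7)
        assert fit.reference_state.value == "AIS"   # lower-Km state holds D=1

    def test_efficiency_target_matches_independent_fits(self):
        a = gen_mm_dataset(10.0, 0.03, GRID, state="AIS")
        b = gen_mm_dataset(18.0, 0.05, GRID, state="PSS365")
        fit = fit_lrf_mm(a, b, "kcat_over_Km")
        ra, rb = fit_michaelis_menten(a), fit_michaelis_menten(b)
        assert fit.lrf == pytest.approx(rb.kcat_over_Km / ra.kcat_over_Km,
                                        rel=1e-6)

    def test_lrf_invariant_under_y_scaling(self):
        a = gen_mm_dataset(10.0, 0.03, GRID, replicates=3, noise_sd=0.02,
                           config=SimConfig(seed=5), state="AIS")
        b = gen_mm_dataset(22.0, 0.04, GRID, replicates=3, noise_sd=0.02,
                           config=SimConfig(seed=6), state="PSS365")
        fit1 = fit_lrf_mm(a, b, "kcat")
        scale = 7.5
        a2 = PhotostateDataset(state="AIS", x=a.x, y=scale * a.y,
                               y_se=scale * a.y_se)
        b2 = PhotostateDataset(state="PSS365", x=b.x, y=scale * b.y,
                               y_se=scale * b.y_se)
        fit2 = fit_lrf_mm(a2, b2, "kcat")
        assert fit2.lrf == pytest.approx(fit1.lrf, rel=1e-6)


class TestCycleAnalysis:
    def test_alternating_slopes_recovered_exactly(self):
        curve, events, states = gen_cycle_curve(GLUTAMINASE_CONSTANTS,
                                                v_base=0.05, lrf=2.5, E0=0.1)
        res = analyze_cycles_activity(curve, events, GLUTAMINASE_CONSTANTS,
                                      states=states)
        assert len(res.per_cycle_lrf) == 6
        for lrf in res.per_cycle_lrf:
            assert lrf == pytest.approx(2.5, rel=1e-9)

    def test_constant_dark_control_has_zero_drift(self):
        curve, events, states = gen_cycle_curve(GLUTAMINASE_CONSTANTS,
                                                v_base=0.05, lrf=2.0, E0=0.1)
        dark, _, _ = gen_cycle_curve(GLUTAMINASE_CONSTANTS, v_base=0.05,
                                     lrf=1.0, E0=0.1)
        res = analyze_cycles_activity(curve, events, GLUTAMINASE_CONSTANTS,
                                      states=states, dark_control=dark)
        assert res.dark_drift[0] == pytest.approx(0.0, abs=1e-9)

    def test_decaying_activity_declines_monotonically_across_segments(self):
        # slow inactivation: near-linear per-segment decline of apparent v
        from photoxen.synthetic_data import gen_progress_curves
        curve = gen_progress_curves("exponential_decline", GLUTAMINASE_CONSTANTS,
                                    v=0.05, E0=0.1, t_end=2100.0, n_points=701,
                                    decline_lambda=3e-4)
        events = [700.0, 1400.0]
        res = analyze_cycles_activity(curve, events, GLUTAMINASE_CONSTANTS,
                                      states=["AIS"] * 3)
        acts = [s.v_over_E0 for s in res.segments]
        assert acts[0] > acts[1] > acts[2]

    def test_overlapping_events_rejected(self):
        curve, events, states = gen_cycle_curve(GLUTAMINASE_CONSTANTS,
                                                v_base=0.05, lrf=2.0, E0=0.1)
        with pytest.raises(ValueError, match="overlap"):
            analyze_cycles_activity(curve, [100.0, 100.0],
                                    GLUTAMINASE_CONSTANTS)
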