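"""PAM quenching parameters: formulas, invariants, and trace extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pmfield as pf


class TestFvFm:
    @pytest.mark.parametrize("f0,fm,expected", [
        (1.0, 4.0, 0.75),
        (2.0, 8.0, 0.75),   # scale invariance
        (3.0, 3.0, 0.0),    # no variable fluorescence
    ])
    def test_values(self, f0, fm, expected):
        assert pf.fvfm(f0, fm) == pytest.approx(expected)

    def test_fm_below_f0_rejected(self):
        with pytest.raises(ValueError):
            pf.fvfm(4.0, 1.0)
        with pytest.raises(ValueError):
            pf.fvfm(0.0, 4.0)


class TestPhi2AndLef:
    def test_phi2_value(self):
        assert pf.phi2(500.0, 2000.0) == pytest.approx(0.75)

    def test_phi2_rejects_fs_above_fmp(self):
        with pytest.raises(ValueError):
            pf.phi2(2100.0, 2000.0)

    def test_lef_with_defaults(self):
        assert pf.lef(0.5, 100.0) == pytest.approx(21.0)

    def test_lef_zero_par(self):
        assert pf.lef(0.7, 0.0) == 0.0

    def test_lef_negative_par_rejected(self):
        with pytest.raises(ValueError):
            pf.lef(0.5, -10.0)


class TestSternVolmer:
    def test_arithmetic(self):
        qe, qi = pf.qe_qi_sv(4000.0, 1000.0, 2000.0)
        assert qe == pytest.approx(2.0)
        assert qi == pytest.approx(1.0)

    def test_no_quenching(self):
        assert pf.qe_qi_sv(4000.0, 4000.0, 4000.0) == (0.0, 0.0)

    def test_all_quenching_is_slow(self):
        qe, qi = pf.qe_qi_sv(4000.0, 2000.0, 2000.0)
        assert qe == 0.0
        assert qi == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pf.qe_qi_sv(4000.0, 0.0, 2000.0)

    @given(fm=st.floats(100.0, 1e5), fmp_frac=st.floats(0.1, 1.0),
           rec_frac=st.floats(0.1, 1.0))
    def test_qe_plus_qi_equals_total_npq(self, fm, fmp_frac, rec_frac):
        fm_rec = fm * max(rec_frac, fmp_frac)
        fmp = fm * fmp_frac
        qe, qi = pf.qe_qi_sv(fm, fmp, fm_rec)
        assert qe + qi == pytest.approx(fm / fmp - 1.0, rel=1e-12, abs=1e-12)

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        qe1, qi1 = pf.qe_qi_sv(4000.0, 1500.0, 2500.0)
        qe2, qi2 = pf.qe_qi_sv(4000.0 * scale, 1500.0 * scale, 2500.0 * scale)
        assert (qe2, qi2) == pytest.approx((qe1, qi1))


class TestQl:
    def test_fully_oxidized(self):
        assert pf.ql(500.0, 2000.0, 500.0) == pytest.approx(1.0)

    def test_fully_reduced(self):
        assert pf.ql(2000.0, 2000.0, 500.0) == 0.0

    def test_intermediate(self):
        assert pf.ql(800.0, 2000.0, 500.0) == pytest.approx(0.5)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            pf.ql(800.0, 500.0, 500.0)


class TestF0Prime:
    def test_no_quenching_returns_f0(self):
        f0, fm = 1000.0, 4000.0
        fv = pf.fvfm(f0, fm)
        assert pf.estimate_f0prime(f0, fv, fm) == pytest.approx(f0)

    @given(fmp_frac=st.floats(0.2, 0.999))
    def test_quenching_lowers_f0prime(self, fmp_frac):
        f0, fm = 1000.0, 4000.0
        fv = pf.fvfm(f0, fm)
        f0p = pf.estimate_f0prime(f0, fv, fm * fmp_frac)
        assert f0p <= f0 + 1e-9

    def test_round_trip_ql_with_estimated_f0prime(self, params):
        lv = pf.fluorescence_levels(params, dpH_mV=40.0, q_L=0.4)
        fv = params.fvfm_dark
        f0p_est = pf.estimate_f0prime(lv["F0"], fv, float(lv["FMp"]))
        ql_est = pf.ql(float(lv["FS"]), float(lv["FMp"]), f0p_est)
        assert ql_est == pytest.approx(0.4, rel=0.02)


class TestAggregation:
    def test_constant_integral(self):
        t = np.linspace(0.0, 16.0, 30)
        assert pf.integrate_daily(t, np.full(30, 2.0)) == pytest.approx(32.0)

    def test_zero_integral(self):
        assert pf.integrate_daily([0, 8, 16], [0, 0, 0]) == 0.0

    def test_triangle_area(self):
        assert pf.integrate_daily([0, 1, 2], [0, 1, 0]) == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pf.integrate_daily([1.0], [2.0])

    @pytest.mark.parametrize("m,w,expected", [
        (3.0, 3.0, 0.0), (4.0, 2.0, 1.0), (0.5, 2.0, -2.0)])
    def test_log2_fold_change(self, m, w, expected):
        assert pf.log2_fold_change(m, w) == pytest.approx(expected)

    def test_log2_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pf.log2_fold_change(0.0, 1.0)


class TestTraceExtraction:
    @pytest.fixture
    def pulse_setup(self, params):
        schedule = pf.LightSchedule(((0.0, 0.0), (50.0, 500.0), (650.0, 0.0)),
                                    1500.0 / 3600.0, "constant")
        series = pf.simulate_pmf_dynamics(params, schedule, dt=1.0,
                                          t_end=1400.0)
        return series

    def test_round_trip_matches_ground_truth_within_1pc(self, params, pulse_setup):
        series = pulse_setup
        trace = pf.synthesize_fluorescence_trace(series, params,
                                                 [10.0, 640.0, 1350.0])
        recs = pf.extract_pulses(trace, irradiance_at=lambda t: 500.0)
        assert len(recs) == 1
        q = pf.compute_pam(recs[0])
        i = int(np.searchsorted(series["time_s"].to_numpy(), 640.0))
        truth = pf.fluorescence_levels(
            params, max(series["dpH_mV"].iat[i] - params.dpH_dark_mV, 0.0),
            series["q_L"].iat[i])
        assert q.fvfm == pytest.approx(params.fvfm_dark, rel=1e-6)
        assert q.qe_sv == pytest.approx(float(truth["qe"]), rel=0.01)
        assert q.qi == pytest.approx(0.0, abs=1e-9)
        assert q.ql == pytest.approx(float(series["q_L"].iat[i]), rel=0.01)

    def test_damage_surfaces_as_qi(self, params, pulse_setup):
        series = pulse_setup
        # damage accrues after the dark-adapted reference pulse
        dmg = np.where(series["time_s"].to_numpy() < 20.0, 0.0, 0.2)
        trace = pf.synthesize_fluorescence_trace(series, params,
                                                 [10.0, 640.0, 1350.0],
                                                 damage_series=dmg)
        recs = pf.extract_pulses(trace, irradiance_at=lambda t: 500.0)
        q = pf.compute_pam(recs[0])
        assert q.qi == pytest.approx(params.qi_per_damage * 0.2, rel=0.01)

    def test_unsorted_pulses_rejected(self, params, pulse_setup):
        with pytest.raises(ValueError):
            pf.synthesize_fluorescence_trace(pulse_setup, params, [640.0, 10.0])

    def test_pulse_outside_trace_rejected(self, params, pulse_setup):
        with pytest.raises(ValueError):
            pf.synthesize_fluorescence_trace(pulse_setup, params, [2000.0])
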