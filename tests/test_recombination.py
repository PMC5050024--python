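"""Field-dependent recombination model, calibration chain, q_I ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pmfield as pf
from pmfield.recombination import stabilization_rate_factor


class TestRecombinationRate:
    def test_intrinsic_rate_at_zero_field_fully_reduced(self):
        est = pf.recombination_rate(q_L=0.0, dpsi_mV=0.0)
        assert est.v_r == pytest.approx(0.3)

    def test_fully_oxidized_qa_gives_zero(self):
        assert pf.recombination_rate(1.0, 80.0).v_r == 0.0

    def test_one_decade_per_60_mV_physical(self):
        assert pf.recombination_rate(0.0, 60.0).v_r == pytest.approx(3.0)

    def test_as_printed_convention_negates_exponent(self):
        model = pf.RecombinationModel(sign_convention="as_printed")
        est = pf.recombination_rate(0.0, 60.0, model)
        assert est.v_r == pytest.approx(0.03)
        assert est.sign_convention == "as_printed"

    def test_dielectric_weight_scales_field(self):
        est = pf.recombination_rate(0.0, 60.0, dielectric_weight=0.5)
        assert est.v_r == pytest.approx(0.3 * 10 ** 0.5)

    def test_q_L_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pf.recombination_rate(1.5, 0.0)

    @given(ql1=st.floats(0.0, 1.0), ql2=st.floats(0.0, 1.0),
           d1=st.floats(0.0, 200.0), d2=st.floats(0.0, 200.0))
    def test_monotone_in_ql_and_field(self, ql1, ql2, d1, d2):
        lo_ql, hi_ql = sorted([ql1, ql2])
        lo_d, hi_d = sorted([d1, d2])
        assert (pf.recombination_rate(hi_ql, lo_d).v_r
                <= pf.recombination_rate(lo_ql, lo_d).v_r + 1e-12)
        assert (pf.recombination_rate(lo_ql, lo_d).v_r
                <= pf.recombination_rate(lo_ql, hi_d).v_r + 1e-12)

    @given(dpsi=st.floats(0.0, 150.0), de0=st.floats(0.3, 1.0))
    def test_energy_gap_form_consistent_with_field_form(self, dpsi, de0):
        # Eq in energy terms: rate ∝ 10^(-dE_stab/0.06), dE_stab = dE0 - dpsi/1000
        prefactor = 0.3 / stabilization_rate_factor(de0)
        v_energy = prefactor * stabilization_rate_factor(de0 - dpsi / 1000.0)
        v_field = pf.recombination_rate(0.0, dpsi).v_r
        assert v_energy == pytest.approx(v_field, rel=1e-9)


class TestCalibration:
    def test_flash_amplitude_maps_to_40_mV(self):
        cal = pf.Calibration()
        assert pf.calibrate_ecs_to_mv(cal.flash_ecs_amplitude, cal) == \
            pytest.approx(40.0)

    def test_zero_and_linearity(self):
        cal = pf.Calibration()
        assert pf.calibrate_ecs_to_mv(0.0, cal) == 0.0
        assert pf.calibrate_ecs_to_mv(3 * cal.flash_ecs_amplitude, cal) == \
            pytest.approx(120.0)

    @given(scale=st.floats(0.0, 50.0))
    def test_homogeneous_degree_one(self, scale):
        cal = pf.Calibration()
        base = pf.calibrate_ecs_to_mv(1e-4, cal)
        assert pf.calibrate_ecs_to_mv(scale * 1e-4, cal) == \
            pytest.approx(scale * base, rel=1e-12, abs=1e-12)

    def test_dark_dpsi_printed_vs_exact(self):
        cal = pf.Calibration()
        assert cal.dark_dpsi_mV == 60.0
        assert cal.dark_dpsi_exact_mV == pytest.approx(56.0)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            pf.Calibration(flash_ecs_amplitude=0.0)


class TestFoldChangeAndRanges:
    def test_fold_change_identity_and_decade(self):
        assert pf.predicted_fold_change(0.0) == 1.0
        assert pf.predicted_fold_change(60.0) == pytest.approx(10.0)

    def test_flash_scale_field_rounds_to_five_fold(self):
        fold = pf.predicted_fold_change(40.0)
        assert fold == pytest.approx(10 ** (2.0 / 3.0))
        assert round(fold) == 5

    def test_steady_state_range_defaults(self):
        assert pf.steady_state_dpsi_range() == pytest.approx((30.0, 120.0))

    def test_steady_state_range_arithmetic(self):
        assert pf.steady_state_dpsi_range(200, 200, 0.2, 0.6) == \
            pytest.approx((40.0, 120.0))
        assert pf.steady_state_dpsi_range(150, 200, 1.0, 1.0) == \
            pytest.approx((150.0, 200.0))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            pf.steady_state_dpsi_range(200, 150, 0.2, 0.6)

    def test_transient_bounds_defaults(self):
        assert pf.transient_dpsi_bounds() == pytest.approx((150.0, 260.0))

    def test_transient_bounds_arithmetic(self):
        assert pf.transient_dpsi_bounds(0.0, (0.0, 0.0), (0.0, 0.0)) == (0.0, 0.0)
        assert pf.transient_dpsi_bounds(50.0) == pytest.approx((140.0, 250.0))


def _anova_table(rng, n=24, effect=0.0):
    ss = rng.normal(1.0, 0.3, n)
    inv = rng.normal(1.0, 0.3, n)
    qi = effect * ss + rng.normal(0.0, 0.2, n)
    return pd.DataFrame({"qi": qi, "ecs_ss": ss, "ecs_inv": inv})


class TestQiAssociation:
    def test_constructed_dpsi_effect_dominates(self):
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(20):
            rep = pf.qi_association(_anova_table(rng, effect=1.0))
            if rep.f_ecs_ss > rep.f_ecs_inv:
                wins += 1
        assert wins >= 19

    def test_duplicate_predictors_rejected(self):
        rng = np.random.default_rng(1)
        tbl = _anova_table(rng)
        tbl["ecs_inv"] = tbl["ecs_ss"]
        with pytest.raises(ValueError, match="collinear"):
            pf.qi_association(tbl)

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(2)
        tbl = _anova_table(rng)
        tbl["ecs_inv"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            pf.qi_association(tbl)

    def test_too_few_rows_rejected(self):
        tbl = pd.DataFrame({"qi": [1.0, 2.0], "ecs_ss": [0.1, 0.2],
                            "ecs_inv": [0.3, 0.1]})
        with pytest.raises(ValueError, match="3 complete rows"):
            pf.qi_association(tbl)

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(3)
        tbl = _anova_table(rng, n=12, effect=0.8)
        rep = pf.qi_association(tbl)
        # oracle: explicit least squares + extra-sum-of-squares F tests
        y = tbl["qi"].to_numpy()
        X_full = np.column_stack([np.ones(len(tbl)), tbl["ecs_ss"], tbl["ecs_inv"]])
        def sse(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return float(r @ r)
        sse_full = sse(X_full)
        df_resid = len(tbl) - 3
        for col, f_obs in ((1, rep.f_ecs_ss), (2, rep.f_ecs_inv)):
            X_drop = np.delete(X_full, col, axis=1)
            f_oracle = (sse(X_drop) - sse_full) / (sse_full / df_resid)
            assert f_obs == pytest.approx(f_oracle, rel=1e-8)
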