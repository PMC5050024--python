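"""ECS quantification: deconvolution algebra, DIRK fits, pmf partitioning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pmfield as pf
from pmfield.ecs import FitError, _fit_first_order


class TestDeconvolution:
    def test_equal_channels_cancel(self):
        c = np.full(50, 0.7)
        np.testing.assert_allclose(pf.deconvolute_ecs(c, c, c), 0.0, atol=1e-15)

    def test_wavelength_linear_background_cancels(self):
        b, c = np.full(20, 1.3), np.full(20, 0.4)
        out = pf.deconvolute_ecs(b - c, b, b + c)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_pure_520_signal_passes_through(self):
        b = np.full(20, 0.2)
        s = np.linspace(0, 1e-3, 20)
        np.testing.assert_allclose(pf.deconvolute_ecs(b, b + s, b), s, atol=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pf.deconvolute_ecs(np.ones(3), np.ones(4), np.ones(4))

    @given(b0=st.floats(-1, 1), b1=st.floats(-1e-2, 1e-2),
           slope=st.floats(-1e-3, 1e-3))
    def test_invariant_to_any_wavelength_linear_background(self, b0, b1, slope):
        t = np.linspace(0, 10, 30)
        sig = 1e-3 * np.exp(-t)
        drift = b0 + b1 * t
        out = pf.deconvolute_ecs(drift + slope * (505 - 520),
                                 drift + sig + slope * (520 - 520),
                                 drift + slope * (535 - 520))
        np.testing.assert_allclose(out, sig, atol=1e-9)


class TestDirkFit:
    def test_constructed_decay_recovers_conductivity(self):
        t = np.linspace(0, 0.5, 200)
        y = 2e-3 * np.exp(-t / 0.05) + 1e-4
        fit = pf.fit_dirk((t, y), dark_window=(0.0, 0.5))
        assert fit.g_H_plus == pytest.approx(20.0, abs=1e-6 * 20.0)
        assert fit.tau == pytest.approx(0.05, rel=1e-6)
        assert fit.ecs_t == pytest.approx(2e-3, rel=1e-6)
        assert fit.baseline == pytest.approx(1e-4, rel=1e-4)

    def test_flat_trace_is_a_fit_failure(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(FitError):
            pf.fit_dirk((t, np.full(100, 0.3)), dark_window=(0.0, 1.0))

    def test_rising_trace_is_a_fit_failure(self):
        t = np.linspace(0, 1, 100)
        with pytest.raises(FitError):
            pf.fit_dirk((t, 1e-3 * (1 - np.exp(-t / 0.1))), dark_window=(0.0, 1.0))

    def test_too_few_samples_rejected(self):
        t = np.linspace(0, 1, 5)
        with pytest.raises(FitError):
            pf.fit_dirk((t, np.exp(-t)), dark_window=(0.0, 1.0))

    def test_noisy_recovery_within_5_percent(self, rng):
        t = np.linspace(0, 0.5, 500)
        errs = []
        for _ in range(40):
            y = 1e-3 * np.exp(-t / 0.05) + rng.normal(0, 1e-5, t.size)
            fit = pf.fit_dirk((t, y), dark_window=(0.0, 0.5))
            errs.append(abs(fit.g_H_plus - 20.0) / 20.0)
        assert np.median(errs) < 0.02
        assert max(errs) < 0.05

    def test_agrees_with_brute_force_grid_search(self):
        t = np.linspace(0, 0.4, 20)
        true_a, true_tau, true_c = 1.5e-3, 0.08, 2e-4
        y = true_a * np.exp(-t / true_tau) + true_c
        fit = pf.fit_dirk((t, y), dark_window=(0.0, 0.4))
        # independent oracle: exhaustive grid around broad ranges
        taus = np.linspace(0.02, 0.2, 400)
        best = (np.inf, None)
        for tau in taus:
            basis = np.exp(-t / tau)
            A = np.vstack([basis, np.ones_like(t)]).T
            coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = float(np.sum((A @ coef - y) ** 2))
            if sse < best[0]:
                best = (sse, tau)
        assert fit.tau == pytest.approx(best[1], rel=1e-3)


class TestPartition:
    def test_definitional_arithmetic(self):
        part = pf.partition_from_levels(S=1.0, D=0.0, M=-0.5)
        assert (part.ecs_t, part.ecs_ss, part.ecs_inv) == (1.5, 1.0, 0.5)
        assert part.fraction_dpsi == pytest.approx(2.0 / 3.0)

    def test_degenerate_levels_give_zero(self):
        part = pf.partition_from_levels(0.3, 0.3, 0.3)
        assert (part.ecs_t, part.ecs_ss, part.ecs_inv) == (0.0, 0.0, 0.0)
        assert "zero_amplitude" in part.flags

    def test_no_inversion_clamped_with_flag(self):
        part = pf.partition_from_levels(S=1.0, D=0.0, M=0.2)
        assert part.ecs_inv == 0.0
        assert "no_inversion" in part.flags

    def test_conservation_on_noiseless_trace(self):
        trace = pf.synthesize_ecs_from_amplitudes(0.8, 0.4, g_H_plus=20.0)
        part = pf.partition_pmf(trace, light_window=(10.0, 15.0),
                                dark_window=(15.0, 17.0),
                                dark_baseline_window=(0.0, 5.0))
        assert part.ecs_t == pytest.approx(part.ecs_ss + part.ecs_inv, abs=1e-9)

    def test_round_trip_against_generator_ground_truth(self):
        truth = (1.0, 0.5)
        trace = pf.synthesize_ecs_from_amplitudes(*truth, g_H_plus=20.0,
                                                  chl_per_area=1.0)
        part = pf.partition_pmf(trace, light_window=(10.0, 15.0),
                                dark_window=(15.0, 17.0),
                                dark_baseline_window=(0.0, 5.0),
                                chl_per_area=1.0)
        assert part.ecs_ss == pytest.approx(truth[0], abs=1e-6)
        assert part.ecs_inv == pytest.approx(truth[1], abs=1e-6)

    def test_scale_equivariance(self):
        t1 = pf.synthesize_ecs_from_amplitudes(0.8, 0.4, chl_per_area=1.0)
        t3 = pf.synthesize_ecs_from_amplitudes(2.4, 1.2, chl_per_area=1.0)
        win = dict(light_window=(10.0, 15.0), dark_window=(15.0, 17.0),
                   dark_baseline_window=(0.0, 5.0))
        p1 = pf.partition_pmf(t1, **win)
        p3 = pf.partition_pmf(t3, **win)
        assert p3.ecs_t == pytest.approx(3 * p1.ecs_t, rel=1e-9)
        assert p3.ecs_ss == pytest.approx(3 * p1.ecs_ss, rel=1e-9)
        assert p3.ecs_inv == pytest.approx(3 * p1.ecs_inv, rel=1e-9)
        f1 = pf.fit_dirk(t1, dark_window=(15.0, 17.0))
        f3 = pf.fit_dirk(t3, dark_window=(15.0, 17.0))
        assert f3.g_H_plus == pytest.approx(f1.g_H_plus, rel=1e-6)


class TestNormalization:
    def test_division(self):
        assert pf.normalize_to_chl(1e-3, 20.0) == pytest.approx(5e-5)
        assert pf.normalize_to_chl(0.0, 7.0) == 0.0

    def test_round_trip_identity(self):
        v = 3.3e-4
        assert pf.normalize_to_chl(v, 20.0) * 20.0 == pytest.approx(v)

    def test_nonpositive_chlorophyll_rejected(self):
        with pytest.raises(ValueError):
            pf.normalize_to_chl(1.0, 0.0)


class TestFlashPair:
    def test_subtraction(self):
        act, flags = pf.psii_activity_from_flash_pair(pf.FlashPair(1.0e-3, 4.0e-4))
        assert act == pytest.approx(6.0e-4)
        assert flags == ()

    def test_no_functional_psii(self):
        act, _ = pf.psii_activity_from_flash_pair(pf.FlashPair(5e-4, 5e-4))
        assert act == 0.0

    def test_negative_flagged_not_clipped(self):
        act, flags = pf.psii_activity_from_flash_pair(pf.FlashPair(3e-4, 5e-4))
        assert act == pytest.approx(-2e-4)
        assert "negative_activity" in flags

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pf.psii_activity_from_flash_pair(pf.FlashPair(np.nan, 1.0))

    def test_round_trip_through_generator(self):
        pair = pf.simulate_flash_ecs(0.6, psi_amplitude=4e-4)
        act, _ = pf.psii_activity_from_flash_pair(pair)
        assert act / 4e-4 == pytest.approx(0.6, abs=1e-12)

    def test_zero_fraction_gives_equal_flashes(self):
        pair = pf.simulate_flash_ecs(0.0)
        assert pair.amp1 == pair.amp2


class TestP700:
    def test_constructed_decay_half_time(self):
        t = np.linspace(0, 0.05, 200)
        k = np.log(2) / 0.005
        y = 1e-3 * np.exp(-k * t) + 1e-5
        fit = pf.fit_p700_halftime(t, y, dark_window=(0.0, 0.05))
        assert fit.half_time == pytest.approx(0.005, rel=1e-6)

    def test_flat_series_fails(self):
        t = np.linspace(0, 0.05, 100)
        with pytest.raises(FitError):
            pf.fit_p700_halftime(t, np.full(100, 1e-3), dark_window=(0.0, 0.05))

    def test_noisy_recovery_within_5_percent(self, rng):
        t = np.linspace(0, 0.05, 400)
        k = np.log(2) / 0.005
        errs = []
        for _ in range(30):
            y = 1e-3 * np.exp(-k * t) + rng.normal(0, 1e-5, t.size)
            fit = pf.fit_p700_halftime(t, y, dark_window=(0.0, 0.05))
            errs.append(abs(fit.half_time - 0.005) / 0.005)
        assert max(errs) < 0.05


def test_first_order_fit_rejects_amplitude_below_noise(rng):
    t = np.linspace(0, 1, 200)
    y = 1e-8 * np.exp(-t / 0.1) + rng.normal(0, 1e-6, t.size)
    with pytest.raises(FitError):
        _fit_first_order(t, y)
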