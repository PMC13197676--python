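"""DTNB kinetics: calibration, conversion, rate law, fitting."""

import numpy as np
import pytest

from covfrag.dtnb import (
    CalibrationError,
    SecondOrderFit,
    aggregate_replicates,
    calibrate_epsilon,
    correct_and_convert,
    fit_second_order,
    second_order_model,
    second_order_ode,
    tnb_from_dtnb,
)
from covfrag.synthetic import simulate_dtnb_run


class TestCalibration:
    def test_epsilon_from_blank(self):
        run = simulate_dtnb_run(0.0, epsilon_path=14000.0, noise_sd=0.0, background_level=0.0)
        # blank(0) = 14000 * 50e-6 = 0.70 AU -> 14000 AU/M back
        assert run.a412_blank[0] == pytest.approx(0.70)
        assert calibrate_epsilon(run) == pytest.approx(14000.0)

    def test_epsilon_linear_in_blank(self):
        run = simulate_dtnb_run(0.0, epsilon_path=28000.0, noise_sd=0.0)
        assert calibrate_epsilon(run) == pytest.approx(28000.0)

    def test_zero_blank_errors(self):
        run = simulate_dtnb_run(0.0, noise_sd=0.0)
        bad = type(run)(
            times=run.times,
            a412_reaction=run.a412_reaction,
            a412_compound_background=run.a412_compound_background,
            a412_blank=np.zeros_like(run.a412_blank),
        )
        with pytest.raises(CalibrationError):
            calibrate_epsilon(bad)

    def test_dtnb_stoichiometry(self):
        assert tnb_from_dtnb(25.0) == 50.0


class TestConversion:
    def test_no_reaction_gives_constant_A0(self):
        run = simulate_dtnb_run(0.0, noise_sd=0.0)
        cal = correct_and_convert(run, calibrate_epsilon(run))[0]
        assert np.allclose(cal.A_t, 100e-6)

    def test_full_consumption_endpoint(self):
        run = simulate_dtnb_run(50.0, noise_sd=0.0)  # very fast: all TNB gone
        cal = correct_and_convert(run, calibrate_epsilon(run))[0]
        assert cal.A_t[-1] == pytest.approx(50e-6, rel=1e-3)

    def test_absorbance_drop_maps_to_concentration(self):
        run = simulate_dtnb_run(0.0, epsilon_path=14000.0, noise_sd=0.0)
        rxn = run.a412_reaction.copy()
        rxn[0, -1] -= 0.14  # 0.14 AU drop = 10 uM TNB consumed
        run2 = type(run)(
            times=run.times,
            a412_reaction=rxn,
            a412_compound_background=run.a412_compound_background,
            a412_blank=run.a412_blank,
        )
        cal = correct_and_convert(run2, 14000.0)[0]
        assert cal.A0_effective - cal.A_t[-1] == pytest.approx(10e-6)

    def test_mass_balance_by_construction(self):
        run = simulate_dtnb_run(0.5, noise_sd=0.003, seed=7)
        cal = correct_and_convert(run, calibrate_epsilon(run))[0]
        lhs = cal.A0_effective - cal.A_t
        rhs = cal.B0_effective - cal.B_t
        assert np.allclose(lhs, rhs, atol=1e-15)


class TestRateLaw:
    def test_t_zero_returns_A0(self):
        for k2 in (0.0, 0.5, -0.1, 100.0):
            assert second_order_model(100e-6, 50e-6, k2, 0.0) == pytest.approx(100e-6)

    def test_k2_zero_constant(self):
        t = np.linspace(0, 1e5, 50)
        assert np.allclose(second_order_model(100e-6, 50e-6, 0.0, t), 100e-6)

    def test_equal_concentration_closed_form(self):
        a = second_order_model(100e-6, 100e-6, 1.0, 1e4)
        assert a == pytest.approx(50e-6)

    @pytest.mark.parametrize("A0,B0", [(100e-6, 50e-6), (50e-6, 100e-6), (100e-6, 99.9999e-6), (200e-6, 10e-6)])
    @pytest.mark.parametrize("k2", [0.01, 0.5, 3.0])
    def test_matches_ode_integration(self, A0, B0, k2):
        """The closed form agrees with step-by-step numerical integration
        of dA/dt = -k2 A B to better than 1e-6 relative error."""
        t = np.linspace(0, 4 * 3600, 25)
        closed = second_order_model(A0, B0, k2, t)
        ode = second_order_ode(A0, B0, k2, t)
        assert np.max(np.abs(closed - ode) / A0) < 1e-6

    def test_equal_branch_continuity(self):
        t = np.linspace(0, 1e4, 11)
        A0, k2 = 100e-6, 1.0
        equal = A0 / (1 + A0 * k2 * t)
        for eps in (1e-9, -1e-9):
            near = second_order_model(A0, A0 * (1 + eps), k2, t)
            assert np.max(np.abs(near - equal)) < 1e-9 * A0

    def test_nonincreasing_for_positive_k2(self):
        t = np.linspace(0, 4 * 3600, 100)
        a = second_order_model(100e-6, 50e-6, 0.8, t)
        assert np.all(np.diff(a) <= 1e-18)


class TestFitting:
    def test_noise_free_recovery_at_benchmark_rate(self):
        """A noise-free run generated at the iodoacetamide benchmark rate
        (k2 = 2.6 M-1 s-1) is recovered to better than 0.1%."""
        run = simulate_dtnb_run(2.6, noise_sd=0.0)
        fit = fit_second_order(correct_and_convert(run, calibrate_epsilon(run))[0])
        assert fit.converged
        assert abs(fit.k2 - 2.6) / 2.6 < 1e-3

    def test_constant_series_fits_zero(self):
        run = simulate_dtnb_run(0.0, noise_sd=0.0)
        fit = fit_second_order(correct_and_convert(run, calibrate_epsilon(run))[0])
        assert fit.k2 == pytest.approx(0.0, abs=1e-9)

    def test_background_drift_yields_negative_k2(self):
        """A slight downward drift in the compound-background wells makes
        the corrected signal rise, which fits as a small negative rate."""
        run = simulate_dtnb_run(0.0, drift=-2e-6, noise_sd=0.0)
        fit = fit_second_order(correct_and_convert(run, calibrate_epsilon(run))[0])
        assert fit.k2 < 0

    def test_needs_five_points(self):
        run = simulate_dtnb_run(0.1, noise_sd=0.0, duration_s=900.0, interval_s=300.0)
        cal = correct_and_convert(run, calibrate_epsilon(run))[0]
        with pytest.raises(ValueError):
            fit_second_order(cal)


class TestAggregation:
    def test_identical_triplicate_shrinks_sd(self):
        f = SecondOrderFit(k2=1.0, k2_sd=0.3, converged=True, residual_rms=0.0)
        agg = aggregate_replicates([f, f, f])
        assert agg.k2 == 1.0
        assert agg.k2_sd == pytest.approx(0.3 / np.sqrt(3))

    def test_single_fit_is_identity(self):
        f = SecondOrderFit(k2=0.5, k2_sd=0.1, converged=True, residual_rms=0.0)
        agg = aggregate_replicates([f])
        assert (agg.k2, agg.k2_sd) == (0.5, 0.1)

    def test_mean_of_spread_fits(self):
        fits = [SecondOrderFit(k, 0.0, True, 0.0) for k in (1.0, 2.0, 3.0)]
        agg = aggregate_replicates(fits)
        assert agg.k2 == 2.0
        assert agg.k2_sd == 0.0

    def test_no_converged_fits_errors(self):
        bad = SecondOrderFit(np.nan, np.nan, converged=False, residual_rms=np.nan)
        with pytest.raises(ValueError):
            aggregate_replicates([bad])
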