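"""DSF: Tm extraction, thermal shifts, hit calling, specificity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from covfrag.dsf import (
    MeltResult,
    NoTransitionError,
    call_hit,
    classify_specificity,
    compute_tm,
    delta_tm,
    dose_time_summary,
)
from covfrag.synthetic import simulate_melt_curve


class TestComputeTm:
    def test_symmetric_sigmoid_inflection(self):
        curve = simulate_melt_curve(46.0)
        assert compute_tm(curve) == pytest.approx(46.0, abs=1e-6)

    def test_flat_curve_raises(self):
        curve = simulate_melt_curve(46.0)
        flat = type(curve)(temperatures=curve.temperatures, fluorescence=np.full_like(curve.temperatures, 100.0))
        with pytest.raises(NoTransitionError):
            compute_tm(flat)

    def test_monotone_decreasing_curve_raises(self):
        curve = simulate_melt_curve(46.0)
        down = type(curve)(temperatures=curve.temperatures, fluorescence=1000.0 - 5.0 * curve.temperatures)
        with pytest.raises(NoTransitionError):
            compute_tm(down)

    def test_noisy_curve_within_02C(self):
        curve = simulate_melt_curve(44.3, noise_cv=0.01, seed=11)
        assert compute_tm(curve) == pytest.approx(44.3, abs=0.2)

    def test_sloped_baselines_small_bias(self):
        curve = simulate_melt_curve(44.3, native_baseline=(100.0, 3.0), unfolded_baseline=(1000.0, -5.0))
        assert compute_tm(curve) == pytest.approx(44.3, abs=0.1)

    def test_grid_density_invariance(self):
        """Doubling the temperature-grid density moves the noise-free Tm
        estimate by less than 0.05 degC."""
        coarse = compute_tm(simulate_melt_curve(46.37, step=0.25))
        fine = compute_tm(simulate_melt_curve(46.37, step=0.125))
        assert abs(coarse - fine) < 0.05

    def test_translation_recovers_offset(self):
        a = compute_tm(simulate_melt_curve(45.0))
        b = compute_tm(simulate_melt_curve(48.5))
        assert b - a == pytest.approx(3.5, abs=0.02)


class TestDeltaTm:
    def test_self_shift_zero(self):
        r = MeltResult(tm=46.0, tm_sd=0.3)
        shift, sd = delta_tm(r, r)
        assert shift == 0.0

    def test_printed_strongest_stabilizer_shift(self):
        shift, _ = delta_tm(MeltResult(tm=50.45), MeltResult(tm=46.0))
        assert shift == pytest.approx(4.45)

    def test_quadrature_sd(self):
        _, sd = delta_tm(MeltResult(46.0, 0.3), MeltResult(45.0, 0.4))
        assert sd == pytest.approx(0.5)

    def test_antisymmetric(self):
        a, b = MeltResult(48.0, 0.1), MeltResult(46.0, 0.2)
        assert delta_tm(a, b)[0] == -delta_tm(b, a)[0]


class TestHitCalling:
    def test_any_condition_above_one_degree(self):
        assert call_hit([0.2, 0.5, 1.2, 0.9]) is True

    def test_just_under_threshold_not_hit(self):
        assert call_hit([0.95, 0.5]) is False
        assert call_hit([1.0]) is False  # strictly greater

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            call_hit([np.nan, np.nan])

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=6), st.floats(0, 3))
    @settings(deadline=None)
    def test_monotone_in_each_shift(self, shifts, bump):
        if call_hit(shifts):
            assert call_hit([shifts[0] + bump] + shifts[1:])


class TestDoseTimeSummary:
    CONC = [(1000.0, 3.0), (250.0, 2.0), (62.5, 1.4), (15.63, 1.1), (3.91, 0.4)]

    def test_lowest_stabilizing_concentration(self):
        row = dose_time_summary("SN054-like", self.CONC, [(0.167, 1.2), (24.0, 3.0)])
        assert row.min_stabilizing_conc == pytest.approx(15.63)
        assert row.first_stabilizing_time == pytest.approx(0.167)

    def test_never_reaching_threshold(self):
        row = dose_time_summary("weak", [(c, 0.5) for c, _ in self.CONC], [(24.0, 0.9)])
        assert row.min_stabilizing_conc is None
        assert row.first_stabilizing_time is None
        assert not row.hit

    def test_lowest_tested_already_stabilizing(self):
        row = dose_time_summary("strong", [(3.91, 1.5), (1000.0, 2.0)], [])
        assert row.min_stabilizing_conc == pytest.approx(3.91)

    def test_high_concentration_destabilization_flag(self):
        conc = [(62.5, 1.5), (1000.0, -2.0)]
        assert dose_time_summary("x", conc, []).destabilizing_at_high_conc


class TestSpecificity:
    @pytest.mark.parametrize(
        "shifts,label",
        [
            ((4.45, 2.25, -0.3), "cys220-plus-surface-arylation"),
            ((0.3, 2.7, -2.1), "masked-stabilization"),
            ((0.0, 0.0, 0.0), "inactive"),
            ((2.0, 1.8, 0.1), "cys220-selective"),
            ((1.5, 0.2, 1.4), "nonspecific"),
        ],
    )
    def test_reference_patterns(self, shifts, label):
        assert classify_specificity("x", *shifts).label == label

    @given(st.floats(-6, 6), st.floats(-6, 6), st.floats(-6, 6))
    @settings(deadline=None)
    def test_total_and_deterministic(self, y, cl, wt):
        first = classify_specificity("x", y, cl, wt).label
        assert first in {
            "cys220-selective",
            "cys220-plus-surface-arylation",
            "masked-stabilization",
            "nonspecific",
            "inactive",
        }
        assert classify_specificity("x", y, cl, wt).label == first
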