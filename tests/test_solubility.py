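"""Turbidimetric solubility: dilution series, scattering, MIS/MFS."""

import numpy as np
import pytest

from covfrag.solubility import (
    BELOW_LOWEST,
    TurbidityTrace,
    call_mis_mfs,
    detect_scattering,
    make_dilution_series,
)
from covfrag.synthetic import simulate_turbidity

WL = tuple(np.arange(600.0, 801.0, 25.0))


def _trace(conc, offsets, base=0.04):
    """Trace with a constant extinction offset per cycle."""
    n = len(WL)
    rows = np.vstack([np.full(n, base + off) for off in offsets])
    return TurbidityTrace(conc, tuple(range(len(offsets))), WL, rows)


class TestDilutionSeries:
    def test_assay_ladder_ends_at_0429(self):
        s = make_dilution_series(5.0, 0.8, 12)
        assert s.displayed()[0] == 5.0
        assert s.displayed()[-1] == pytest.approx(0.429)

    def test_single_step_identity(self):
        assert make_dilution_series(3.3, 0.8, 1).concentrations == (3.3,)

    def test_reduced_ladder_from_2048(self):
        assert make_dilution_series(2.048, 0.8, 3).displayed() == (2.05, 1.64, 1.31)

    @pytest.mark.parametrize("args", [(-1.0, 0.8, 3), (5.0, 1.2, 3), (5.0, 0.8, 0)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_dilution_series(*args)


class TestScatteringDetection:
    def test_identical_to_blank_is_clear(self):
        blank = _trace(0.0, [0.0, 0.0])
        assert detect_scattering(_trace(5.0, [0.0, 0.0]), blank, 0) is False

    def test_large_offset_scatters(self):
        blank = _trace(0.0, [0.0, 0.0])
        assert detect_scattering(_trace(5.0, [0.5, 0.5]), blank, 0) is True

    def test_exact_threshold_is_clear(self):
        """Strict inequality: a trace sitting exactly at blank+threshold
        does not count as scattering (binary-exact offsets)."""
        blank = _trace(0.0, [0.0], base=0.0)
        at_threshold = _trace(5.0, [0.25], base=0.0)
        assert detect_scattering(at_threshold, blank, 0, abs_threshold=0.25) is False
        just_above = _trace(5.0, [0.2501], base=0.0)
        assert detect_scattering(just_above, blank, 0, abs_threshold=0.25) is True

    def test_mismatched_grids_rejected(self):
        blank = TurbidityTrace(0.0, (0,), (600.0, 700.0), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            detect_scattering(_trace(5.0, [0.0]), blank, 0)


class TestMisMfs:
    BLANK = _trace(0.0, [0.0, 0.0])

    def _series(self, scatter_first, scatter_last):
        concs = make_dilution_series(5.0, 0.8, 12).concentrations
        return [
            _trace(c, [0.5 if c in scatter_first else 0.0, 0.5 if c in scatter_last else 0.0])
            for c in concs
        ]

    def test_scattering_above_2p56_both_cycles(self):
        concs = make_dilution_series(5.0, 0.8, 12).concentrations
        high = {c for c in concs if c >= 2.56}
        rec = call_mis_mfs(self._series(high, high), self.BLANK)
        assert rec.mis == pytest.approx(2.048)
        assert rec.mfs == pytest.approx(2.048)

    def test_clear_everywhere_reports_top(self):
        rec = call_mis_mfs(self._series(set(), set()), self.BLANK)
        assert rec.mis == rec.mfs == 5.0

    def test_late_precipitation_lowers_mfs_only(self):
        concs = make_dilution_series(5.0, 0.8, 12).concentrations
        rec = call_mis_mfs(self._series(set(), {concs[0]}), self.BLANK)
        assert rec.mis == 5.0
        assert rec.mfs == pytest.approx(4.0)

    def test_scattering_at_lowest_reports_marker(self):
        concs = make_dilution_series(5.0, 0.8, 12).concentrations
        rec = call_mis_mfs(self._series(set(concs), set(concs)), self.BLANK)
        assert rec.mis == BELOW_LOWEST

    def test_nonmonotone_noise_resolved_conservatively(self):
        """A clear well above a scattering one does not rescue it: the call
        is the highest concentration below the lowest scattering one."""
        concs = make_dilution_series(5.0, 0.8, 12).concentrations
        rec = call_mis_mfs(self._series({concs[2]}, {concs[2]}), self.BLANK)
        assert rec.mis == pytest.approx(concs[3])

    def test_added_scattering_never_raises_call(self):
        concs = make_dilution_series(5.0, 0.8, 12).concentrations
        base = {concs[1]}
        rec0 = call_mis_mfs(self._series(base, base), self.BLANK)
        for extra in concs[::3]:
            rec1 = call_mis_mfs(self._series(base | {extra}, base | {extra}), self.BLANK)
            assert rec1.mis <= rec0.mis


class TestSimulatedTurbidity:
    def test_limit_above_top_gives_top(self):
        series = make_dilution_series(5.0, 0.8, 12)
        traces, blank = simulate_turbidity(8.0, series, seed=1, baseline_sd=0.001)
        rec = call_mis_mfs(traces, blank)
        assert rec.mis == rec.mfs == 5.0

    def test_limit_inside_ladder_round_trip(self):
        series = make_dilution_series(5.0, 0.8, 12)
        traces, blank = simulate_turbidity(2.3, series, seed=1, baseline_sd=0.001)
        rec = call_mis_mfs(traces, blank)
        assert rec.mis == pytest.approx(2.048)

    def test_kinetic_precipitation_gives_mfs_below_mis(self):
        series = make_dilution_series(5.0, 0.8, 12)
        traces, blank = simulate_turbidity(4.5, series, seed=1, baseline_sd=0.001, kinetic_rate=0.01)
        rec = call_mis_mfs(traces, blank)
        assert rec.mfs < rec.mis
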