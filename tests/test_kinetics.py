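"""Growth fitting, dispersal-onset detection and reproducibility stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilm_flowcell.kinetics import (
    DispersalResult,
    InsufficientDataError,
    aggregate_over_areas,
    detect_dispersal_onset,
    doubling_time,
    fit_growth,
    propagation_stat,
    reproducibility_row,
    reproducibility_table,
)
from biofilm_flowcell.quantification import QuantSeries


def make_series(volumes, t0=40.0, dt=10.0, position="7a"):
    volumes = np.asarray(volumes, dtype=float)
    times = t0 + dt * np.arange(len(volumes))
    return QuantSeries(position, times, np.ones(len(volumes), dtype=int), volumes)


class TestGrowthFit:
    def test_exact_exponential_recovered_to_machine_precision(self):
        t = 40.0 + 10.0 * np.arange(20)
        v = 5.0 * np.exp(0.01 * t)
        fit = fit_growth(make_series(v))
        assert fit.growth_rate == pytest.approx(0.01, rel=1e-12)
        assert fit.doubling_time == pytest.approx(math.log(2) / 0.01, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_sampling_interval_irrelevant_for_exact_input(self):
        for dt in (5.0, 10.0, 25.0):
            t = 40.0 + dt * np.arange(12)
            v = 2.0 * np.exp(0.02 * t)
            fit = fit_growth(make_series(v, dt=dt))
            assert fit.doubling_time == pytest.approx(math.log(2) / 0.02, rel=1e-12)

    def test_fit_stops_at_peak(self):
        t = np.arange(10, dtype=float)
        v = np.concatenate([10.0 * np.exp(0.05 * t[:6]), [5.0, 2.0, 1.0, 0.5]])
        fit = fit_growth(make_series(v))
        assert fit.peak_cycle == 6
        assert fit.growth_rate == pytest.approx(0.05 / 10.0, rel=1e-9)  # dt=10 min

    def test_zero_cycles_excluded(self):
        v = [0.0, 0.0, 10.0, 20.0, 40.0, 80.0]
        fit = fit_growth(make_series(v))
        assert fit.n_cycles_used == 4
        assert fit.growth_rate > 0

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_growth(make_series([0.0, 1.0, 5.0]))  # peak at cycle 3, 2 positive

    def test_non_growing_flagged_not_raised(self):
        fit = fit_growth(make_series([8.0, 4.0, 2.0, 1.0, 9.0]))
        # peak at last cycle; decreasing prefix fits a negative slope
        assert not fit.growing
        assert math.isnan(fit.doubling_time)


class TestDoublingTime:
    def test_ln2_rate_gives_one_minute(self):
        assert doubling_time(math.log(2.0)) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "g,expected", [(0.01, 69.31), (0.014748, 47.0), (math.log(2) / 65.0, 65.0)]
    )
    def test_closed_form(self, g, expected):
        assert doubling_time(g) == pytest.approx(expected, abs=0.01)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)


class TestOnsetDetection:
    def test_single_peak(self):
        s = make_series([0.5, 1, 2, 4, 3, 1, 0.2])
        s.vnorm = s.volumes.copy()
        res = detect_dispersal_onset(s)
        assert res.onset_cycle == 5  # the cycle holding value 3
        assert res.t_disp == pytest.approx(s.times[4])
        assert res.peak_cycle == 4

    def test_strictly_increasing_has_no_onset(self):
        res = detect_dispersal_onset(make_series([1, 2, 4, 8, 16]))
        assert res.onset_cycle is None
        assert res.t_disp is None

    def test_ties_resolve_to_earliest_peak(self):
        res = detect_dispersal_onset(make_series([1, 5, 5, 5, 2, 1]))
        assert res.peak_cycle == 2
        assert res.onset_cycle == 5  # first value strictly below the maximum

    def test_transient_dip_before_true_peak_is_not_onset(self):
        res = detect_dispersal_onset(make_series([1, 3, 2, 6, 10, 4, 1]))
        assert res.peak_cycle == 5
        assert res.onset_cycle == 6

    def test_onset_strictly_after_peak(self, rng):
        for _ in range(20):
            v = np.abs(rng.normal(5, 3, size=15)) + 0.1
            res = detect_dispersal_onset(make_series(v))
            if res.onset_cycle is not None:
                assert res.onset_cycle > res.peak_cycle

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(min_value=-500, max_value=500))
    def test_time_shift_equivariance(self, shift):
        v = [0.5, 1, 2, 4, 3, 1, 0.2]
        a = detect_dispersal_onset(make_series(v, t0=40.0))
        b = detect_dispersal_onset(make_series(v, t0=40.0 + shift))
        assert b.t_disp - a.t_disp == pytest.approx(shift, abs=1e-9)
        fa = fit_growth(make_series([1, 2, 4, 8, 16, 32], t0=40.0))
        fb = fit_growth(make_series([1, 2, 4, 8, 16, 32], t0=40.0 + shift))
        assert fa.growth_rate == pytest.approx(fb.growth_rate, rel=1e-9)


class TestAggregation:
    def test_identical_values(self):
        assert aggregate_over_areas([370, 370, 370]) == (370.0, 0.0)

    def test_sample_standard_deviation(self):
        mean, sd = aggregate_over_areas([364, 370, 376])
        assert mean == pytest.approx(370.0)
        assert sd == pytest.approx(6.0)

    def test_singleton_flagged_undefined(self):
        mean, sd = aggregate_over_areas([412.0])
        assert mean == 412.0
        assert math.isnan(sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_over_areas([])


def _dispersal_result(onsets_by_position):
    from biofilm_flowcell.kinetics import OnsetResult

    onsets = {
        p: OnsetResult(p, 10, t, 9, 1.0) for p, t in onsets_by_position.items()
    }
    return DispersalResult(flow_rate=0.1, onsets=onsets, fits={})


class TestPropagation:
    def test_identical_onsets_give_zero(self):
        res = _dispersal_result({"1a": 400.0, "1b": 400.0, "12a": 400.0, "12b": 400.0})
        assert propagation_stat(res) == 0.0

    def test_downstream_first_gives_positive_delta(self):
        res = _dispersal_result({"1a": 433.0, "1b": 433.0, "12a": 370.0, "12b": 370.0})
        assert propagation_stat(res) == pytest.approx(63.0)

    def test_missing_endpoint_raises(self):
        res = _dispersal_result({"5a": 400.0})
        with pytest.raises(ValueError):
            propagation_stat(res)


class TestReproducibility:
    def test_low_flow_row(self):
        row = reproducibility_row(0.1, (370.0, 6.0), (387.0, 0.0))
        assert row.run1_cv_pct == 1.6
        assert row.run2_cv_pct == 0.0
        assert row.delta12_min == 17
        assert row.delta12_pct == 4.6

    def test_identical_runs_give_zero_delta(self):
        row = reproducibility_row(0.5, (432.0, 6.0), (432.0, 6.0))
        assert row.delta12_min == 0
        assert row.delta12_pct == 0.0

    def test_mid_flow_row(self):
        row = reproducibility_row(1.5, (472.0, 6.0), (468.0, 0.0))
        assert row.run1_cv_pct == 1.3
        assert row.delta12_min == 4
        assert row.delta12_pct == 0.8

    def test_single_run_leaves_between_run_fields_empty(self):
        row = reproducibility_row(4.0, (539.0, 10.0))
        assert row.run1_cv_pct == 1.9
        assert row.delta12_min is None and row.run2_mean_min is None

    def test_raw_triplets_accepted(self):
        row = reproducibility_row(0.1, [364.0, 370.0, 376.0], [387.0, 387.0, 387.0])
        assert row.run1_mean_min == 370
        assert row.run1_sd_min == 6
        assert row.delta12_min == 17

    def test_table_assembly(self):
        rows = [
            reproducibility_row(0.1, (370.0, 6.0), (387.0, 0.0)),
            reproducibility_row(4.0, (539.0, 10.0)),
        ]
        df = reproducibility_table(rows)
        assert list(df["flow_rate"]) == [0.1, 4.0]
        assert df.loc[1, "delta12_min"] is None or np.isnan(df.loc[1, "delta12_min"])
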