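"""Site aggregation, phase averages, smoothing, step-down and drop detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxispec import (
    EventConfig,
    RBFiSeries,
    SiteTable,
    StO2Series,
    aggregate_sites,
    detect_abrupt_drop,
    median_smooth,
    phase_average,
    stepdown_profile,
)
from oxispec.errors import (
    AlignmentError,
    ParameterError,
    PhaseError,
    ProfileError,
)
from oxispec.timeseries import round_half_away


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expect",
        [(0.2085, 3, 0.209), (0.9335, 3, 0.934), (92.5, 0, 93.0),
         (0.67475, 3, 0.675), (-0.2085, 3, -0.209), (84.635, 0, 85.0)],
    )
    def test_half_away_from_zero(self, x, nd, expect):
        assert round_half_away(x, nd) == expect


class TestAggregateSites:
    def test_four_site_mean(self):
        row = {"hilum": 0.834, "superior": 0.804, "lateral": 0.635, "inferior": 0.426}
        assert aggregate_sites(row) == 0.675

    def test_partial_row_with_zeros(self):
        row = {"hilum": 0, "superior": 0, "lateral": 0.089, "inferior": 0.745}
        assert aggregate_sites(row) == 0.209

    @pytest.mark.parametrize("v", [0.0, 0.318, 1.0])
    def test_equal_sites_identity(self, v):
        assert aggregate_sites({s: v for s in ("hilum", "superior", "lateral", "inferior")}) == v

    def test_empty_and_unknown_site_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_sites({})
        with pytest.raises(ParameterError):
            aggregate_sites({"apex": 0.5})


def _table(rows):
    recs = []
    for t, vals in rows:
        for site, v in zip(("hilum", "superior", "lateral", "inferior"), vals):
            recs.append({"time_s": t, "site": site, "sto2": v})
    return SiteTable(pd.DataFrame(recs))


class TestPhaseAverage:
    def test_identical_single_rows_each_side(self):
        table = _table([(0.0, [0.5] * 4), (100.0, [0.5] * 4)])
        assert phase_average(table, 50.0) == (50, 50)

    def test_pools_site_values_not_row_averages(self):
        # unequal row sizes would bias a row-average pool
        recs = [
            {"time_s": 0.0, "site": "hilum", "sto2": 0.2},
            {"time_s": 10.0, "site": "hilum", "sto2": 0.4},
            {"time_s": 10.0, "site": "superior", "sto2": 1.0},
            {"time_s": 20.0, "site": "hilum", "sto2": 0.8},
        ]
        table = SiteTable(pd.DataFrame(recs))
        before, after = phase_average(table, 20.0)
        assert before == round(100 * (0.2 + 0.4 + 1.0) / 3)
        assert after == 80

    def test_one_sided_table_rejected(self):
        table = _table([(0.0, [0.5] * 4)])
        with pytest.raises(PhaseError):
            phase_average(table, 50.0)


class TestMedianSmooth:
    def test_constant_series_unchanged(self):
        s = StO2Series(np.arange(5.0), np.full(5, 0.7), ("ok",) * 5)
        np.testing.assert_array_equal(median_smooth(s, 3).sto2, s.sto2)

    def test_single_outlier_suppressed(self):
        s = StO2Series(np.arange(5.0), [0.9, 0.9, 0.1, 0.9, 0.9], ("ok",) * 5)
        np.testing.assert_allclose(median_smooth(s, 3).sto2, 0.9)

    def test_flagged_samples_excluded_from_windows(self):
        flags = ("ok", "ambient-light", "ok", "ok", "ok")
        s = StO2Series(np.arange(5.0), [0.9, 0.0, 0.9, 0.88, 0.9], flags)
        out = median_smooth(s, 3)
        assert np.all(out.sto2 >= 0.88)
        assert out.flags == flags

    def test_matches_brute_force_sliding_median(self, rng):
        for _ in range(20):
            n = int(rng.integers(7, 40))
            vals = rng.uniform(0, 1, n)
            s = StO2Series(np.arange(float(n)), vals, ("ok",) * n)
            out = median_smooth(s, 5)
            # independent brute force: clipped centred window over all samples
            expect = [
                np.median(vals[max(0, i - 2): min(n, i + 3)]) for i in range(n)
            ]
            np.testing.assert_allclose(out.sto2, expect)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        data=st.lists(st.floats(min_value=0, max_value=1), min_size=5, max_size=60),
        window=st.sampled_from([1, 3, 5]),
    )
    def test_output_within_input_range(self, data, window):
        n = len(data)
        s = StO2Series(np.arange(float(n)), data, ("ok",) * n)
        out = median_smooth(s, window)
        assert np.all(out.sto2 >= min(data) - 1e-12)
        assert np.all(out.sto2 <= max(data) + 1e-12)

    @pytest.mark.parametrize("window", [0, 2, 4, 99])
    def test_bad_window_rejected(self, window):
        s = StO2Series(np.arange(5.0), np.full(5, 0.5), ("ok",) * 5)
        with pytest.raises(ParameterError):
            median_smooth(s, window)


class TestStepdownProfile:
    def test_largest_drop_and_plateau(self):
        prof = stepdown_profile(
            [100, 75, 50, 25, 0], [0.859, 0.819, 0.786, 0.593, 0.595]
        )
        assert prof.largest_drop_interval == (50.0, 25.0)
        assert prof.plateau_onset == 25.0

    def test_equal_steps_tie_broken_toward_higher_flow(self):
        prof = stepdown_profile([100, 75, 50, 25], [0.8, 0.7, 0.6, 0.5])
        assert prof.largest_drop_interval == (100.0, 75.0)

    def test_no_plateau_returns_none(self):
        prof = stepdown_profile([100, 50, 0], [0.9, 0.6, 0.3], plateau_tol=0.02)
        assert prof.plateau_onset is None

    def test_too_few_levels_rejected(self):
        with pytest.raises(ProfileError):
            stepdown_profile([100, 50], [0.9, 0.5])

    def test_non_decreasing_flows_rejected(self):
        with pytest.raises(ProfileError):
            stepdown_profile([100, 100, 50], [0.9, 0.8, 0.5])


def _flat_series(n=60, value=0.9, dt=15.0):
    t = np.arange(n) * dt
    return StO2Series(t, np.full(n, value), ("ok",) * n)


class TestDetectAbruptDrop:
    def test_flat_series_no_event(self):
        s = _flat_series()
        r = RBFiSeries(s.times, np.full(len(s), 1.0))
        assert detect_abrupt_drop(s, r).kind == "none"

    def test_synchronized_drop_detected(self):
        t = np.arange(80) * 15.0
        sto2 = np.where(t < 600.0, 0.95, 0.91)
        rbfi = np.where(t < 600.0, 1.0, 0.2)
        win = detect_abrupt_drop(
            StO2Series(t, sto2, ("ok",) * 80), RBFiSeries(t, rbfi)
        )
        assert win.kind == "decompensation"
        assert win.contains(600.0)

    def test_sto2_drop_without_rbfi_drop_ignored(self):
        t = np.arange(80) * 15.0
        sto2 = np.where(t < 600.0, 0.95, 0.91)
        rbfi = np.full(80, 1.0)
        win = detect_abrupt_drop(
            StO2Series(t, sto2, ("ok",) * 80), RBFiSeries(t, rbfi)
        )
        assert win.kind == "none"

    def test_rbfi_drop_without_sto2_drop_ignored(self):
        t = np.arange(80) * 15.0
        rbfi = np.where(t < 600.0, 1.0, 0.1)
        win = detect_abrupt_drop(_flat_series(80), RBFiSeries(t, rbfi))
        assert win.kind == "none"

    def test_non_overlapping_series_rejected(self):
        s = _flat_series(10)
        r = RBFiSeries(s.times + 1e6, np.ones(10))
        with pytest.raises(AlignmentError):
            detect_abrupt_drop(s, r)
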