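"""Tertile banding, window classification and exposure-group comparison."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import episurg as ep
from episurg.errors import (
    CoverageError,
    DegenerateBandsError,
    DegenerateComparisonError,
)
from episurg.exposure import Label

from _oracles import classify_window_bruteforce, pearson_chi2


def _flat_series(values):
    dates = np.arange(np.datetime64("2020-05-01"), np.datetime64("2020-05-01") + len(values))
    v = np.asarray(values, float)
    return ep.IncidenceSeries("X", dates, v, v)


class TestTertiles:
    def test_thresholds_are_thirds_of_period_maximum(self):
        inc = _flat_series([0, 100, 900, 400, 0, 0, 0, 0, 0, 0])
        b = ep.compute_tertiles(inc, dt.date(2020, 5, 1), dt.date(2020, 5, 10))
        assert b.lower_threshold == pytest.approx(300.0)
        assert b.upper_threshold == pytest.approx(600.0)

    def test_unit_maximum(self):
        inc = _flat_series([0.0, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0])
        b = ep.compute_tertiles(inc, dt.date(2020, 5, 1), dt.date(2020, 5, 7))
        assert b.lower_threshold == pytest.approx(1 / 3)
        assert b.upper_threshold == pytest.approx(2 / 3)

    def test_all_zero_period_is_degenerate(self):
        with pytest.raises(DegenerateBandsError):
            ep.compute_tertiles(_flat_series(np.zeros(20)), dt.date(2020, 5, 1), dt.date(2020, 5, 20))

    def test_period_not_covered(self):
        with pytest.raises(CoverageError):
            ep.compute_tertiles(_flat_series(np.ones(5)), dt.date(2020, 5, 1), dt.date(2020, 6, 30))

    def test_empirical_mode_uses_quantiles(self):
        vals = np.concatenate([np.full(40, 10.0), np.full(40, 20.0), np.full(40, 30.0)])
        inc = _flat_series(vals)
        b = ep.compute_tertiles(
            inc, dt.date(2020, 5, 1), dt.date(2020, 5, 1) + dt.timedelta(days=119),
            mode="empirical",
        )
        assert 10.0 <= b.lower_threshold <= 20.0 <= b.upper_threshold <= 30.0


class TestClassify:
    @pytest.fixture
    def scenario(self, single_wave_incidence):
        """Single-wave country: bands + peaks over the full series period."""
        inc = single_wave_incidence
        start = dt.date(2020, 3, 1)
        end = dt.date(2020, 9, 16)
        bands = ep.compute_tertiles(inc, start, end)
        peaks = ep.detect_peaks(inc)
        return inc, bands, peaks

    def test_three_patient_wave_scenario(self, scenario):
        """Windows fully below, late-entering, and fully inside the top band."""
        inc, bands, peaks = scenario
        s, dates = inc.smoothed_daily, inc.dates
        above = np.flatnonzero(s >= bands.upper_threshold)
        first_top = dt.date(2020, 3, 1) + dt.timedelta(days=int(above[0]))
        # patient A: whole window before the curve enters the top band
        a = ep.classify_patient(inc, bands, peaks, first_top - dt.timedelta(days=40))
        # patient B: only the tail of the follow-up reaches the top band
        b = ep.classify_patient(inc, bands, peaks, first_top - dt.timedelta(days=20))
        # patient C: surgery and whole follow-up inside the top band
        c = ep.classify_patient(inc, bands, peaks, first_top + dt.timedelta(days=2))
        assert a.label is Label.BOTTOM_TWO
        assert b.label is Label.TOP_TERTILE
        assert c.label is Label.TOP_TERTILE

    def test_boundary_value_belongs_to_top_band(self):
        vals = np.r_[np.full(10, 200.0), [600.0], np.full(39, 200.0), [900.0], np.full(9, 0.0)]
        inc = _flat_series(vals)
        bands = ep.compute_tertiles(inc, dt.date(2020, 5, 1), dt.date(2020, 6, 29))
        assert bands.upper_threshold == pytest.approx(600.0)
        peaks = ep.PeakSet("X", [ep.Peak(dt.date(2020, 6, 20), 900, 10, 700)])
        lab = ep.classify_patient(inc, bands, peaks, dt.date(2020, 5, 2), follow_up_days=9)
        assert lab.label is Label.TOP_TERTILE  # one day exactly at the threshold

    def test_no_peak_country_excluded(self, single_wave_incidence):
        inc = single_wave_incidence
        bands = ep.compute_tertiles(inc, dt.date(2020, 3, 1), dt.date(2020, 9, 16))
        lab = ep.classify_patient(inc, bands, ep.PeakSet("X"), dt.date(2020, 6, 9))
        assert lab.label is Label.EXCLUDED_NO_PEAK

    def test_window_outside_series_rejected(self, scenario):
        inc, bands, peaks = scenario
        with pytest.raises(CoverageError):
            ep.classify_patient(inc, bands, peaks, dt.date(2020, 9, 10))

    def test_agrees_with_day_by_day_oracle(self, two_wave_incidence):
        inc = two_wave_incidence
        bands = ep.compute_tertiles(inc, dt.date(2020, 5, 1), dt.date(2020, 11, 30))
        peaks = ep.detect_peaks(inc)
        rng = np.random.default_rng(42)
        start = dt.date(2020, 5, 1)
        for _ in range(300):
            d = start + dt.timedelta(days=int(rng.integers(0, 184)))
            got = ep.classify_patient(inc, bands, peaks, d).label.value
            assert got == classify_window_bruteforce(inc, bands.upper_threshold, d, 30)

    def test_raising_threshold_only_demotes(self, two_wave_incidence):
        inc = two_wave_incidence
        bands = ep.compute_tertiles(inc, dt.date(2020, 5, 1), dt.date(2020, 11, 30))
        peaks = ep.detect_peaks(inc)
        start = dt.date(2020, 5, 1)
        days = [start + dt.timedelta(days=7 * k) for k in range(26)]
        for factor in (1.1, 1.5, 2.0):
            raised = ep.TertileBands(
                bands.country, bands.study_start, bands.study_end,
                bands.lower_threshold, bands.upper_threshold * factor,
            )
            for d in days:
                lo = ep.classify_patient(inc, bands, peaks, d).label
                hi = ep.classify_patient(inc, raised, peaks, d).label
                if lo is Label.BOTTOM_TWO:
                    assert hi is Label.BOTTOM_TWO

    def test_every_patient_gets_exactly_one_label(self, two_wave_incidence):
        inc = two_wave_incidence
        bands = ep.compute_tertiles(inc, dt.date(2020, 5, 1), dt.date(2020, 11, 30))
        peaks = ep.detect_peaks(inc)
        spec = ep.CohortSpec(n=200, seed=3)
        records, _ = ep.generate_cohort(spec, inc)
        labels = [
            ep.classify_patient(inc, bands, peaks, r.surgery_date, 30, r.patient_id)
            for r in records
        ]
        by = {lab: 0 for lab in Label}
        for l in labels:
            by[l.label] += 1
        assert sum(by.values()) == len(records)


class TestGroupComparison:
    def _labels(self, n_top, n_bottom):
        mk = lambda i, lab: ep.ExposureLabel(f"p{i}", lab, dt.date(2020, 5, 1), dt.date(2020, 5, 31))
        return [mk(i, Label.TOP_TERTILE) for i in range(n_top)] + [
            mk(n_top + i, Label.BOTTOM_TWO) for i in range(n_bottom)
        ]

    def test_published_scale_contrast(self):
        labels = self._labels(4674, 1924)
        outcomes = {f"p{i}": i < 34 or 4674 <= i < 4676 for i in range(6598)}
        comp = ep.compare_exposure_groups(labels, outcomes, test="pearson")
        assert comp.counts.tolist() == [[34, 4640], [2, 1922]]
        assert 100 * comp.proportions["TOP_TERTILE"] == pytest.approx(0.7274, abs=1e-3)
        assert 100 * comp.proportions["BOTTOM_TWO"] == pytest.approx(0.1040, abs=1e-3)
        # frozen closed-form Pearson statistic for this table
        assert comp.statistic == pytest.approx(9.7636, abs=1e-3)
        assert comp.p_value == pytest.approx(0.001780, abs=1e-5)

    def test_identical_rates_give_null_statistic(self):
        labels = self._labels(1000, 1000)
        outcomes = {f"p{i}": (i % 1000) < 10 for i in range(2000)}
        comp = ep.compare_exposure_groups(labels, outcomes, test="pearson")
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_fisher_fallback_on_sparse_table(self):
        labels = self._labels(40, 40)
        outcomes = {f"p{i}": i in (0, 1, 2) for i in range(80)}
        comp = ep.compare_exposure_groups(labels, outcomes)  # expected cell < 5
        assert comp.test_name == "fisher_exact"

    def test_empty_group_is_degenerate(self):
        labels = self._labels(10, 0)
        with pytest.raises(DegenerateComparisonError):
            ep.compare_exposure_groups(labels, {f"p{i}": False for i in range(10)})

    def test_excluded_patients_dropped(self):
        labels = self._labels(5, 5)
        labels.append(
            ep.ExposureLabel("px", Label.EXCLUDED_NO_PEAK, dt.date(2020, 5, 1), dt.date(2020, 5, 31))
        )
        outcomes = {f"p{i}": i == 0 for i in range(10)}  # no outcome for px on purpose
        comp = ep.compare_exposure_groups(labels, outcomes, test="fisher")
        assert comp.counts.sum() == 10

    @given(
        st.tuples(*[st.integers(min_value=1, max_value=500) for _ in range(4)])
    )
    @settings(max_examples=200, deadline=None)
    def test_pearson_matches_textbook_closed_form(self, cells):
        a, b, c, d = cells
        labels = self._labels(a + b, c + d)
        outcomes = {}
        for i in range(a + b):
            outcomes[f"p{i}"] = i < a
        for i in range(c + d):
            outcomes[f"p{a + b + i}"] = i < c
        comp = ep.compare_exposure_groups(labels, outcomes, test="pearson")
        assert comp.statistic == pytest.approx(pearson_chi2([[a, b], [c, d]]), rel=1e-10)
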