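"""Incidence-tertile exposure classification of surgical follow-up windows.

Each country's study-period smoothed incidence is banded into three tertiles
of magnitude (thirds of the study-period maximum). A patient's surgery day
plus 30-day follow-up window is labelled TOP_TERTILE if the smoothed
incidence reaches the upper band on any window day, BOTTOM_TWO otherwise,
and EXCLUDED_NO_PEAK when the country shows no qualifying epidemic peak in
the study period. Postoperative COVID rates are then compared between the
two exposure groups on a 2x2 table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .epicurve import IncidenceSeries, PeakSet, _as_date, has_peak_in_window
from .errors import (
    CoverageError,
    DegenerateBandsError,
    DegenerateComparisonError,
)

__all__ = [
    "Label",
    "TertileBands",
    "ExposureLabel",
    "GroupComparison",
    "compute_tertiles",
    "classify_patient",
    "compare_exposure_groups",
    "rate_ratio",
]


class Label(str, Enum):
    TOP_TERTILE = "TOP_TERTILE"
    BOTTOM_TWO = "BOTTOM_TWO"
    EXCLUDED_NO_PEAK = "EXCLUDED_NO_PEAK"


@dataclass(frozen=True)
class TertileBands:
    """Incidence thresholds splitting [0, max] into three equal bands."""

    country: str
    study_start: dt.date
    study_end: dt.date
    lower_threshold: float
    upper_threshold: float

    def __post_init__(self):
        if not (0.0 <= self.lower_threshold <= self.upper_threshold):
            raise DegenerateBandsError("thresholds must satisfy 0 <= lower <= upper")


@dataclass(frozen=True)
class ExposureLabel:
    patient_id: str
    label: Label
    window_start: dt.date
    window_end: dt.date


@dataclass
class GroupComparison:
    """2x2 exposure-by-outcome comparison."""

    counts: np.ndarray  # rows: TOP, BOTTOM_TWO; cols: covid yes, no
    proportions: dict[str, float]  # per-group case proportion
    statistic: float
    p_value: float
    test_name: str

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=["TOP_TERTILE", "BOTTOM_TWO"],
            columns=["covid", "no_covid"],
        )


def compute_tertiles(
    incidence: IncidenceSeries,
    study_start,
    study_end,
    mode: str = "max_thirds",
) -> TertileBands:
    """Tertile thresholds over the study period.

    mode="max_thirds" (default): thresholds at 1/3 and 2/3 of the maximum
    smoothed incidence in the period — bands of magnitude, matching how the
    bands are drawn against the curve. mode="empirical": 33.3/66.7 percent
    quantiles of the daily smoothed values.
    """
    study_start, study_end = _as_date(study_start), _as_date(study_end)
    vals = incidence.values_between(study_start, study_end, smoothed=True)
    n_days = (study_end - study_start).days + 1
    if len(vals) < n_days:
        raise CoverageError("smoothed incidence does not cover the study period")
    if np.max(vals) <= 0:
        raise DegenerateBandsError("all-zero incidence over the study period")
    if mode == "max_thirds":
        m = float(np.max(vals))
        lo, hi = m / 3.0, 2.0 * m / 3.0
    elif mode == "empirical":
        lo, hi = (float(q) for q in np.quantile(vals, [1.0 / 3.0, 2.0 / 3.0]))
    else:
        raise ValueError(f"unknown tertile mode {mode!r}")
    return TertileBands(incidence.country, study_start, study_end, lo, hi)


def classify_patient(
    incidence: IncidenceSeries,
    bands: TertileBands,
    peaks: PeakSet,
    surgery_date,
    follow_up_days: int = 30,
    patient_id: str = "",
) -> ExposureLabel:
    """Label one surgery + follow-up window against the tertile bands.

    The window is [surgery_date, surgery_date + follow_up_days], inclusive
    both ends. TOP_TERTILE if smoothed incidence >= upper threshold on any
    window day (values exactly on the boundary belong to the upper band);
    EXCLUDED_NO_PEAK when the country has no detected peak in the study
    period, regardless of incidence.
    """
    surgery_date = _as_date(surgery_date)
    window_end = surgery_date + dt.timedelta(days=follow_up_days)
    d0 = pd.Timestamp(incidence.dates[0]).date()
    d1 = pd.Timestamp(incidence.dates[-1]).date()
    if surgery_date < d0 or window_end > d1:
        raise CoverageError(
            f"window {surgery_date}..{window_end} outside series range {d0}..{d1}"
        )
    if not has_peak_in_window(peaks, bands.study_start, bands.study_end):
        label = Label.EXCLUDED_NO_PEAK
    else:
        vals = incidence.values_between(surgery_date, window_end, smoothed=True)
        label = Label.TOP_TERTILE if np.any(vals >= bands.upper_threshold) else Label.BOTTOM_TWO
    return ExposureLabel(patient_id, label, surgery_date, window_end)


def compare_exposure_groups(
    labels: list[ExposureLabel],
    outcomes: Mapping[str, bool],
    test: str = "auto",
) -> GroupComparison:
    """Compare postoperative COVID rates between exposure groups.

    Pearson chi-square without continuity correction by default, falling back
    to Fisher's exact (two-sided) when any expected cell count is below 5.
    ``test`` forces "pearson" or "fisher". Excluded (no-peak) patients are
    dropped; every remaining patient must have an outcome.
    """
    counts = np.zeros((2, 2), dtype=int)
    for lab in labels:
        if lab.label is Label.EXCLUDED_NO_PEAK:
            continue
        row = 0 if lab.label is Label.TOP_TERTILE else 1
        col = 0 if bool(outcomes[lab.patient_id]) else 1
        counts[row, col] += 1
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise DegenerateComparisonError("an exposure group has zero members")
    props = {
        "TOP_TERTILE": counts[0, 0] / totals[0],
        "BOTTOM_TWO": counts[1, 0] / totals[1],
    }
    expected = np.outer(totals, counts.sum(axis=0)) / counts.sum()
    if test == "auto":
        test = "fisher" if expected.min() < 5 else "pearson"
    if test == "pearson":
        if counts.sum(axis=0).min() == 0:  # outcome constant: no association testable
            stat, p = 0.0, 1.0
        else:
            stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
        name = "pearson_chi2"
    elif test == "fisher":
        stat, p = stats.fisher_exact(counts, alternative="two-sided")
        name = "fisher_exact"
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(counts, props, float(stat), float(p), name)


def rate_ratio(comparison: GroupComparison, level: float = 0.95) -> tuple[float, float, float]:
    """Top-vs-bottom rate ratio with a Katz log-scale confidence interval.

    A 0.5 continuity correction is applied to every cell when any cell of the
    a/n1 vs b/n2 contrast is zero.
    """
    a, n1 = comparison.counts[0, 0], comparison.counts[0].sum()
    b, n2 = comparison.counts[1, 0], comparison.counts[1].sum()
    a, b, n1, n2 = (float(x) for x in (a, b, n1, n2))
    if a == 0 or b == 0:
        a, b, n1, n2 = a + 0.5, b + 0.5, n1 + 0.5, n2 + 0.5
    rr = (a / n1) / (b / n2)
    se = np.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return rr, rr * np.exp(-z * se), rr * np.exp(z * se)
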