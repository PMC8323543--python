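"""Country-level epidemic incidence curves.

Ingests cumulative confirmed-case time series (JHU CSSE global dialect),
differentiates them into daily incidence, smooths with a zero-phase low-pass
Butterworth filter, and detects epidemic peaks by joint width / relative-height
rules (local maxima at least ``min_width_days`` wide at half prominence and at
least ``min_height_frac`` of the country's maximum smoothed incidence).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    CountryNotFoundError,
    FormatError,
    InsufficientDataError,
)

__all__ = [
    "CumulativeSeries",
    "IncidenceSeries",
    "FilterSpec",
    "Peak",
    "PeakSet",
    "read_case_timeseries",
    "write_case_timeseries",
    "differentiate",
    "butterworth_smooth",
    "detect_peaks",
    "has_peak_in_window",
]

_JHU_META_COLUMNS = ["Province/State", "Country/Region", "Lat", "Long"]


def _as_date(d) -> dt.date:
    """Coerce date-likes (date, datetime, Timestamp, ISO string) to datetime.date."""
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


def _check_daily_contiguous(dates: np.ndarray) -> None:
    if len(dates) > 1:
        steps = np.diff(dates.astype("datetime64[D]")).astype(int)
        if not np.all(steps == 1):
            raise FormatError("dates must be strictly increasing with a 1-day step")


@dataclass
class CumulativeSeries:
    """Cumulative confirmed-case counts for one country, one value per day."""

    country: str
    dates: np.ndarray  # datetime64[D], daily, contiguous
    cumulative: np.ndarray  # non-negative counts

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        if self.dates.shape != self.cumulative.shape:
            raise FormatError("dates and cumulative must have equal length")
        _check_daily_contiguous(self.dates)
        if np.any(self.cumulative < 0):
            raise FormatError("cumulative counts must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class IncidenceSeries:
    """Daily new-case counts (first differences) and their smoothed version."""

    country: str
    dates: np.ndarray
    raw_daily: np.ndarray
    smoothed_daily: np.ndarray | None = None

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.raw_daily = np.asarray(self.raw_daily, dtype=float)
        _check_daily_contiguous(self.dates)
        if self.smoothed_daily is not None:
            self.smoothed_daily = np.asarray(self.smoothed_daily, dtype=float)
            if self.smoothed_daily.shape != self.raw_daily.shape:
                raise FormatError("smoothed series must match raw series length")

    def __len__(self) -> int:
        return len(self.dates)

    def values_between(self, start, end, smoothed: bool = True) -> np.ndarray:
        """Series values on [start, end], inclusive both ends."""
        start, end = np.datetime64(_as_date(start)), np.datetime64(_as_date(end))
        mask = (self.dates >= start) & (self.dates <= end)
        v = self.smoothed_daily if smoothed else self.raw_daily
        if v is None:
            raise InsufficientDataError("smoothed series not populated")
        return v[mask]

    def index_of(self, date) -> int:
        date = np.datetime64(_as_date(date))
        offset = (date - self.dates[0]).astype(int)
        if offset < 0 or offset >= len(self):
            raise KeyError(f"{date} outside series range")
        return int(offset)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth filter settings.

    cutoff is a frequency in cycles/day (sampling rate is 1/day, so the
    Nyquist frequency is 0.5). The default 1/14 cycles/day suppresses the
    weekly reporting periodicity that dominates raw counts while keeping
    multi-week epidemic waves intact.
    """

    order: int = 2
    cutoff: float = 1.0 / 14.0
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise FormatError("filter order must be >= 1")
        if not (0.0 < self.cutoff < 0.5):
            raise FormatError("cutoff must lie strictly inside (0, 0.5) cycles/day")


@dataclass(frozen=True)
class Peak:
    """One detected incidence maximum."""

    peak_date: dt.date
    height: float  # smoothed incidence at the maximum, cases/day
    width_days: float  # width at half prominence
    prominence: float  # height above the surrounding baseline


@dataclass
class PeakSet:
    """All qualifying peaks for one country, ordered by date."""

    country: str
    peaks: list[Peak] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "country": self.country,
                "peak_date": [p.peak_date.isoformat() for p in self.peaks],
                "height": [p.height for p in self.peaks],
                "width_days": [p.width_days for p in self.peaks],
                "prominence": [p.prominence for p in self.peaks],
            }
        )


def read_case_timeseries(path, country: str) -> CumulativeSeries:
    """Read one country's cumulative series from a JHU CSSE global CSV.

    Rows for all provinces/states of the country are summed element-wise into
    a single national series. Date header columns (M/D/YY) must be in
    increasing order.
    """
    df = pd.read_csv(path)
    if list(df.columns[:4]) != _JHU_META_COLUMNS:
        raise FormatError(
            f"expected leading columns {_JHU_META_COLUMNS}, got {list(df.columns[:4])}"
        )
    date_cols = list(df.columns[4:])
    if not date_cols:
        raise FormatError("no date columns present")
    try:
        dates = pd.to_datetime(date_cols, format="%m/%d/%y")
    except ValueError as exc:
        raise FormatError(f"date columns are not M/D/YY: {exc}") from exc
    if not dates.is_monotonic_increasing or dates.has_duplicates:
        raise FormatError("date header must be strictly increasing")
    rows = df[df["Country/Region"] == country]
    if rows.empty:
        raise CountryNotFoundError(country, df["Country/Region"].unique().tolist())
    cumulative = rows[date_cols].to_numpy(dtype=float).sum(axis=0)
    return CumulativeSeries(country, dates.values.astype("datetime64[D]"), cumulative)


def write_case_timeseries(series_list: list[CumulativeSeries], path) -> None:
    """Write cumulative series in the same JHU CSSE dialect the reader consumes."""
    if not series_list:
        raise FormatError("nothing to write")
    dates = series_list[0].dates
    for s in series_list[1:]:
        if not np.array_equal(s.dates, dates):
            raise FormatError("all series must share one date axis")
    cols = [pd.Timestamp(d).strftime("%-m/%-d/%y") for d in dates]
    records = []
    for s in series_list:
        row = {"Province/State": "", "Country/Region": s.country, "Lat": 0.0, "Long": 0.0}
        row.update(dict(zip(cols, s.cumulative.astype(int))))
        records.append(row)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def differentiate(series: CumulativeSeries) -> IncidenceSeries:
    """First-difference a cumulative series into daily incidence.

    The first day keeps the full cumulative count; negative differences
    (retrospective data corrections) are clipped to zero since incidence is
    non-negative by definition.
    """
    if len(series) < 2:
        raise InsufficientDataError("need at least 2 days to differentiate")
    raw = np.empty_like(series.cumulative)
    raw[0] = series.cumulative[0]
    raw[1:] = np.clip(np.diff(series.cumulative), 0.0, None)
    return IncidenceSeries(series.country, series.dates, raw)


def butterworth_smooth(
    incidence: IncidenceSeries, spec: FilterSpec = FilterSpec()
) -> IncidenceSeries:
    """Low-pass the raw daily series; zero-phase (forward-backward) by default.

    The filter has unit gain at DC so constant series are fixed points;
    negative filter outputs are clipped to zero.
    """
    n = len(incidence)
    min_len = 3 * (spec.order + 1) + 1  # filtfilt default pad length
    if n < max(min_len, 3 * spec.order + 1):
        raise InsufficientDataError(
            f"series of length {n} too short for order-{spec.order} filtering"
        )
    b, a = sps.butter(spec.order, spec.cutoff, btype="low", fs=1.0)
    if spec.zero_phase:
        smoothed = sps.filtfilt(b, a, incidence.raw_daily)
    else:
        smoothed = sps.lfilter(b, a, incidence.raw_daily)
    smoothed = np.clip(smoothed, 0.0, None)
    return IncidenceSeries(incidence.country, incidence.dates, incidence.raw_daily, smoothed)


def detect_peaks(
    incidence: IncidenceSeries,
    min_width_days: float = 7,
    min_height_frac: float = 0.15,
) -> PeakSet:
    """Detect epidemic peaks in the smoothed series.

    A local maximum qualifies if its width at half prominence is at least
    ``min_width_days`` and its height reaches ``min_height_frac`` of the
    maximum smoothed incidence of the series. Endpoints are never peaks
    (their width is undefined). An all-zero series yields an empty set.
    """
    if incidence.smoothed_daily is None:
        raise InsufficientDataError("smoothed series not populated; run butterworth_smooth")
    s = incidence.smoothed_daily
    params = {"min_width_days": float(min_width_days), "min_height_frac": float(min_height_frac)}
    out = PeakSet(incidence.country, [], params)
    if len(s) == 0 or np.max(s) <= 0:
        return out
    idx, props = sps.find_peaks(s, prominence=(None, None), width=(None, None), rel_height=0.5)
    height_floor = min_height_frac * float(np.max(s))
    for i, k in enumerate(idx):
        width = float(props["widths"][i])
        height = float(s[k])
        if width >= min_width_days and height >= height_floor:
            out.peaks.append(
                Peak(
                    peak_date=pd.Timestamp(incidence.dates[k]).date(),
                    height=height,
                    width_days=width,
                    prominence=float(props["prominences"][i]),
                )
            )
    out.peaks.sort(key=lambda p: p.peak_date)
    return out


def has_peak_in_window(peaks: PeakSet, start, end) -> bool:
    """True iff some detected peak date falls in [start, end] (inclusive)."""
    start, end = _as_date(start), _as_date(end)
    if start > end:
        raise ValueError("start must not be after end")
    return any(start <= p.peak_date <= end for p in peaks)
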