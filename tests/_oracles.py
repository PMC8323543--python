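"""Brute-force reference implementations used only to cross-check the package.

These deliberately avoid scipy's peak machinery: local maxima are found by
an explicit scan, prominence by walking outward to the nearest higher
ground, width by linear interpolation at half prominence, and the Pearson
statistic by direct summation of (O - E)^2 / E.
"""

from __future__ import annotations

import numpy as np


def local_maxima(s: np.ndarray) -> list[int]:
    """Interior local maxima; plateaus are reported at their midpoint."""
    out = []
    i, n = 1, len(s)
    while i < n - 1:
        if s[i - 1] < s[i]:
            j = i
            while j < n - 1 and s[j + 1] == s[i]:
                j += 1
            if j < n - 1 and s[j + 1] < s[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def prominence(s: np.ndarray, k: int) -> float:
    """Height of peak k above the higher of its two surrounding bases."""
    h = s[k]
    lmin = h
    i = k - 1
    while i >= 0 and s[i] <= h:
        lmin = min(lmin, s[i])
        i -= 1
    rmin = h
    j = k + 1
    while j < len(s) and s[j] <= h:
        rmin = min(rmin, s[j])
        j += 1
    return h - max(lmin, rmin)


def width_at_half_prominence(s: np.ndarray, k: int, prom: float) -> float:
    """Interpolated width of peak k at the half-prominence evaluation height."""
    height = s[k] - 0.5 * prom
    i = k
    while i > 0 and s[i - 1] > height:
        i -= 1
    left = float(i)
    if i > 0 and s[i - 1] <= height and s[i] != s[i - 1]:
        left = i - (s[i] - height) / (s[i] - s[i - 1])
    j = k
    while j < len(s) - 1 and s[j + 1] > height:
        j += 1
    right = float(j)
    if j < len(s) - 1 and s[j + 1] <= height and s[j] != s[j + 1]:
        right = j + (s[j] - height) / (s[j] - s[j + 1])
    return right - left


def detect_peaks_bruteforce(
    s: np.ndarray, min_width_days: float = 7, min_height_frac: float = 0.15
) -> list[tuple[int, float, float]]:
    """(index, width, prominence) of every qualifying maximum, by explicit scan."""
    out = []
    if len(s) == 0 or s.max() <= 0:
        return out
    floor = min_height_frac * s.max()
    for k in local_maxima(s):
        prom = prominence(s, k)
        w = width_at_half_prominence(s, k, prom)
        if w >= min_width_days and s[k] >= floor:
            out.append((k, w, prom))
    return out


def pearson_chi2(table: np.ndarray) -> float:
    """Sum of (O - E)^2 / E over the cells, expected counts from the margins."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - e) ** 2 / e
    return stat


def classify_window_bruteforce(incidence, upper_threshold, surgery_date, follow_up_days):
    """Day-by-day scan of the follow-up window against the upper tertile bound."""
    import datetime as dt

    for d in range(follow_up_days + 1):
        day = surgery_date + dt.timedelta(days=d)
        k = incidence.index_of(day)
        if incidence.smoothed_daily[k] >= upper_threshold:
            return "TOP_TERTILE"
    return "BOTTOM_TWO"
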