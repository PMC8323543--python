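"""Detect epidemic peaks in a synthetic two-wave national case curve.

Builds a cumulative case series, differentiates it into daily incidence,
smooths with the zero-phase Butterworth low-pass, and reports every local
maximum that is at least 7 days wide (at half prominence) and reaches 15%
of the country's maximum smoothed incidence.
"""

import datetime as dt

import episurg as ep

spec = ep.EpidemicCurveSpec(
    waves=[ep.Wave(peak_day=75, sd=30, amplitude=900),
           ep.Wave(peak_day=185, sd=30, amplitude=700)],
    n_days=270, start_date=dt.date(2020, 4, 1), noise="poisson", seed=1,
)
cumulative = ep.generate_epidemic_curve(spec)
incidence = ep.butterworth_smooth(ep.differentiate(cumulative))
peaks = ep.detect_peaks(incidence, min_width_days=7, min_height_frac=0.15)

print(f"{incidence.country}: {len(peaks)} qualifying peak(s)")
for p in peaks:
    print(f"  {p.peak_date}  height {p.height:7.1f} cases/day  "
          f"width {p.width_days:5.1f} d  prominence {p.prominence:7.1f}")
# Each line is one epidemic wave: its date, smoothed size, how wide the wave
# is at half prominence, and how far it rises above the surrounding baseline.
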