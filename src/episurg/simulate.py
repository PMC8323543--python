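"""Synthetic epidemic curves and surgical cohorts with known ground truth.

Two generators make every pipeline stage testable without external data:

* Gaussian-mixture multi-wave epidemic curves (optionally Poisson-noised)
  whose integrals and peak locations have closed forms;
* patient cohorts whose covariate mix mirrors the study population
  (young, mostly female, high comorbidity load), whose complication severity
  is drawn from a known proportional-odds model and whose postoperative
  COVID risk follows a known logistic model of true tertile-band exposure
  and ethnicity.

Deterministic fixtures additionally reproduce, patient by patient, the
marginal counts of the published outcome, protocol and exposure tables so
that tabulations can be checked as exact integer ratios.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import CDGrade, PatientRecord
from .epicurve import CumulativeSeries, IncidenceSeries, _as_date
from .errors import CoverageError, ValidationError
from .exposure import ExposureLabel, Label, compute_tertiles

__all__ = [
    "Wave",
    "EpidemicCurveSpec",
    "CohortSpec",
    "CohortTruth",
    "generate_epidemic_curve",
    "generate_cohort",
    "generate_printed_fixture",
    "labels_from_records",
    "STUDY_START",
    "STUDY_END",
]

# cohort accrual window of the study design
STUDY_START = dt.date(2020, 5, 1)
STUDY_END = dt.date(2020, 10, 31)


@dataclass(frozen=True)
class Wave:
    peak_day: float  # day index within the series
    sd: float  # days
    amplitude: float  # cases/day at the mode


@dataclass
class EpidemicCurveSpec:
    """Gaussian-mixture daily-incidence curve, accumulated into counts."""

    waves: list[Wave] = field(default_factory=list)
    n_days: int = 365
    start_date: dt.date = dt.date(2020, 3, 1)
    noise: str = "none"  # none | poisson
    seed: int = 0
    country: str = "Synthland"

    def __post_init__(self):
        for w in self.waves:
            if w.amplitude < 0 or w.sd <= 0 or not (0 < w.peak_day < self.n_days):
                raise ValidationError(f"invalid wave {w}")
        if self.noise not in ("none", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")


def wave_intensity(spec: EpidemicCurveSpec) -> np.ndarray:
    """Noise-free daily intensity sum_k A_k exp(-(t - mu_k)^2 / (2 sd_k^2))."""
    t = np.arange(spec.n_days, dtype=float)
    out = np.zeros(spec.n_days)
    for w in spec.waves:
        out += w.amplitude * np.exp(-((t - w.peak_day) ** 2) / (2.0 * w.sd**2))
    return out


def generate_epidemic_curve(spec: EpidemicCurveSpec) -> CumulativeSeries:
    """Accumulate the (optionally Poisson-sampled) daily intensity into counts."""
    intensity = wave_intensity(spec)
    if spec.noise == "poisson":
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
        daily = rng.poisson(intensity).astype(float)
    else:
        daily = np.round(intensity)
    dates = np.datetime64(spec.start_date) + np.arange(spec.n_days)
    return CumulativeSeries(spec.country, dates.astype("datetime64[D]"), np.cumsum(daily))


# ---------------------------------------------------------------------------
# cohort generator

# covariate prevalences of the elective-primary study population
_DEFAULT_PREVALENCE = {
    "male": 0.266,
    "non_white": 0.2559,
    "t2d_diet": 0.059,
    "t2d_oral": 0.121,
    "t2d_insulin": 0.036,
    "hypertension": 0.309,
    "osa_no_cpap": 0.121,
    "osa_cpap": 0.134,
    "hypercholesterolaemia": 0.215,
    "other_comorbidity": 0.291,
    "smoking_current": 0.147,
    "smoking_ex": 0.131,
}
_DEFAULT_CATEGORY_MIX = {"elective_primary": 0.9195, "elective_revisional": 0.0583,
                         "emergency": 0.0222}
_DEFAULT_PROCEDURE_MIX = {"LSG": 0.563, "RYGB": 0.295, "OAGB": 0.0995, "other": 0.0425}

# highest-grade distribution of the elective-primary cohort; cutpoints of the
# generating proportional-odds model are the cumulative logits of this table
_GRADE_FRACTIONS = {
    CDGrade.NONE: 0.9324, CDGrade.I: 0.0234, CDGrade.II: 0.0192,
    CDGrade.IIIa: 0.0047, CDGrade.IIIb: 0.0134, CDGrade.IVa: 0.0045,
    CDGrade.IVb: 0.0010, CDGrade.V: 0.0014,
}


def _default_cutpoints() -> list[float]:
    cum = np.cumsum([_GRADE_FRACTIONS[g] for g in CDGrade])
    cum = cum / cum[-1]
    return list(logit(cum[:-1]))


def _default_ordinal_beta() -> dict[str, float]:
    # one common log-odds effect per covariate, matching the reported ORs
    return {
        "age": float(np.log(1.008)),
        "male": float(np.log(1.259)),
        "smoker_ever": float(np.log(1.253)),
        "t2d_insulin": float(np.log(1.451)),
        "osa_no_cpap": float(np.log(1.107)),
        "hypercholesterolaemia": float(np.log(1.440)),
        "cat_revisional": float(np.log(1.927)),
        "cat_emergency": float(np.log(3.089)),
        "proc_RYGB": float(np.log(1.219)),
    }


def _default_covid_gammas() -> tuple[float, float, float]:
    g0 = float(logit(0.001))  # bottom-two-band symptomatic COVID risk
    g1 = float(logit(0.007) - logit(0.001))  # top-band contrast (rate ratio 7)
    odds_nw = (18 / 1904) / (1 - 18 / 1904)
    odds_w = (25 / 5800) / (1 - 25 / 5800)
    g2 = float(np.log(odds_nw / odds_w))  # non-white ethnicity effect
    return g0, g1, g2


@dataclass
class CohortSpec:
    """Data-generating twin of the study cohort."""

    n: int = 6000
    age_mean: float = 40.35
    age_sd: float = 11.9
    bmi_mean: float = 43.03
    bmi_sd: float = 6.9
    prevalence: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    category_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CATEGORY_MIX))
    procedure_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PROCEDURE_MIX))
    ordinal_beta: dict[str, float] = field(default_factory=_default_ordinal_beta)
    ordinal_cutpoints: list[float] = field(default_factory=_default_cutpoints)
    # ordinal age effect is per year; centred so cutpoints stay interpretable
    age_center: float = 40.35
    covid_gamma0: float = _default_covid_gammas()[0]
    covid_gamma1: float = _default_covid_gammas()[1]
    covid_gamma2: float = _default_covid_gammas()[2]
    surgery_start: dt.date = STUDY_START
    surgery_end: dt.date = STUDY_END
    follow_up_days: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        for k, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"prevalence {k}={p} outside [0, 1]")
        if np.any(np.diff(self.ordinal_cutpoints) <= 0):
            raise ValidationError("cutpoints must be strictly increasing")


@dataclass
class CohortTruth:
    """Hidden generating truth retained for parameter-recovery tests."""

    spec: CohortSpec
    top_band: np.ndarray  # bool per patient: window truly reaches top tertile
    eta: np.ndarray  # ordinal linear predictor per patient
    upper_threshold: float
    covid_prob: np.ndarray


def _feature_value(r: PatientRecord, name: str, age_center: float) -> float:
    from .ordinal import FEATURES

    if name == "age":
        return float(r.age) - age_center
    return FEATURES[name](r)


def generate_cohort(
    spec: CohortSpec, curve: IncidenceSeries
) -> tuple[list[PatientRecord], CohortTruth]:
    """Draw a cohort; outcomes follow the spec's ordinal and COVID models.

    The true exposure band of each patient is computed from the supplied
    incidence series (thirds-of-maximum bands over the surgery accrual
    period, any-window-day rule), so pipeline estimates can be compared
    against generating truth.
    """
    if curve.smoothed_daily is None:
        curve = IncidenceSeries(curve.country, curve.dates, curve.raw_daily, curve.raw_daily)
    last = pd.Timestamp(curve.dates[-1]).date()
    if _as_date(spec.surgery_end) + dt.timedelta(days=spec.follow_up_days) > last:
        raise CoverageError("incidence curve does not cover all follow-up windows")

    streams = np.random.SeedSequence(int(spec.seed)).spawn(4)
    rng_cov = np.random.default_rng(streams[0])
    rng_dates = np.random.default_rng(streams[1])
    rng_ord = np.random.default_rng(streams[2])
    rng_cov19 = np.random.default_rng(streams[3])

    n = spec.n
    pr = spec.prevalence
    age = np.clip(rng_cov.normal(spec.age_mean, spec.age_sd, n), 18.0, 90.0)
    bmi = np.clip(rng_cov.normal(spec.bmi_mean, spec.bmi_sd, n), 16.0, 90.0)
    sex = np.where(rng_cov.random(n) < pr["male"], "M", "F")
    ethnicity = np.where(rng_cov.random(n) < pr["non_white"], "non_white", "white")
    t2d = rng_cov.choice(
        ["diet", "oral", "insulin", "none"], n,
        p=[pr["t2d_diet"], pr["t2d_oral"], pr["t2d_insulin"],
           1 - pr["t2d_diet"] - pr["t2d_oral"] - pr["t2d_insulin"]],
    )
    osa = rng_cov.choice(
        ["no_cpap", "cpap", "none"], n,
        p=[pr["osa_no_cpap"], pr["osa_cpap"], 1 - pr["osa_no_cpap"] - pr["osa_cpap"]],
    )
    smoking = rng_cov.choice(
        ["current", "ex", "never"], n,
        p=[pr["smoking_current"], pr["smoking_ex"],
           1 - pr["smoking_current"] - pr["smoking_ex"]],
    )
    htn = rng_cov.random(n) < pr["hypertension"]
    chol = rng_cov.random(n) < pr["hypercholesterolaemia"]
    other_com = rng_cov.random(n) < pr["other_comorbidity"]
    cats, cat_p = zip(*spec.category_mix.items())
    category = rng_cov.choice(cats, n, p=np.asarray(cat_p) / np.sum(cat_p))
    procs, proc_p = zip(*spec.procedure_mix.items())
    procedure = rng_cov.choice(procs, n, p=np.asarray(proc_p) / np.sum(proc_p))
    procedure = np.where(category == "elective_primary", procedure, "other")

    span = (_as_date(spec.surgery_end) - _as_date(spec.surgery_start)).days
    offsets = rng_dates.integers(0, span + 1, n)
    dates = [_as_date(spec.surgery_start) + dt.timedelta(days=int(o)) for o in offsets]

    records = [
        PatientRecord(
            patient_id=f"sim-{i:06d}",
            country=curve.country,
            surgery_date=dates[i],
            category=str(category[i]),
            procedure=str(procedure[i]),
            age=float(age[i]),
            sex=str(sex[i]),
            bmi=float(bmi[i]),
            ethnicity=str(ethnicity[i]),
            t2d=str(t2d[i]),
            hypertension=bool(htn[i]),
            osa=str(osa[i]),
            hypercholesterolaemia=bool(chol[i]),
            other_comorbidity=bool(other_com[i]),
            smoking=str(smoking[i]),
        )
        for i in range(n)
    ]

    # ordinal outcome from the proportional-odds model
    beta_names = list(spec.ordinal_beta)
    eta = np.zeros(n)
    for name in beta_names:
        vals = np.array([_feature_value(r, name, spec.age_center) for r in records])
        eta += spec.ordinal_beta[name] * vals
    cut = np.asarray(spec.ordinal_cutpoints, dtype=float)
    cum = expit(cut[None, :] - eta[:, None])
    probs = np.diff(np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))]), axis=1)
    u = rng_ord.random(n)
    y = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    type_cycle = ["bleeding", "leak", "wound_infection", "pneumonia", "other"]
    for i, r in enumerate(records):
        if y[i] > 0:
            r.complications = [(type_cycle[i % len(type_cycle)], CDGrade(int(y[i])))]

    # true exposure band from the generating curve
    bands = compute_tertiles(curve, spec.surgery_start, spec.surgery_end)
    s = curve.smoothed_daily
    w = spec.follow_up_days
    rolmax = pd.Series(s).rolling(w + 1).max().to_numpy()
    i0 = np.array([curve.index_of(d) for d in dates])
    top = rolmax[i0 + w] >= bands.upper_threshold

    lin = spec.covid_gamma0 + spec.covid_gamma1 * top.astype(float)
    lin = lin + spec.covid_gamma2 * (ethnicity == "non_white").astype(float)
    covid_prob = expit(lin)
    covid = rng_cov19.random(n) < covid_prob
    for i, r in enumerate(records):
        r.covid_postop = bool(covid[i])

    truth = CohortTruth(spec, top, eta, bands.upper_threshold, covid_prob)
    return records, truth


# ---------------------------------------------------------------------------
# deterministic printed fixtures (synthetic stand-ins for the undeposited registry)

# (category, procedure, n, highest-grade counts I..V, specific-type counts, covid count)
_TYPE_ORDER = ["bleeding", "leak", "wound_infection", "pneumonia", "dvt", "pe", "other"]
_TABLE2_LEAVES = [
    ("elective_primary", "LSG", 3988, [84, 63, 16, 50, 13, 3, 4], [57, 26, 20, 5, 2, 2, 112], 20),
    ("elective_primary", "RYGB", 2091, [63, 48, 8, 31, 15, 2, 0], [41, 13, 11, 7, 1, 3, 93], 10),
    ("elective_primary", "OAGB", 705, [11, 17, 7, 12, 3, 0, 4], [20, 9, 7, 1, 0, 1, 25], 5),
    ("elective_primary", "other", 300, [8, 8, 2, 2, 1, 2, 2], [2, 2, 4, 2, 0, 1, 14], 3),
    ("elective_revisional", "other", 285, [11, 6, 5, 8, 4, 1, 0], [5, 8, 4, 2, 0, 0, 22], 0),
    ("elective_revisional", "other", 164, [4, 5, 3, 5, 1, 0, 0], [4, 1, 7, 1, 0, 0, 9], 2),
    ("emergency", "other", 171, [12, 11, 1, 10, 1, 0, 0], [0, 2, 6, 3, 1, 0, 27], 3),
]
_GRADE_ORDER = [CDGrade.I, CDGrade.II, CDGrade.IIIa, CDGrade.IIIb,
                CDGrade.IVa, CDGrade.IVb, CDGrade.V]


def _fixture_date(i: int) -> dt.date:
    span = (STUDY_END - STUDY_START).days + 1
    return STUDY_START + dt.timedelta(days=i % span)


def _build_table2() -> list[PatientRecord]:
    records: list[PatientRecord] = []
    uid = 0
    for category, procedure, n, grades, types, n_covid in _TABLE2_LEAVES:
        highest = [g for g, c in zip(_GRADE_ORDER, grades) for _ in range(c)]
        entries = ["covid19"] * n_covid + [t for t, c in zip(_TYPE_ORDER, types) for _ in range(c)]
        leaf: list[PatientRecord] = []
        for i in range(n):
            r = PatientRecord(
                patient_id=f"t2-{uid:05d}", country="Synthland",
                surgery_date=_fixture_date(uid), category=category, procedure=procedure,
            )
            if i < len(highest):
                r.complications = [(entries[i], highest[i])]
                r.covid_postop = entries[i] == "covid19"
            leaf.append(r)
            uid += 1
        # surplus typed entries become second complications of the same grade,
        # attached to patients not already carrying that type
        j = 0
        for t in entries[len(highest):]:
            while {typ for typ, _ in leaf[j].complications} & {t} or not leaf[j].complications:
                j += 1
            leaf[j].complications.append((t, leaf[j].highest_grade))
            j += 1
        records.extend(leaf)
    return records


def _assign_prefix(records: list[PatientRecord], count: int, setter) -> None:
    for r in records[:count]:
        setter(r)


def _build_table4() -> list[PatientRecord]:
    records = [
        PatientRecord(
            patient_id=f"t4-{i:05d}", country="Synthland", surgery_date=_fixture_date(i),
            category=("elective_primary" if i < 7084 else
                      "elective_revisional" if i < 7533 else "emergency"),
            procedure="LSG" if i < 7084 else "other",
        )
        for i in range(7704)
    ]
    elective = records[:7533]
    emergency = records[7533:]
    for group, iso_counts, n_test, n_ppe in (
        (elective, [2067, 163, 1061, 4068, 174], 6042, 3316),
        (emergency, [1, 2, 22, 119, 27], 93, 49),
    ):
        pos = 0
        for lvl, c in zip(["1_week", "10_days", "2_weeks", "none", "other"], iso_counts):
            for r in group[pos : pos + c]:
                r.isolation = lvl
            pos += c
        _assign_prefix(group, n_test, lambda r: setattr(r, "preop_test", True))
        _assign_prefix(group, n_ppe, lambda r: setattr(r, "ppe", True))
    return records


def _build_exposure2x2() -> list[PatientRecord]:
    records = []
    for i in range(6598):
        top = i < 4674
        covid = (top and i < 34) or (not top and i < 4674 + 2)
        records.append(
            PatientRecord(
                patient_id=f"x-{i:05d}", country="Synthland",
                surgery_date=_fixture_date(i),
                exposure_label=(Label.TOP_TERTILE if top else Label.BOTTOM_TWO).value,
                covid_postop=covid,
            )
        )
    return records


def _build_table6() -> list[PatientRecord]:
    records = [
        PatientRecord(patient_id=f"t6-{i:05d}", country="Synthland",
                      surgery_date=_fixture_date(i), hospital_treats_covid=False)
        for i in range(7704)
    ]
    covid_grp, rest = records[:43], records[43:]
    for r in covid_grp:
        r.covid_postop = True
    for group, n_nw, n_iso, n_test, n_hosp, n_ppe in (
        (covid_grp, 18, 26, 35, 32, 23),
        (rest, 1886, 3290, 6100, 6054, 4319),
    ):
        _assign_prefix(group, n_nw, lambda r: setattr(r, "ethnicity", "non_white"))
        _assign_prefix(group, n_iso, lambda r: setattr(r, "isolation", "2_weeks"))
        _assign_prefix(group, n_test, lambda r: setattr(r, "preop_test", True))
        _assign_prefix(group, n_hosp, lambda r: setattr(r, "hospital_treats_covid", True))
        _assign_prefix(group, n_ppe, lambda r: setattr(r, "ppe", True))
    return records


_FIXTURES = {
    "table2": _build_table2,
    "table4": _build_table4,
    "exposure2x2": _build_exposure2x2,
    "table6": _build_table6,
}


def generate_printed_fixture(table: str) -> list[PatientRecord]:
    """Deterministic synthetic cohort whose marginals equal a printed table.

    ``table`` is one of table2 (30-day outcome grades), table4 (perioperative
    protocols), exposure2x2 (tertile-exposure vs postoperative COVID) or
    table6 (factors associated with postoperative COVID). All unconstrained
    fields are filled deterministically; these are synthetic stand-ins for
    the study registry, faithful only in the stated marginal counts.
    """
    try:
        return _FIXTURES[table]()
    except KeyError:
        raise ValidationError(
            f"unknown fixture {table!r}; available: {sorted(_FIXTURES)}"
        ) from None


def labels_from_records(records: list[PatientRecord]):
    """Exposure labels + outcome map from records with precomputed bands."""
    labels, outcomes = [], {}
    for r in records:
        if r.exposure_label is None:
            raise ValidationError(f"record {r.patient_id} has no exposure label")
        end = r.surgery_date + dt.timedelta(days=30) if r.surgery_date else None
        labels.append(ExposureLabel(r.patient_id, Label(r.exposure_label), r.surgery_date, end))
        outcomes[r.patient_id] = r.covid_postop
    return labels, outcomes
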