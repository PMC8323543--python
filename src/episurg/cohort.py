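"""Surgical cohort records, Clavien-Dindo outcome tabulation and univariate tests.

Complication severity follows the Clavien-Dindo (CD) ordinal scale
(NONE < I < II < IIIa < IIIb < IVa < IVb < V). A patient with several
complications is summarised by the highest grade. Grades I-II are minor,
III-V major; IVa/IVb/V imply intensive care; V is death.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, ValidationError

__all__ = [
    "CDGrade",
    "PatientRecord",
    "OutcomeTable",
    "highest_grade",
    "tabulate_outcomes",
    "univariate_compare",
    "tabulate_protocols",
    "records_to_frame",
    "write_patient_csv",
    "read_patient_csv",
]


class CDGrade(IntEnum):
    """Clavien-Dindo grade under its total order; NONE means no complication."""

    NONE = 0
    I = 1
    II = 2
    IIIa = 3
    IIIb = 4
    IVa = 5
    IVb = 6
    V = 7

    @classmethod
    def from_label(cls, label: str) -> "CDGrade":
        key = str(label).strip()
        try:
            return cls[key] if key in cls.__members__ else cls[key.upper()]
        except KeyError:
            # tolerate case variants like "iiia"
            for member in cls:
                if member.name.lower() == key.lower():
                    return member
            raise ValidationError(f"unknown Clavien-Dindo grade {label!r}") from None

    @property
    def is_minor(self) -> bool:
        return self in (CDGrade.I, CDGrade.II)

    @property
    def is_major(self) -> bool:
        return self >= CDGrade.IIIa

    @property
    def needs_icu(self) -> bool:
        return self >= CDGrade.IVa


COMPLICATION_TYPES = [
    "bleeding",
    "leak",
    "wound_infection",
    "pneumonia",
    "dvt",
    "pe",
    "covid19",
    "other",
]

ISOLATION_LEVELS = ["1_week", "10_days", "2_weeks", "none", "other"]


@dataclass
class PatientRecord:
    """One surgical patient with covariates, CD-graded complications and outcome."""

    patient_id: str
    country: str = ""
    surgery_date: dt.date | None = None
    category: str = "elective_primary"  # elective_primary | elective_revisional | emergency
    procedure: str = "LSG"  # LSG | RYGB | OAGB | other
    age: float = 40.0
    sex: str = "F"  # M | F
    bmi: float = 43.0
    ethnicity: str = "white"  # white | non_white
    t2d: str = "none"  # none | diet | oral | insulin
    hypertension: bool = False
    osa: str = "none"  # none | no_cpap | cpap
    hypercholesterolaemia: bool = False
    other_comorbidity: bool = False
    smoking: str = "never"  # current | ex | never
    complications: list[tuple[str, CDGrade]] = field(default_factory=list)
    covid_postop: bool = False
    isolation: str = "none"  # one of ISOLATION_LEVELS
    preop_test: bool = False
    ppe: bool = False
    hospital_treats_covid: bool = True
    hospital_category: str = "district_general"
    hospital_beds_band: str = "<200"
    surgeon_experience_band: str = "1000-2000"
    exposure_label: str | None = None  # precomputed exposure band, if known

    def __post_init__(self):
        if self.age < 18:
            raise ValidationError("cohort is adults only (age >= 18)")
        if self.bmi <= 0:
            raise ValidationError("bmi must be positive")
        self.complications = [
            (t, g if isinstance(g, CDGrade) else CDGrade.from_label(g))
            for t, g in self.complications
        ]

    @property
    def preop_isolation(self) -> bool:
        return self.isolation != "none"

    @property
    def highest_grade(self) -> CDGrade:
        return highest_grade(self.complications)


def highest_grade(complications: list[tuple[str, CDGrade]]) -> CDGrade:
    """Maximum grade under the CD order; NONE for an empty list."""
    best = CDGrade.NONE
    for _, g in complications:
        g = g if isinstance(g, CDGrade) else CDGrade.from_label(g)
        if g > best:
            best = g
    return best


# ---------------------------------------------------------------------------
# tabulations


_GRADE_ROWS = [g for g in CDGrade if g is not CDGrade.NONE]


@dataclass
class OutcomeTable:
    """Counts and percentages per stratum, one column per stratum level."""

    counts: pd.DataFrame
    percentages: pd.DataFrame  # counts / stratum n * 100 (n row excluded)

    def to_csv(self, path) -> None:
        merged = self.counts.astype(object).copy()
        for col in merged.columns:
            for row in merged.index:
                if row == "n":
                    continue
                merged.loc[row, col] = (
                    f"{self.counts.loc[row, col]} ({self.percentages.loc[row, col]:.2f}%)"
                )
        merged.to_csv(path)

    def to_text(self) -> str:
        return self.counts.to_string()


def tabulate_outcomes(records: list[PatientRecord], stratify_by: str = "category") -> OutcomeTable:
    """Tabulate 30-day outcomes per stratum of ``stratify_by``.

    Rows: n, per-grade highest-grade counts, all complications, minor (I-II),
    major (III-V), ICU (IVa/IVb/V), deaths (V), postoperative COVID and the
    specific complication types (a patient counts once per type).
    An empty stratum yields a zero column with n = 0.
    """
    rows = (
        ["n"]
        + [f"grade_{g.name}" for g in _GRADE_ROWS]
        + ["all_complications", "minor_I_II", "major_III_V", "icu_IV_V", "deaths", "covid19_postop"]
        + [f"type_{t}" for t in COMPLICATION_TYPES]
    )
    strata: dict[str, list[PatientRecord]] = {}
    for r in records:
        strata.setdefault(str(getattr(r, stratify_by)), []).append(r)
    counts = pd.DataFrame(0, index=rows, columns=sorted(strata), dtype=int)
    for level, members in strata.items():
        counts.loc["n", level] = len(members)
        for r in members:
            hg = r.highest_grade
            if hg is not CDGrade.NONE:
                counts.loc[f"grade_{hg.name}", level] += 1
                counts.loc["all_complications", level] += 1
                counts.loc["minor_I_II" if hg.is_minor else "major_III_V", level] += 1
                if hg.needs_icu:
                    counts.loc["icu_IV_V", level] += 1
                if hg is CDGrade.V:
                    counts.loc["deaths", level] += 1
            if r.covid_postop:
                counts.loc["covid19_postop", level] += 1
            for t in {t for t, _ in r.complications}:
                if t in COMPLICATION_TYPES:
                    counts.loc[f"type_{t}", level] += 1
    n = counts.loc["n"].replace(0, np.nan)
    percentages = counts.drop(index="n").div(n, axis=1).mul(100.0).fillna(0.0)
    return OutcomeTable(counts, percentages)


@dataclass
class UnivariateResult:
    statistic: float
    p_value: float
    test_name: str


def _grouping_mask(records: list[PatientRecord], grouping: str) -> np.ndarray:
    if grouping == "complication":
        return np.array([r.highest_grade is not CDGrade.NONE for r in records])
    if grouping == "covid":
        return np.array([r.covid_postop for r in records])
    raise ValueError(f"unknown grouping {grouping!r}")


def univariate_compare(
    records: list[PatientRecord],
    variable: str,
    grouping: str = "complication",
    method: str = "auto",
    correction: bool = False,
    normality_alpha: float = 0.05,
) -> UnivariateResult:
    """Univariate comparison of one variable between outcome groups.

    Categorical variables: Pearson chi-square on the contingency table
    (without continuity correction unless ``correction``). Continuous
    variables: Welch t-test when a per-group Shapiro-Wilk screen at
    ``normality_alpha`` passes, Mann-Whitney U (asymptotic, tie-corrected)
    otherwise; ``method`` forces "t", "mannwhitney" or "chi2".
    """
    group = _grouping_mask(records, grouping)
    if group.all() or not group.any():
        raise DegenerateTestError("grouping variable is constant")
    values = np.array([getattr(r, variable) for r in records], dtype=object)
    numeric = all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in values)

    if method == "chi2" or (method == "auto" and not numeric):
        table = pd.crosstab(pd.Series(values.astype(str)), pd.Series(group))
        if table.shape[0] < 2:
            raise DegenerateTestError(f"variable {variable!r} is constant")
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
        return UnivariateResult(float(stat), float(p), "pearson_chi2")

    x = values[group].astype(float)
    y = values[~group].astype(float)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateTestError(f"variable {variable!r} is constant")
    if method == "auto":
        method = "t" if _normality_screen(x, y, normality_alpha) else "mannwhitney"
    if method == "t":
        stat, p = stats.ttest_ind(x, y, equal_var=False)
        return UnivariateResult(float(stat), float(p), "welch_t")
    if method == "mannwhitney":
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return UnivariateResult(float(stat), float(p), "mann_whitney_u")
    raise ValueError(f"unknown method {method!r}")


def _normality_screen(x: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk per group; subsampled above 500 for stability of the screen."""
    rng = np.random.default_rng(0)
    for g in (x, y):
        if len(g) < 8:  # too small to screen: default to the rank test
            return False
        sample = g if len(g) <= 500 else rng.choice(g, 500, replace=False)
        if stats.shapiro(sample).pvalue < alpha:
            return False
    return True


def tabulate_protocols(records: list[PatientRecord]) -> pd.DataFrame:
    """Perioperative protocol summary in the elective vs emergency layout.

    Rows: the self-isolation duration categories, preoperative testing and
    theatre PPE use; columns: counts and percentages against the elective
    and emergency denominators.
    """
    elective = [r for r in records if r.category in ("elective_primary", "elective_revisional")]
    emergency = [r for r in records if r.category == "emergency"]
    rows = [f"isolation_{lvl}" for lvl in ISOLATION_LEVELS] + ["preop_test", "ppe_used"]
    out = pd.DataFrame(
        0.0, index=rows, columns=["elective_n", "elective_pct", "emergency_n", "emergency_pct"]
    )
    for prefix, group in (("elective", elective), ("emergency", emergency)):
        n = len(group)
        for lvl in ISOLATION_LEVELS:
            c = sum(r.isolation == lvl for r in group)
            out.loc[f"isolation_{lvl}", f"{prefix}_n"] = c
            out.loc[f"isolation_{lvl}", f"{prefix}_pct"] = 100.0 * c / n if n else 0.0
        for row, flag in (("preop_test", "preop_test"), ("ppe_used", "ppe")):
            c = sum(getattr(r, flag) for r in group)
            out.loc[row, f"{prefix}_n"] = c
            out.loc[row, f"{prefix}_pct"] = 100.0 * c / n if n else 0.0
    out[["elective_n", "emergency_n"]] = out[["elective_n", "emergency_n"]].astype(int)
    out.attrs["n_elective"] = len(elective)
    out.attrs["n_emergency"] = len(emergency)
    return out


# ---------------------------------------------------------------------------
# CSV round trip

_SIMPLE_FIELDS = [
    f.name
    for f in fields(PatientRecord)
    if f.name not in ("complications", "surgery_date")
]


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records to one row per patient (complications as type:grade;...)."""
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in _SIMPLE_FIELDS}
        row["surgery_date"] = r.surgery_date.isoformat() if r.surgery_date else ""
        row["complications"] = ";".join(f"{t}:{g.name}" for t, g in r.complications)
        row["highest_grade"] = r.highest_grade.name
        rows.append(row)
    return pd.DataFrame(rows)


def write_patient_csv(records: list[PatientRecord], path) -> None:
    records_to_frame(records).drop(columns=["highest_grade"]).to_csv(path, index=False)


def read_patient_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    bool_fields = {
        "hypertension", "hypercholesterolaemia", "other_comorbidity",
        "covid_postop", "preop_test", "ppe", "hospital_treats_covid",
    }
    for _, row in df.iterrows():
        kwargs = {}
        for name in _SIMPLE_FIELDS:
            if name not in row:
                continue
            v = row[name]
            if name in bool_fields:
                v = str(v).strip().lower() in ("true", "1", "yes")
            elif name == "exposure_label":
                v = None if v == "" else str(v)
            kwargs[name] = v
        sd = str(row.get("surgery_date", "")).strip()
        kwargs["surgery_date"] = dt.date.fromisoformat(sd) if sd else None
        comp = str(row.get("complications", "")).strip()
        kwargs["complications"] = [
            (part.split(":")[0], CDGrade.from_label(part.split(":")[1]))
            for part in comp.split(";")
            if part
        ]
        records.append(PatientRecord(**kwargs))
    return records
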