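"""BMI, LMS growth-reference z-scores, and cohort eligibility filtering.

The LMS method expresses an age- and sex-specific BMI distribution through
three parameters — Box-Cox power L, median M, coefficient of variation S —
and standardizes a measurement X as::

    z = ((X/M)**L - 1) / (L*S)   if L != 0
    z = ln(X/M) / S              if L == 0

with the exact inverse X = M*(1 + L*S*z)**(1/L) (resp. M*exp(S*z)).
Reference rows are keyed by sex (1 = male, 2 = female) and half-month age
bins (agemos = floor(age in months) + 0.5), the convention of the CDC 2000
reference tables, which can be dropped in via :meth:`GrowthReference.from_csv`.

Because the real CDC tables cannot be redistributed here, the package ships
:func:`synthetic_growth_reference`, a programmatically generated stand-in
with smooth L/M/S curves calibrated to widely known school-age medians
(e.g. boys at 11 y: median BMI ~17.8 kg/m², median stature ~143.5 cm).  It
is synthetic: adequate for simulation, round-trip and magnitude checks, not
for clinical use.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .errors import RecordError, WalkbmiError

MALE, FEMALE = 1, 2

RACE_LEVELS = ("black", "hispanic", "asian", "white", "other", "missing")

COHORT_COLUMNS = [
    "child_id", "sex", "birth_date", "race_ethnicity", "x", "y", "tract_id",
    "visit_date", "height_m", "weight_kg", "excluded_condition",
]

DAYS_PER_YEAR = 365.25


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m²."""
    if np.any(np.asarray(weight_kg) <= 0) or np.any(np.asarray(height_m) <= 0):
        raise RecordError("weight and height must be positive")
    return weight_kg / height_m**2


class GrowthReference:
    """Age-in-months x sex table of LMS parameters.

    Parameters
    ----------
    table : DataFrame
        Columns ``sex`` (1 male / 2 female), ``agemos`` (half-month bins),
        ``L``, ``M``, ``S``; M and S must be positive everywhere.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "agemos", "L", "M", "S"}
        if not required.issubset(table.columns):
            raise WalkbmiError(f"growth reference needs columns {sorted(required)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise WalkbmiError("growth reference M and S must be positive")
        self.table = table.sort_values(["sex", "agemos"]).reset_index(drop=True)
        self._lut = {
            (int(r.sex), float(r.agemos)): (float(r.L), float(r.M), float(r.S))
            for r in self.table.itertuples()
        }
        self._coverage = {
            int(s): (g["agemos"].min(), g["agemos"].max())
            for s, g in self.table.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def coverage(self, sex: int) -> tuple[float, float]:
        return self._coverage[int(sex)]

    def lms(self, sex: int, age_months: float) -> tuple[float, float, float]:
        """LMS row for the half-month bin containing ``age_months``."""
        lo, hi = self._coverage[int(sex)]
        bin_age = np.floor(age_months) + 0.5
        if not (lo <= bin_age <= hi):
            raise WalkbmiError(
                f"age {age_months:.1f} months outside reference coverage "
                f"[{lo}, {hi}] for sex {sex}"
            )
        return self._lut[(int(sex), float(bin_age))]


def lms_z(x: float, ref: GrowthReference, sex: int, age_months: float) -> float:
    """LMS z-score of measurement ``x`` for the given sex and age."""
    L, M, S = ref.lms(sex, age_months)
    if L != 0:
        return ((x / M) ** L - 1.0) / (L * S)
    return np.log(x / M) / S


def inverse_lms(z: float, ref: GrowthReference, sex: int, age_months: float) -> float:
    """Measurement value whose LMS z-score equals ``z`` (exact inverse)."""
    L, M, S = ref.lms(sex, age_months)
    if L != 0:
        base = 1.0 + L * S * z
        if np.any(np.asarray(base) <= 0):
            raise WalkbmiError("z outside the domain of the inverse LMS transform")
        return M * base ** (1.0 / L)
    return M * np.exp(S * z)


def zscores(
    bmi_values: np.ndarray,
    sexes: np.ndarray,
    age_months: np.ndarray,
    ref: GrowthReference,
) -> np.ndarray:
    """Vectorized LMS z-scores (NaN where age is outside coverage)."""
    bmi_values = np.asarray(bmi_values, dtype=float)
    sexes = np.asarray(sexes, dtype=int)
    age_months = np.asarray(age_months, dtype=float)
    out = np.full(bmi_values.shape, np.nan)
    bins = np.floor(age_months) + 0.5
    for i in range(len(out)):
        key = (int(sexes[i]), float(bins[i]))
        row = ref._lut.get(key)
        if row is None:
            continue
        L, M, S = row
        x = bmi_values[i]
        out[i] = ((x / M) ** L - 1) / (L * S) if L != 0 else np.log(x / M) / S
    return out


# ---------------------------------------------------------------------------
# synthetic growth reference (labelled synthetic; see module docstring)

_BMI_M_ANCHORS = {
    MALE: [(2, 16.5), (4, 15.8), (5.5, 15.4), (8, 16.2), (11, 17.8),
           (14, 19.4), (17, 21.4), (20, 23.0)],
    FEMALE: [(2, 16.4), (4, 15.5), (5.5, 15.2), (8, 16.2), (11, 18.0),
             (14, 19.9), (17, 21.1), (20, 21.7)],
}
_BMI_S_ANCHORS = {
    MALE: [(2, 0.075), (4, 0.085), (8, 0.105), (11, 0.132), (13, 0.145),
           (16, 0.142), (20, 0.135)],
    FEMALE: [(2, 0.080), (4, 0.090), (8, 0.110), (11, 0.135), (13, 0.145),
             (16, 0.140), (20, 0.135)],
}
_BMI_L = -2.0  # left-skewed pediatric BMI; constant Box-Cox power

_STATURE_M_ANCHORS = {
    MALE: [(2, 86.5), (4, 102.5), (6, 115.5), (8, 128.0), (10, 138.5),
           (11, 143.5), (12, 149.0), (13, 156.0), (14, 163.5), (15, 170.0),
           (16, 173.5), (17, 175.5), (19, 176.8), (20, 177.0)],
    FEMALE: [(2, 85.0), (4, 101.0), (6, 115.0), (8, 127.5), (10, 138.5),
             (11, 144.5), (12, 151.5), (13, 157.0), (14, 160.5), (15, 162.0),
             (16, 162.5), (20, 163.3)],
}
_STATURE_S = {MALE: 0.043, FEMALE: 0.042}


def synthetic_growth_reference(kind: str = "bmi") -> GrowthReference:
    """Synthetic LMS reference for ``kind`` in {"bmi", "stature"}.

    Monthly half-month bins from 24.5 to 240.5 months for both sexes.
    BMI curves reproduce the familiar adiposity dip near age 5.5 and the
    adolescent rise; stature medians follow piecewise-linear interpolation
    of school-age anchor heights (cm).  Synthetic stand-in for the CDC 2000
    tables, not real reference data.
    """
    if kind not in ("bmi", "stature"):
        raise WalkbmiError("kind must be 'bmi' or 'stature'")
    agemos = np.arange(24.5, 240.5 + 1e-9, 1.0)
    years = agemos / 12.0
    rows = []
    for sex in (MALE, FEMALE):
        if kind == "bmi":
            mx, my = zip(*_BMI_M_ANCHORS[sex])
            sx, sy = zip(*_BMI_S_ANCHORS[sex])
            M = np.interp(years, mx, my)
            S = np.interp(years, sx, sy)
            L = np.full_like(M, _BMI_L)
        else:
            mx, my = zip(*_STATURE_M_ANCHORS[sex])
            M = np.interp(years, mx, my)
            S = np.full_like(M, _STATURE_S[sex])
            L = np.ones_like(M)
        for a, l, m, s in zip(agemos, L, M, S):
            rows.append((sex, a, l, m, s))
    return GrowthReference(
        pd.DataFrame(rows, columns=["sex", "agemos", "L", "M", "S"])
    )


def weight_difference_for_delta_z(
    delta_z: float,
    bmi_ref: GrowthReference,
    stature_ref: GrowthReference,
    sex: int = MALE,
    age_years: float = 11.0,
) -> float:
    """Weight difference (kg) corresponding to a BMI z-score difference.

    Evaluated for a child at the 50th percentile of BMI and stature for age
    and sex: the BMI difference between z = delta_z and z = 0, times the
    median height squared.
    """
    age_months = age_years * 12.0
    x1 = inverse_lms(delta_z, bmi_ref, sex, age_months)
    x0 = inverse_lms(0.0, bmi_ref, sex, age_months)
    height_m = inverse_lms(0.0, stature_ref, sex, age_months) / 100.0
    return (x1 - x0) * height_m**2


# ---------------------------------------------------------------------------
# study windows and eligibility


@dataclass(frozen=True)
class StudyWindows:
    """Index and history windows for visit selection.

    Defaults: index well-child visits August 2011 through August 2012;
    earlier history visits from January 2008.
    """

    index_start: date = date(2011, 8, 1)
    index_end: date = date(2012, 8, 31)
    history_start: date = date(2008, 1, 1)

    def __post_init__(self) -> None:
        if not (self.history_start <= self.index_start <= self.index_end):
            raise WalkbmiError("study windows must be ordered history <= index")


#: exclusion reason codes, in the order criteria are applied
EXCLUSION_REASONS = (
    "a_out_of_region",
    "b_age_out_of_range",
    "c_no_index_z",
    "d_z_outlier",
    "e_condition",
    "f_fewer_than_two_measures",
    "g_followup_under_one_year",
)


def _age_years(birth: pd.Timestamp, when: pd.Timestamp) -> float:
    return (when - birth).days / DAYS_PER_YEAR


def eligibility_filter(
    visits: pd.DataFrame,
    ref: GrowthReference,
    mode: str = "cross_sectional",
    windows: StudyWindows | None = None,
    region=None,
    outlier_all_visits: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion criteria and build per-child analysis rows.

    Criteria, applied in order (the first failure is logged):

    a. home location inside the study region (skipped when ``region`` is None),
    b. age 4 to < 19 years at the index visit,
    c. at least one BMI z-score from a well-child visit in the index window,
    d. index-visit BMI z-score strictly between -6 and 6 (all visits when
       ``outlier_all_visits``),
    e. no growth-affecting chronic condition or pregnancy flag,
    f. (longitudinal only) at least two BMI measures in the history+index span,
    g. (longitudinal only) >= 1 year between the first and last measurement.

    Returns ``(analysis, exclusion_log)``: one analysis row per retained
    child (index-visit BMI/z; plus first-visit and change columns in
    longitudinal mode), and one log row per dropped child with its reason
    code.
    """
    if mode not in ("cross_sectional", "longitudinal"):
        raise WalkbmiError("mode must be 'cross_sectional' or 'longitudinal'")
    windows = windows or StudyWindows()
    v = visits.copy()
    missing = [c for c in COHORT_COLUMNS if c not in v.columns]
    if missing:
        raise RecordError(f"cohort table missing columns {missing}")
    try:
        v["birth_date"] = pd.to_datetime(v["birth_date"], format="ISO8601")
        v["visit_date"] = pd.to_datetime(v["visit_date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise RecordError(f"unparseable date in cohort table: {exc}") from exc
    bad = v[(v["height_m"] <= 0) | (v["weight_kg"] <= 0)]
    if len(bad):
        raise RecordError(
            f"non-positive height/weight for child {bad.iloc[0]['child_id']!r}"
        )
    v["bmi"] = v["weight_kg"] / v["height_m"] ** 2
    v["age_years"] = (v["visit_date"] - v["birth_date"]).dt.days / DAYS_PER_YEAR
    v["z"] = zscores(
        v["bmi"].to_numpy(), v["sex"].to_numpy(),
        (v["age_years"] * 12).to_numpy(), ref,
    )

    idx_start = pd.Timestamp(windows.index_start)
    idx_end = pd.Timestamp(windows.index_end)
    hist_start = pd.Timestamp(windows.history_start)

    kept_rows: list[dict] = []
    log_rows: list[dict] = []
    for child_id, g in v.groupby("child_id", sort=True):
        g = g.sort_values("visit_date")
        first_row = g.iloc[0]
        reason = None

        if region is not None and not region.covers(
            Point(float(first_row.x), float(first_row.y))
        ):
            reason = "a_out_of_region"

        in_index = g[(g.visit_date >= idx_start) & (g.visit_date <= idx_end)]
        index_visit = in_index.iloc[-1] if len(in_index) else None

        if reason is None and index_visit is not None:
            age = index_visit.age_years
            if not (4.0 <= age < 19.0):
                reason = "b_age_out_of_range"
        if reason is None and (index_visit is None or np.isnan(index_visit.z)):
            reason = "c_no_index_z"
        if reason is None:
            zs = g["z"] if outlier_all_visits else pd.Series([index_visit.z])
            if ((zs >= 6) | (zs <= -6)).any():
                reason = "d_z_outlier"
        if reason is None and int(first_row.excluded_condition) == 1:
            reason = "e_condition"

        span = g[(g.visit_date >= hist_start) & (g.visit_date <= idx_end)]
        span = span.dropna(subset=["z"])
        if mode == "longitudinal":
            if reason is None and len(span) < 2:
                reason = "f_fewer_than_two_measures"
            if reason is None:
                gap_days = (index_visit.visit_date - span.iloc[0].visit_date).days
                if gap_days < 365:
                    reason = "g_followup_under_one_year"

        if reason is not None:
            log_rows.append({"child_id": child_id, "reason": reason})
            continue

        row = {
            "child_id": child_id,
            "sex": int(first_row.sex),
            "race_ethnicity": str(first_row.race_ethnicity),
            "x": float(first_row.x),
            "y": float(first_row.y),
            "tract_id": str(first_row.tract_id),
            "index_date": index_visit.visit_date,
            "age_years": float(index_visit.age_years),
            "bmi": float(index_visit.bmi),
            "outcome_z": float(index_visit.z),
        }
        if mode == "longitudinal":
            first_visit = span.iloc[0]
            row.update(
                first_date=first_visit.visit_date,
                first_age_years=float(first_visit.age_years),
                first_z=float(first_visit.z),
                delta_z=float(index_visit.z - first_visit.z),
                delta_age_years=float(
                    index_visit.age_years - first_visit.age_years
                ),
            )
        kept_rows.append(row)

    analysis = pd.DataFrame(kept_rows)
    log = pd.DataFrame(log_rows, columns=["child_id", "reason"])
    return analysis, log
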