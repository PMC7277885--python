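"""Per-day and per-patient cohort analyses.

A hospitalization record is expanded into one row per patient-day carrying
the care setting, the daily-maximum NEWS band, the current mICD level and
the derived ICC class.  On top of the day rows the module builds
contingency tables (counts, row percentages, Pearson chi-square), measures
how consistently patients are allocated to settings matching their care
complexity, and runs the nonparametric group comparisons (Shapiro-Wilk
normality screen, Kruskal-Wallis H).

Per-day statistics treat patient-days as independent units.  Days within
one hospitalization are of course correlated; the tabulations here are
descriptive of the allocation process, not inferential about patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingDataError, ValidationError
from .icc import IccMatrix, classify_icc, default_icc_matrix
from .micd import MicdAssessment, classify_dependence, score_micd
from .news import (
    BandTable,
    VitalSigns,
    classify_instability,
    default_band_table,
    score_news,
)

__all__ = [
    "ConsistencyReport",
    "CrossTab",
    "DEFAULT_EXPECTED_ICC",
    "OUTCOME_CATEGORIES",
    "PatientRecord",
    "SETTINGS",
    "WARDS",
    "apply_inclusion_filters",
    "consistency_analysis",
    "crosstab",
    "expand_to_days",
    "group_comparison",
    "per_patient_summary",
    "round_percent",
]

WARDS = ("internal_medicine", "neurology", "pneumology")
SETTINGS = ("sub_intensive", "high", "medium", "low")

OUTCOME_CATEGORIES = (
    "ordinary_discharge",
    "transfer_to_another_ward",
    "death",
    "re_entry",
    "other_institute",
    "hospice",
    "integrated_home_care",
    "transfer_to_higher_care",
    "transfer_to_lower_care",
)

ADMISSION_TYPES = ("inpatient", "day_hospital", "outpatient")
ADMISSION_SOURCES = ("direct", "external_transfer")

#: allocation hypothesis: the ICC class each care setting should host
DEFAULT_EXPECTED_ICC: dict[str, str] = {
    "sub_intensive": "High",
    "high": "High",
    "medium": "Medium",
    "low": "Low",
}

DAY_ROW_COLUMNS = (
    "patient_id",
    "date",
    "ward",
    "setting",
    "news_total_daily_max",
    "news_band",
    "micd_total_current",
    "micd_level",
    "icc_level",
)


def _as_date(value) -> date:
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"malformed date {value!r}") from exc


@dataclass
class PatientRecord:
    """One hospitalization with its setting, vitals and mICD timelines."""

    patient_id: str
    ward: str
    age: float
    gender: str
    admission_date: date
    discharge_date: date
    outcome: str
    setting_intervals: list[tuple[date, date, str]] = field(default_factory=list)
    vitals_series: list[VitalSigns] = field(default_factory=list)
    micd_series: list[MicdAssessment] = field(default_factory=list)
    admission_type: str = "inpatient"
    admission_source: str = "direct"
    drg_value: float | None = None

    @property
    def length_of_stay(self) -> int:
        """Patient-days contributed: admission inclusive, discharge exclusive;
        a same-day admission/discharge still counts as one day."""
        return max(1, (self.discharge_date - self.admission_date).days)

    @property
    def day_span_end(self) -> date:
        return self.admission_date + timedelta(days=self.length_of_stay)

    def validate(self) -> None:
        if self.ward not in WARDS:
            raise ValidationError(
                f"{self.patient_id}: unknown ward {self.ward!r}"
            )
        if self.outcome not in OUTCOME_CATEGORIES:
            raise ValidationError(
                f"{self.patient_id}: unknown outcome {self.outcome!r}"
            )
        if self.admission_type not in ADMISSION_TYPES:
            raise ValidationError(
                f"{self.patient_id}: unknown admission_type {self.admission_type!r}"
            )
        if self.admission_source not in ADMISSION_SOURCES:
            raise ValidationError(
                f"{self.patient_id}: unknown admission_source {self.admission_source!r}"
            )
        if self.admission_date > self.discharge_date:
            raise ValidationError(
                f"{self.patient_id}: admission after discharge"
            )
        self._validate_intervals()
        self._validate_assessments()

    def _validate_intervals(self) -> None:
        if not self.setting_intervals:
            raise ValidationError(f"{self.patient_id}: no setting intervals")
        ivs = sorted(self.setting_intervals, key=lambda iv: iv[0])
        if ivs[0][0] != self.admission_date:
            raise ValidationError(
                f"{self.patient_id}: first setting interval does not start at admission"
            )
        for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if e0 != s1:
                raise ValidationError(
                    f"{self.patient_id}: setting intervals have a gap or overlap at {e0}"
                )
        for s, e, setting in ivs:
            if setting not in SETTINGS:
                raise ValidationError(
                    f"{self.patient_id}: unknown setting {setting!r}"
                )
            if e <= s:
                raise ValidationError(
                    f"{self.patient_id}: empty setting interval at {s}"
                )
        if ivs[-1][1] != self.day_span_end:
            raise ValidationError(
                f"{self.patient_id}: setting intervals do not cover the stay"
            )
        self.setting_intervals = ivs

    def _validate_assessments(self) -> None:
        boundaries = {s for s, _, _ in self.setting_intervals}
        for a in self.micd_series:
            a.validate()
            if a.assessed_at is None:
                raise ValidationError(
                    f"{self.patient_id}: mICD assessment without a date"
                )
            if not self.admission_date <= a.assessed_at <= self.discharge_date:
                raise ValidationError(
                    f"{self.patient_id}: mICD assessed outside the stay"
                )
            if a.context == "setting_transfer" and a.assessed_at not in boundaries:
                raise ValidationError(
                    f"{self.patient_id}: transfer mICD at {a.assessed_at} "
                    "does not coincide with a setting change"
                )

    def setting_on(self, day: date) -> str:
        for s, e, setting in self.setting_intervals:
            if s <= day < e:
                return setting
        raise ValidationError(f"{self.patient_id}: no setting covers {day}")


def apply_inclusion_filters(
    records: Iterable[PatientRecord],
    window_start,
    window_end,
) -> tuple[list[PatientRecord], dict[str, int]]:
    """Apply the cohort inclusion rules and tally per-rule exclusions.

    Keeps records of inpatients present in the wards at any point inside
    ``[window_start, window_end]``; drops day-hospital and outpatient
    admissions and patients transferred in from outside the analyzed area.
    """
    window_start = _as_date(window_start)
    window_end = _as_date(window_end)
    kept: list[PatientRecord] = []
    exclusions = {
        "day_hospital": 0,
        "outpatient": 0,
        "external_transfer": 0,
        "outside_window": 0,
    }
    for rec in records:
        if rec.admission_type == "day_hospital":
            exclusions["day_hospital"] += 1
        elif rec.admission_type == "outpatient":
            exclusions["outpatient"] += 1
        elif rec.admission_source == "external_transfer":
            exclusions["external_transfer"] += 1
        elif rec.discharge_date < window_start or rec.admission_date > window_end:
            exclusions["outside_window"] += 1
        else:
            kept.append(rec)
    return kept, exclusions


def expand_to_days(
    records: Iterable[PatientRecord],
    bands: BandTable | None = None,
    matrix: IccMatrix | None = None,
    scheme: str = "text_bands",
    missing_vitals: str = "lenient",
) -> pd.DataFrame:
    """Expand hospitalizations into one row per patient per calendar day.

    ``news_total_daily_max`` is the maximum NEWS total over that day's
    observations; the mICD total is the most recent assessment at or before
    the day; the ICC class combines the two through the matrix.  Days with
    no vitals raise in ``strict`` mode and carry the previous day's score
    forward in ``lenient`` mode.
    """
    if missing_vitals not in ("strict", "lenient"):
        raise ValidationError("missing_vitals must be 'strict' or 'lenient'")
    if bands is None:
        bands = default_band_table()
    if matrix is None:
        matrix = default_icc_matrix()

    rows: list[dict] = []
    for rec in records:
        rec.validate()
        scored = {}
        for v in rec.vitals_series:
            day = _as_date(v.observed_at)
            total = score_news(v, bands).total
            scored.setdefault(day, []).append(total)
        assessments = sorted(rec.micd_series, key=lambda a: a.assessed_at)
        if not assessments:
            raise MissingDataError(f"{rec.patient_id}: no mICD assessments")
        carried: int | None = None
        for offset in range(rec.length_of_stay):
            day = rec.admission_date + timedelta(days=offset)
            if day in scored:
                news_total = max(scored[day])
                carried = news_total
            elif missing_vitals == "lenient" and carried is not None:
                news_total = carried
            else:
                raise MissingDataError(
                    f"{rec.patient_id}: no vitals on {day}"
                    + ("" if missing_vitals == "strict" else " and nothing to carry forward")
                )
            current = [a for a in assessments if a.assessed_at <= day]
            if not current:
                raise MissingDataError(
                    f"{rec.patient_id}: no mICD assessment at or before {day}"
                )
            micd = score_micd(current[-1], scheme)
            band = classify_instability(news_total, bands.band_cutpoints)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "date": day,
                    "ward": rec.ward,
                    "setting": rec.setting_on(day),
                    "news_total_daily_max": news_total,
                    "news_band": band,
                    "micd_total_current": micd.total,
                    "micd_level": micd.level,
                    "icc_level": classify_icc(band, micd.level, matrix),
                }
            )
    return pd.DataFrame(rows, columns=list(DAY_ROW_COLUMNS))


def round_percent(value: float) -> float:
    """Round a percentage half-up to one decimal, as the report tables print."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CrossTab:
    """Counts and row percentages of a factor pair, with a chi-square test."""

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    chi2_stat: float
    chi2_dof: int
    chi2_p: float

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def column_totals(self) -> tuple[pd.Series, pd.Series]:
        """The table's Total row: column counts and their share of all units."""
        totals = self.counts.sum(axis=0)
        pct = (totals / totals.sum() * 100).map(round_percent)
        return totals, pct

    def to_frame(self) -> pd.DataFrame:
        """Interleave N and % columns the way the printed tables do."""
        out = {}
        for col in self.counts.columns:
            out[f"{col}_n"] = self.counts[col]
            out[f"{col}_pct"] = self.row_percent[col]
        return pd.DataFrame(out, index=self.counts.index)


def crosstab(
    rows: pd.DataFrame,
    row_factor: str,
    col_factor: str,
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> CrossTab:
    """Cross-tabulate two categorical columns of the day or patient rows.

    Factor levels given in ``row_order``/``col_order`` are retained even at
    zero margin.  The attached chi-square is the Pearson statistic without
    continuity correction, computed on the non-empty rows and columns; a
    warning is logged when an expected cell count falls below 5.
    """
    if len(rows) == 0:
        raise ValidationError("cannot cross-tabulate an empty input")
    for factor in (row_factor, col_factor):
        if factor not in rows.columns:
            raise ValidationError(f"unknown factor column {factor!r}")
    r = rows[row_factor]
    c = rows[col_factor]
    if row_order is not None:
        r = pd.Categorical(r, categories=list(row_order))
    if col_order is not None:
        c = pd.Categorical(c, categories=list(col_order))
    counts = pd.crosstab(r, c, dropna=False)
    counts.index.name = row_factor
    counts.columns.name = col_factor
    if row_order is not None:
        counts = counts.reindex(list(row_order), fill_value=0)
    if col_order is not None:
        counts = counts.reindex(columns=list(col_order), fill_value=0)

    sums = counts.sum(axis=1)
    pct = counts.div(sums.replace(0, np.nan), axis=0).mul(100)
    pct = pct.fillna(0.0).map(round_percent)

    chi = counts.loc[sums > 0, counts.sum(axis=0) > 0]
    if chi.shape[0] > 1 and chi.shape[1] > 1:
        res = stats.chi2_contingency(chi.to_numpy(), correction=False)
        stat, p, dof, expected = res.statistic, res.pvalue, res.dof, res.expected_freq
        if (expected < 5).any():
            warnings.warn(
                "chi-square approximation: some expected cell counts < 5",
                stacklevel=2,
            )
    else:
        stat, p, dof = 0.0, 1.0, 0
    return CrossTab(
        counts=counts,
        row_percent=pct,
        chi2_stat=float(stat),
        chi2_dof=int(dof),
        chi2_p=float(p),
    )


@dataclass
class ConsistencyReport:
    """Share of patient-days allocated to the setting their ICC calls for."""

    per_setting: dict[str, tuple[int, int]]  # setting -> (consistent, total)
    overall: tuple[int, int]
    mapping: dict[str, str]

    def proportion(self, setting: str | None = None) -> float:
        num, den = self.overall if setting is None else self.per_setting[setting]
        return num / den if den else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for setting in self.mapping:
            num, den = self.per_setting.get(setting, (0, 0))
            rows.append(
                {
                    "setting": setting,
                    "expected_icc": self.mapping[setting],
                    "consistent_days": num,
                    "total_days": den,
                    "proportion": num / den if den else float("nan"),
                }
            )
        num, den = self.overall
        rows.append(
            {
                "setting": "overall",
                "expected_icc": "",
                "consistent_days": num,
                "total_days": den,
                "proportion": num / den if den else float("nan"),
            }
        )
        return pd.DataFrame(rows)


def consistency_analysis(
    day_rows: pd.DataFrame,
    mapping: Mapping[str, str] | None = None,
) -> ConsistencyReport:
    """Proportion of days whose ICC matches the setting's expected class."""
    mapping = dict(DEFAULT_EXPECTED_ICC if mapping is None else mapping)
    missing = set(SETTINGS) - set(mapping)
    if missing:
        raise ValidationError(f"consistency mapping missing settings: {sorted(missing)}")
    per_setting: dict[str, tuple[int, int]] = {}
    total_num = total_den = 0
    for setting, expected in mapping.items():
        sub = day_rows[day_rows["setting"] == setting]
        num = int((sub["icc_level"] == expected).sum())
        den = int(len(sub))
        per_setting[setting] = (num, den)
        total_num += num
        total_den += den
    return ConsistencyReport(
        per_setting=per_setting, overall=(total_num, total_den), mapping=mapping
    )


def per_patient_summary(
    records: Iterable[PatientRecord],
    bands: BandTable | None = None,
    matrix: IccMatrix | None = None,
    scheme: str = "text_bands",
) -> tuple[pd.DataFrame, list[str]]:
    """Admission-ICC level vs. external outcome indices, one row per level.

    The admission ICC combines the earliest admission-day NEWS with the
    admission mICD.  Records lacking either are returned in the second
    element and excluded from the table.
    """
    if bands is None:
        bands = default_band_table()
    if matrix is None:
        matrix = default_icc_matrix()
    rows = []
    excluded: list[str] = []
    for rec in records:
        admission_vitals = [
            v for v in rec.vitals_series if _as_date(v.observed_at) == rec.admission_date
        ]
        admission_micd = [a for a in rec.micd_series if a.context == "admission"]
        if not admission_vitals or not admission_micd:
            excluded.append(rec.patient_id)
            continue
        news = score_news(admission_vitals[0], bands)
        micd = score_micd(admission_micd[0], scheme)
        rows.append(
            {
                "icc_admission": classify_icc(news.band, micd.level, matrix),
                "death": rec.outcome == "death",
                "transfer_to_higher_care": rec.outcome == "transfer_to_higher_care",
                "los_days": rec.length_of_stay,
                "drg_value": rec.drg_value,
            }
        )
    if not rows:
        return (
            pd.DataFrame(
                columns=[
                    "n_patients",
                    "deaths",
                    "transfers_to_higher_care",
                    "mean_los_days",
                    "mean_drg_value",
                ]
            ),
            excluded,
        )
    df = pd.DataFrame(rows)
    df["icc_admission"] = pd.Categorical(
        df["icc_admission"], categories=["Low", "Medium", "High"]
    )
    grouped = df.groupby("icc_admission", observed=False)
    table = pd.DataFrame(
        {
            "n_patients": grouped.size(),
            "deaths": grouped["death"].sum().astype(int),
            "transfers_to_higher_care": grouped["transfer_to_higher_care"]
            .sum()
            .astype(int),
            "mean_los_days": grouped["los_days"].mean(),
            "mean_drg_value": grouped["drg_value"].mean(),
        }
    )
    table.index.name = "icc_admission"
    return table, excluded


def group_comparison(
    values: Sequence[float],
    group_labels: Sequence,
) -> dict:
    """Shapiro-Wilk per group plus the Kruskal-Wallis H test across groups.

    The Shapiro-Wilk approximation is accurate for 4 <= n <= 2000; outside
    that range a warning is issued and the statistic is still returned where
    computable.  Ties in H are handled by midranks with the tie correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if len(values) != len(labels):
        raise ValidationError("values and group_labels differ in length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    names = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("each group must be non-empty")

    shapiro: dict = {}
    for name, g in zip(names, groups):
        if not 4 <= len(g) <= 2000:
            warnings.warn(
                f"Shapiro-Wilk approximation is accurate for 4 <= n <= 2000; "
                f"group {name!r} has n={len(g)}",
                stacklevel=2,
            )
        if len(g) >= 3 and np.ptp(g) > 0:
            w, p = stats.shapiro(g)
            shapiro[name] = {"w": float(w), "p": float(p), "n": int(len(g))}
        else:
            shapiro[name] = {"w": float("nan"), "p": float("nan"), "n": int(len(g))}

    if np.ptp(np.concatenate(groups)) == 0:
        # no rank separation at all; scipy refuses identical data
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    return {
        "shapiro": shapiro,
        "kruskal_h": float(h),
        "kruskal_dof": len(groups) - 1,
        "kruskal_p": float(p),
    }
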