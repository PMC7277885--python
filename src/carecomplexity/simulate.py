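"""Seeded synthetic hospital cohorts with the study's statistical structure.

No patient-level records are publicly deposited for the cohort the package
analyzes, so this module generates stand-in cohorts whose printed marginals
it reproduces: ward sizes, gender/age/length-of-stay class mixes and care
setting allocation per ward, discharge outcomes per ward, and the per-setting
distributions of daily NEWS bands and mICD dependence levels.  The joint
distribution beyond those marginals is a modelling choice, not data.

Sampling is *latent-first*: each patient-day first draws its clinical
instability band and each setting interval its dependence level, and only
then are concrete vital signs and rubric dimension levels realized inside
the parameter regions that score back into that band.  Re-scoring generated
data through the scoring modules therefore reproduces the latent classes
exactly, which pins the generator to the scoring rules it feeds.

Two latent-severity modes exist:

* observational (``mismatch_rate=None``, the default configuration): band
  and level mixes are drawn per assigned setting from the configured
  tables, so allocation inconsistency appears at the observed rates;
* experimental (``mismatch_rate=m``): every day's complexity is drawn
  consistent with its assigned setting, then a fraction ``m`` of
  patient-days is re-assigned to a setting inconsistent with its ICC,
  uniformly among the inconsistent settings.  This gives a known ground
  truth (overall consistency ``1-m``) for validating the analysis.

A single root seed is split into four independent streams in a fixed order
(patients, days, vitals, dimensions) so extending one stage never shifts
the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_EXPECTED_ICC,
    OUTCOME_CATEGORIES,
    SETTINGS,
    WARDS,
    PatientRecord,
)
from .errors import ConfigError, InfeasibleConfigError
from .icc import IccMatrix, default_icc_matrix
from .micd import CUTPOINT_SCHEMES, DIMENSIONS, LEVEL_LABELS, MicdAssessment
from .news import BAND_LABELS, BandTable, Interval, VitalSigns, default_band_table

__all__ = [
    "AGE_CLASS_RANGES",
    "CohortConfig",
    "LOS_CLASS_RANGES",
    "default_paper_config",
    "generate_cohort",
    "repair_total_days",
]

#: age classes as tabulated, with the year ranges used for realization
AGE_CLASS_RANGES: dict[str, tuple[int, int]] = {
    "<60": (30, 59),
    "61-70": (61, 70),
    "71-80": (71, 80),
    "81-90": (81, 90),
    ">90": (91, 99),
}

#: length-of-stay classes as tabulated; the open class is capped at 30 days
LOS_CLASS_RANGES: dict[str, tuple[int, int]] = {
    "1-3": (1, 3),
    "4-9": (4, 9),
    "10-15": (10, 15),
    ">15": (16, 30),
}


def _check_probs(name: str, probs: Mapping[str, float], labels: Sequence[str]) -> None:
    unknown = set(probs) - set(labels)
    if unknown:
        raise ConfigError(f"{name}: unknown categories {sorted(unknown)}")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {total}, not 1")
    if any(p < 0 for p in probs.values()):
        raise ConfigError(f"{name}: negative probability")


@dataclass
class CohortConfig:
    """Everything the generator needs, per ward and per care setting."""

    n_patients: dict[str, int]
    total_patient_days: int | None
    setting_probs: dict[str, dict[str, float]]
    gender_probs: dict[str, dict[str, float]]
    age_class_weights: dict[str, dict[str, float]]
    los_class_weights: dict[str, dict[str, float]]
    outcome_probs: dict[str, dict[str, float]]
    news_band_probs: dict[str, dict[str, float]]
    micd_level_probs: dict[str, dict[str, float]]
    mismatch_rate: float | None = None
    transfer_prob: float = 0.10
    start_date: date = date(2020, 1, 15)
    window_days: int = 31
    cutpoint_scheme: str = "text_bands"
    drg_lognormal: tuple[float, float] = (8.1, 0.5)  # ~EUR 3300 median
    seed: int = 0

    def validate(self) -> None:
        for ward, n in self.n_patients.items():
            if ward not in WARDS:
                raise ConfigError(f"unknown ward {ward!r}")
            if n < 0:
                raise ConfigError(f"n_patients[{ward}] < 0")
        n_total = sum(self.n_patients.values())
        if self.total_patient_days is not None and self.total_patient_days < n_total:
            raise InfeasibleConfigError(
                f"total_patient_days={self.total_patient_days} < {n_total} patients"
            )
        for ward in self.n_patients:
            _check_probs(f"setting_probs[{ward}]", self.setting_probs[ward], SETTINGS)
            _check_probs(f"gender_probs[{ward}]", self.gender_probs[ward], ("M", "F"))
            _check_probs(
                f"age_class_weights[{ward}]",
                self.age_class_weights[ward],
                tuple(AGE_CLASS_RANGES),
            )
            _check_probs(
                f"los_class_weights[{ward}]",
                self.los_class_weights[ward],
                tuple(LOS_CLASS_RANGES),
            )
            _check_probs(
                f"outcome_probs[{ward}]", self.outcome_probs[ward], OUTCOME_CATEGORIES
            )
        for setting in SETTINGS:
            _check_probs(
                f"news_band_probs[{setting}]", self.news_band_probs[setting], BAND_LABELS
            )
            _check_probs(
                f"micd_level_probs[{setting}]",
                self.micd_level_probs[setting],
                LEVEL_LABELS,
            )
        if self.mismatch_rate is not None and not 0 <= self.mismatch_rate <= 1:
            raise ConfigError(f"mismatch_rate={self.mismatch_rate} outside [0, 1]")
        if self.cutpoint_scheme not in CUTPOINT_SCHEMES:
            raise ConfigError(f"unknown cutpoint scheme {self.cutpoint_scheme!r}")


def default_paper_config(seed: int = 0) -> CohortConfig:
    """The configuration calibrated to the study cohort's printed tables.

    450 patients (internal medicine 349, neurology 39, pneumology 62) over
    exactly 2884 patient-days; setting, gender, age-class, stay-length and
    outcome mixes per ward; daily NEWS-band and mICD-level mixes per care
    setting, all proportional to the published contingency-table counts.
    """

    def norm(counts: Mapping[str, float]) -> dict[str, float]:
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}

    setting_counts = {
        "internal_medicine": {"sub_intensive": 11, "high": 10, "medium": 280, "low": 48},
        "neurology": {"sub_intensive": 1, "high": 5, "medium": 33, "low": 0},
        "pneumology": {"sub_intensive": 5, "high": 8, "medium": 49, "low": 0},
    }
    gender_counts = {
        "internal_medicine": {"M": 173, "F": 176},
        "neurology": {"M": 13, "F": 26},
        "pneumology": {"M": 30, "F": 32},
    }
    age_counts = {
        "internal_medicine": {"<60": 24, "61-70": 41, "71-80": 81, "81-90": 139, ">90": 64},
        "neurology": {"<60": 9, "61-70": 6, "71-80": 13, "81-90": 10, ">90": 1},
        "pneumology": {"<60": 6, "61-70": 6, "71-80": 29, "81-90": 15, ">90": 6},
    }
    los_counts = {
        "internal_medicine": {"1-3": 75, "4-9": 194, "10-15": 62, ">15": 18},
        "neurology": {"1-3": 0, "4-9": 24, "10-15": 6, ">15": 9},
        "pneumology": {"1-3": 14, "4-9": 39, "10-15": 7, ">15": 2},
    }
    outcome_counts = {
        "internal_medicine": {
            "ordinary_discharge": 239,
            "transfer_to_another_ward": 7,
            "death": 40,
            "re_entry": 0,
            "other_institute": 6,
            "hospice": 2,
            "integrated_home_care": 3,
            "transfer_to_higher_care": 11,
            "transfer_to_lower_care": 41,
        },
        "neurology": {
            "ordinary_discharge": 28,
            "transfer_to_another_ward": 2,
            "death": 0,
            "re_entry": 0,
            "other_institute": 4,
            "hospice": 2,
            "integrated_home_care": 0,
            "transfer_to_higher_care": 0,
            "transfer_to_lower_care": 3,
        },
        "pneumology": {
            "ordinary_discharge": 50,
            "transfer_to_another_ward": 1,
            "death": 1,
            "re_entry": 0,
            "other_institute": 0,
            "hospice": 1,
            "integrated_home_care": 0,
            "transfer_to_higher_care": 2,
            "transfer_to_lower_care": 7,
        },
    }
    # daily clinical-instability mix per setting
    band_counts = {
        "sub_intensive": {"stable": 31, "unstable": 35, "critical": 13},
        "high": {"stable": 123, "unstable": 55, "critical": 7},
        "medium": {"stable": 1888, "unstable": 269, "critical": 140},
        "low": {"stable": 205, "unstable": 67, "critical": 55},
    }
    # care-dependence mix per setting
    level_counts = {
        "sub_intensive": {"low": 30, "average": 44, "high": 5},
        "high": {"low": 59, "average": 117, "high": 9},
        "medium": {"low": 1289, "average": 855, "high": 153},
        "low": {"low": 58, "average": 182, "high": 83},
    }
    return CohortConfig(
        n_patients={"internal_medicine": 349, "neurology": 39, "pneumology": 62},
        total_patient_days=2884,
        setting_probs={w: norm(c) for w, c in setting_counts.items()},
        gender_probs={w: norm(c) for w, c in gender_counts.items()},
        age_class_weights={w: norm(c) for w, c in age_counts.items()},
        los_class_weights={w: norm(c) for w, c in los_counts.items()},
        outcome_probs={w: norm(c) for w, c in outcome_counts.items()},
        news_band_probs={s: norm(c) for s, c in band_counts.items()},
        micd_level_probs={s: norm(c) for s, c in level_counts.items()},
        seed=seed,
    )


def repair_total_days(
    sampled_los: Sequence[int],
    target: int,
    rng: np.random.Generator | int | None = 0,
) -> list[int]:
    """Minimally perturb a length-of-stay vector so it sums to ``target``.

    Random entries are incremented (or decremented, never below one day)
    one day at a time until the sum matches; the class structure is only
    approximately preserved.  Deterministic for a given generator state.
    """
    los = [int(x) for x in sampled_los]
    if any(x < 1 for x in los):
        raise InfeasibleConfigError("lengths of stay must be >= 1")
    if target < len(los):
        raise InfeasibleConfigError(
            f"target {target} infeasible for {len(los)} patients (minimum 1 day each)"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    diff = target - sum(los)
    while diff > 0:
        los[int(rng.integers(len(los)))] += 1
        diff -= 1
    while diff < 0:
        i = int(rng.integers(len(los)))
        if los[i] > 1:
            los[i] -= 1
            diff += 1
    return los


def _choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


def _split_total(
    rng: np.random.Generator, total: int, n_parts: int, low: int, high: int
) -> list[int]:
    """Distribute ``total`` over ``n_parts`` values each in [low, high]."""
    parts: list[int] = []
    remaining = total
    for k in range(n_parts, 0, -1):
        lo = max(low, remaining - high * (k - 1))
        hi = min(high, remaining - low * (k - 1))
        value = int(rng.integers(lo, hi + 1))
        parts.append(value)
        remaining -= value
    return parts


# -------------------------------------------------------------------------
# realization of concrete observations inside a latent class

_BAND_TOTAL_RANGE = {"stable": (0, 4), "unstable": (5, 6), "critical": (7, 12)}


def _realize_vitals(
    rng: np.random.Generator, band: str, bands: BandTable, day: date
) -> VitalSigns:
    lo, hi = _BAND_TOTAL_RANGE[band]
    total = int(rng.integers(lo, hi + 1))
    # AVPU contributes 0 or 3, oxygen 0 or 2; the five interval-scored
    # parameters are contiguous 0..3 and absorb any remainder
    numeric = list(bands.parameters)
    max_numeric = 3 * len(numeric)
    avpu_options = [s for s in (0, 3) if 0 <= total - s <= 2 + max_numeric]
    weights = {0: 0.9, 3: 0.1}
    probs = np.array([weights[s] for s in avpu_options], dtype=float)
    avpu_score = avpu_options[rng.choice(len(avpu_options), p=probs / probs.sum())]
    remaining = total - avpu_score
    o2_options = [
        s for s in sorted({0, bands.oxygen_score}) if 0 <= remaining - s <= max_numeric
    ]
    o2_weights = {0: 0.65, bands.oxygen_score: 0.35}
    probs = np.array([o2_weights[s] for s in o2_options], dtype=float)
    o2_score = o2_options[rng.choice(len(o2_options), p=probs / probs.sum())]
    remaining -= o2_score

    order = list(numeric)
    rng.shuffle(order)
    scores = dict(zip(order, _split_total(rng, remaining, len(order), 0, 3)))

    values: dict[str, float] = {}
    for name, score in scores.items():
        candidates = [iv for iv in bands.parameters[name] if iv.score == score]
        iv: Interval = candidates[int(rng.integers(len(candidates)))]
        s_lo, s_hi = bands.sanity_bounds[name]
        lo_v = s_lo if iv.min is None else max(iv.min, s_lo)
        hi_v = s_hi if iv.max is None else min(iv.max, s_hi)
        if name == "temperature":
            values[name] = int(rng.integers(round(lo_v * 10), round(hi_v * 10) + 1)) / 10
        else:
            values[name] = int(rng.integers(lo_v, hi_v + 1))
    avpu = (
        "Alert"
        if avpu_score == 0
        else ("Verbal", "Pain", "Unresponsive")[int(rng.integers(3))]
    )
    return VitalSigns(
        respiration_rate=int(values["respiration_rate"]),
        spo2=int(values["spo2"]),
        supplemental_oxygen=o2_score > 0,
        temperature=float(values["temperature"]),
        systolic_bp=int(values["systolic_bp"]),
        heart_rate=int(values["heart_rate"]),
        avpu=avpu,
        observed_at=day,
    )


def _realize_micd(
    rng: np.random.Generator,
    level: str,
    scheme: str,
    day: date,
    context: str,
) -> MicdAssessment:
    low_max, avg_max = CUTPOINT_SCHEMES[scheme]
    ranges = {"low": (8, low_max), "average": (low_max + 1, avg_max), "high": (avg_max + 1, 32)}
    lo, hi = ranges[level]
    total = int(rng.integers(lo, hi + 1))
    dims = _split_total(rng, total, len(DIMENSIONS), 1, 4)
    order = list(DIMENSIONS)
    rng.shuffle(order)
    return MicdAssessment(
        **dict(zip(order, dims)), assessed_at=day, context=context
    )


def _inconsistent_settings(icc: str, mapping: Mapping[str, str]) -> list[str]:
    return [s for s in SETTINGS if mapping[s] != icc]


def _consistent_cells(icc: str, matrix: IccMatrix) -> list[tuple[str, str]]:
    return [cell for cell, value in sorted(matrix.cells.items()) if value == icc]


def generate_cohort(
    config: CohortConfig,
    seed: int | None = None,
    return_latent: bool = False,
):
    """Generate one synthetic cohort of :class:`PatientRecord`.

    With ``return_latent=True`` also returns a data frame with the latent
    per-day NEWS band and mICD level each day was sampled from, for
    round-trip validation against the scoring modules.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_patients, rng_days, rng_vitals, rng_dims = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    bands = default_band_table()
    matrix = default_icc_matrix()
    scheme = config.cutpoint_scheme
    mismatch = config.mismatch_rate

    wards = sorted(config.n_patients)
    patients: list[dict] = []
    for ward in wards:
        for i in range(config.n_patients[ward]):
            age_class = _choice(rng_patients, config.age_class_weights[ward])
            los_class = _choice(rng_patients, config.los_class_weights[ward])
            a_lo, a_hi = AGE_CLASS_RANGES[age_class]
            l_lo, l_hi = LOS_CLASS_RANGES[los_class]
            mu, sigma = config.drg_lognormal
            patients.append(
                {
                    "patient_id": f"{ward[:2].upper()}-{i + 1:04d}",
                    "ward": ward,
                    "gender": _choice(rng_patients, config.gender_probs[ward]),
                    "age": int(rng_patients.integers(a_lo, a_hi + 1)),
                    "los": int(rng_patients.integers(l_lo, l_hi + 1)),
                    "outcome": _choice(rng_patients, config.outcome_probs[ward]),
                    "base_setting": _choice(rng_patients, config.setting_probs[ward]),
                    "admission_offset": int(rng_patients.integers(config.window_days)),
                    "drg_value": round(float(rng_patients.lognormal(mu, sigma)), 2),
                }
            )

    if config.total_patient_days is not None:
        repaired = repair_total_days(
            [p["los"] for p in patients], config.total_patient_days, rng_days
        )
        for p, los in zip(patients, repaired):
            p["los"] = los

    records: list[PatientRecord] = []
    latent_rows: list[dict] = []
    for p in patients:
        admission = config.start_date + timedelta(days=p["admission_offset"])
        los = p["los"]
        days = [admission + timedelta(days=k) for k in range(los)]

        if mismatch is None:
            # observational mode: setting first, severity mixes conditional on it
            day_settings = [p["base_setting"]] * los
            if los >= 2 and rng_days.random() < config.transfer_prob:
                others = [
                    s
                    for s in SETTINGS
                    if s != p["base_setting"] and config.setting_probs[p["ward"]][s] > 0
                ]
                if others:
                    cut = int(rng_days.integers(1, los))
                    new = others[int(rng_days.integers(len(others)))]
                    day_settings[cut:] = [new] * (los - cut)
            # mICD level is drawn once per setting interval, bands per day
            day_levels: list[str] = []
            day_bands: list[str] = []
            current_setting = None
            level = None
            for s in day_settings:
                if s != current_setting:
                    level = _choice(rng_days, config.micd_level_probs[s])
                    current_setting = s
                day_levels.append(level)
                day_bands.append(_choice(rng_days, config.news_band_probs[s]))
        else:
            # experimental mode: draw complexity consistent with the base
            # setting, then displace a fraction m of days
            expected = DEFAULT_EXPECTED_ICC[p["base_setting"]]
            cells = _consistent_cells(expected, matrix)
            band, level = cells[int(rng_days.integers(len(cells)))]
            day_bands = [band] * los
            day_levels = [level] * los
            day_settings = []
            for _ in range(los):
                if rng_days.random() < mismatch:
                    options = _inconsistent_settings(expected, DEFAULT_EXPECTED_ICC)
                    day_settings.append(options[int(rng_days.integers(len(options)))])
                else:
                    day_settings.append(p["base_setting"])

        # collapse per-day settings into contiguous intervals
        intervals: list[tuple[date, date, str]] = []
        for day, s in zip(days, day_settings):
            if intervals and intervals[-1][2] == s:
                intervals[-1] = (intervals[-1][0], day + timedelta(days=1), s)
            else:
                intervals.append((day, day + timedelta(days=1), s))

        vitals = [
            _realize_vitals(rng_vitals, band, bands, day)
            for day, band in zip(days, day_bands)
        ]
        micd_series: list[MicdAssessment] = []
        for k, (start, _, _) in enumerate(intervals):
            level_at = day_levels[(start - admission).days]
            micd_series.append(
                _realize_micd(
                    rng_dims,
                    level_at,
                    scheme,
                    start,
                    "admission" if k == 0 else "setting_transfer",
                )
            )
        rec = PatientRecord(
            patient_id=p["patient_id"],
            ward=p["ward"],
            age=p["age"],
            gender=p["gender"],
            admission_date=admission,
            discharge_date=admission + timedelta(days=los),
            outcome=p["outcome"],
            setting_intervals=intervals,
            vitals_series=vitals,
            micd_series=micd_series,
            drg_value=p["drg_value"],
        )
        rec.validate()
        records.append(rec)
        if return_latent:
            for day, s, b, lv in zip(days, day_settings, day_bands, day_levels):
                latent_rows.append(
                    {
                        "patient_id": p["patient_id"],
                        "date": day,
                        "setting": s,
                        "news_band": b,
                        "micd_level": lv,
                    }
                )
    if return_latent:
        return records, pd.DataFrame(latent_rows)
    return records
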