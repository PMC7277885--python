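from datetime import date, timedelta

import pandas as pd
import pytest

from carecomplexity.cohort import PatientRecord
from carecomplexity.micd import MicdAssessment
from carecomplexity.news import VitalSigns


def calm_vitals(day, **overrides):
    """Vitals scoring 0 on every NEWS component unless overridden."""
    fields = dict(
        respiration_rate=16,
        spo2=98,
        supplemental_oxygen=False,
        temperature=37.0,
        systolic_bp=120,
        heart_rate=70,
        avpu="Alert",
        observed_at=day,
    )
    fields.update(overrides)
    return VitalSigns(**fields)


def flat_micd(day, level=1, context="admission"):
    """All eight dimensions at the same level."""
    dims = dict(
        nutrition_hydration=level,
        elimination=level,
        hygiene_comfort=level,
        mobilization=level,
        diagnostic_procedures=level,
        therapeutic_procedures=level,
        sensory_perception=level,
        skin_integrity=level,
    )
    return MicdAssessment(**dims, assessed_at=day, context=context)


def make_record(
    patient_id="P1",
    ward="internal_medicine",
    admission=date(2020, 1, 20),
    los=3,
    setting="medium",
    outcome="ordinary_discharge",
    **kwargs,
):
    """A minimal valid record: one setting, calm daily vitals, level-1 mICD."""
    discharge = admission + timedelta(days=los)
    defaults = dict(
        setting_intervals=[(admission, discharge, setting)],
        vitals_series=[
            calm_vitals(admission + timedelta(days=k)) for k in range(los)
        ],
        micd_series=[flat_micd(admission)],
    )
    defaults.update(kwargs)
    return PatientRecord(
        patient_id=patient_id,
        ward=ward,
        age=75,
        gender="F",
        admission_date=admission,
        discharge_date=discharge,
        outcome=outcome,
        **defaults,
    )


# Printed per-setting, per-day contingency counts from the published study:
# clinical-instability bands and care-dependence levels by care setting.
INSTABILITY_BY_SETTING = {
    "sub_intensive": {"stable": 31, "unstable": 35, "critical": 13},
    "high": {"stable": 123, "unstable": 55, "critical": 7},
    "medium": {"stable": 1888, "unstable": 269, "critical": 140},
    "low": {"stable": 205, "unstable": 67, "critical": 55},
}
DEPENDENCE_BY_SETTING = {
    "sub_intensive": {"low": 30, "average": 44, "high": 5},
    "high": {"low": 59, "average": 117, "high": 9},
    "medium": {"low": 1289, "average": 855, "high": 153},
    "low": {"low": 58, "average": 182, "high": 83},
}


def counts_to_rows(table, col_name):
    """Replicate a {setting: {category: count}} table into unit rows."""
    rows = [
        {"setting": setting, col_name: category}
        for setting, cats in table.items()
        for category, count in cats.items()
        for _ in range(count)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def instability_day_rows():
    return counts_to_rows(INSTABILITY_BY_SETTING, "news_band")


@pytest.fixture
def dependence_day_rows():
    return counts_to_rows(DEPENDENCE_BY_SETTING, "micd_level")
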