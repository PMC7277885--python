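from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from carecomplexity.cohort import (
    apply_inclusion_filters,
    consistency_analysis,
    crosstab,
    expand_to_days,
    group_comparison,
    per_patient_summary,
    round_percent,
)
from carecomplexity.errors import MissingDataError, ValidationError

from conftest import calm_vitals, flat_micd, make_record

ADM = date(2020, 1, 20)


# ---------------------------------------------------------------- inclusion


def test_inclusion_filters_drop_day_hospital_and_external_transfers():
    records = [
        make_record("A"),
        make_record("B"),
        make_record("C"),
        make_record("D", admission_type="day_hospital"),
        make_record("E", admission_source="external_transfer"),
    ]
    kept, exclusions = apply_inclusion_filters(records, "2020-01-15", "2020-02-15")
    assert [r.patient_id for r in kept] == ["A", "B", "C"]
    assert exclusions == {
        "day_hospital": 1,
        "outpatient": 0,
        "external_transfer": 1,
        "outside_window": 0,
    }


def test_inclusion_filters_empty_input():
    kept, exclusions = apply_inclusion_filters([], "2020-01-15", "2020-02-15")
    assert kept == []
    assert all(v == 0 for v in exclusions.values())


def test_record_discharged_before_window_is_excluded():
    early = make_record("A", admission=date(2019, 12, 1), los=3)
    kept, exclusions = apply_inclusion_filters([early], "2020-01-15", "2020-02-15")
    assert kept == []
    assert exclusions["outside_window"] == 1


# ------------------------------------------------------------- day expansion


def test_three_day_stay_expands_to_three_rows_same_setting():
    days = expand_to_days([make_record(los=3, setting="medium")])
    assert len(days) == 3
    assert set(days["setting"]) == {"medium"}
    assert list(days["date"]) == [ADM + timedelta(days=k) for k in range(3)]


def test_transfer_switches_setting_and_micd_from_day_two():
    """Hand-traced timeline: medium for day 1, low with a new mICD after."""
    transfer_day = ADM + timedelta(days=1)
    end = ADM + timedelta(days=3)
    rec = make_record(
        los=3,
        setting_intervals=[(ADM, transfer_day, "medium"), (transfer_day, end, "low")],
        vitals_series=[calm_vitals(ADM + timedelta(days=k)) for k in range(3)],
        micd_series=[
            flat_micd(ADM, level=1),
            flat_micd(transfer_day, level=3, context="setting_transfer"),
        ],
    )
    days = expand_to_days([rec])
    assert list(days["setting"]) == ["medium", "low", "low"]
    assert list(days["micd_level"]) == ["low", "high", "high"]
    assert list(days["micd_total_current"]) == [8, 24, 24]


def test_daily_max_over_multiple_observations():
    """Two observations totalling 3 and 6 make the day unstable."""
    rec = make_record(
        los=1,
        vitals_series=[
            calm_vitals(ADM, respiration_rate=25),  # total 3
            calm_vitals(ADM, respiration_rate=22, spo2=95, heart_rate=95,
                        systolic_bp=105, temperature=38.5),  # 2+1+1+1+1 = 6
        ],
    )
    days = expand_to_days([rec])
    assert days.loc[0, "news_total_daily_max"] == max(3, 6)
    assert days.loc[0, "news_band"] == "unstable"


def test_missing_day_carried_forward_in_lenient_mode_only():
    rec = make_record(los=3, vitals_series=[calm_vitals(ADM, respiration_rate=25)])
    days = expand_to_days([rec], missing_vitals="lenient")
    assert list(days["news_total_daily_max"]) == [3, 3, 3]
    with pytest.raises(MissingDataError, match="no vitals"):
        expand_to_days([rec], missing_vitals="strict")


def test_patient_days_are_conserved():
    records = [make_record(f"P{k}", los=k + 1) for k in range(5)]
    days = expand_to_days(records)
    assert len(days) == sum(r.length_of_stay for r in records)


def test_interval_gap_is_rejected():
    end = ADM + timedelta(days=3)
    rec = make_record(
        los=3,
        setting_intervals=[
            (ADM, ADM + timedelta(days=1), "medium"),
            (ADM + timedelta(days=2), end, "low"),  # 1-day gap
        ],
    )
    with pytest.raises(ValidationError, match="gap"):
        expand_to_days([rec])


# ------------------------------------------------------------------ crosstab


def test_crosstab_reproduces_printed_low_care_critical_percent(instability_day_rows):
    """Low-care critical days: 55 of 327 -> 16.8%."""
    tab = crosstab(
        instability_day_rows,
        "setting",
        "news_band",
        ["sub_intensive", "high", "medium", "low"],
        ["stable", "unstable", "critical"],
    )
    assert tab.counts.loc["low", "critical"] == 55
    assert tab.row_percent.loc["low", "critical"] == 16.8
    assert tab.n == len(instability_day_rows)


def test_crosstab_reproduces_printed_dependence_totals(dependence_day_rows):
    """Dependence-level day totals 1436/1198/250 -> 49.8/41.5/8.7%."""
    tab = crosstab(
        dependence_day_rows,
        "setting",
        "micd_level",
        ["sub_intensive", "high", "medium", "low"],
        ["low", "average", "high"],
    )
    totals, pct = tab.column_totals()
    assert list(totals) == [1436, 1198, 250]
    assert list(pct) == [49.8, 41.5, 8.7]


def test_row_percentages_sum_to_100(instability_day_rows):
    tab = crosstab(instability_day_rows, "setting", "news_band")
    assert (abs(tab.row_percent.sum(axis=1) - 100) <= 0.1).all()


def test_single_cell_table_is_100_percent():
    rows = pd.DataFrame({"a": ["x"] * 7, "b": ["y"] * 7})
    tab = crosstab(rows, "a", "b")
    assert tab.row_percent.iloc[0, 0] == 100.0
    assert tab.chi2_stat == 0.0


def test_zero_margin_level_is_retained():
    rows = pd.DataFrame({"a": ["x", "x"], "b": ["y", "z"]})
    tab = crosstab(rows, "a", "b", row_order=["x", "w"], col_order=["y", "z"])
    assert tab.counts.loc["w"].sum() == 0


def test_proportional_rows_give_zero_chi2():
    rows = pd.DataFrame(
        {"a": ["x"] * 4 + ["y"] * 8, "b": (["p", "q"] * 2) + (["p", "q"] * 4)}
    )
    tab = crosstab(rows, "a", "b")
    assert tab.chi2_stat == pytest.approx(0.0, abs=1e-12)


def test_chi2_matches_hand_computed_2x2():
    """Pearson X2 = N(ad-bc)^2 / (r1 r2 c1 c2) = 60*300^2/30^4 = 20/3."""
    rows = pd.DataFrame(
        {
            "a": ["x"] * 30 + ["y"] * 30,
            "b": ["p"] * 10 + ["q"] * 20 + ["p"] * 20 + ["q"] * 10,
        }
    )
    tab = crosstab(rows, "a", "b")
    assert tab.chi2_stat == pytest.approx(20 / 3, rel=1e-12)
    assert tab.chi2_dof == 1


def test_empty_input_rejected():
    with pytest.raises(ValidationError, match="empty"):
        crosstab(pd.DataFrame(columns=["a", "b"]), "a", "b")


def test_round_percent_is_half_up():
    assert round_percent(16.85) == 16.9
    assert round_percent(8.6699) == 8.7


# --------------------------------------------------------------- consistency


def toy_day_rows(pairs):
    return pd.DataFrame(pairs, columns=["setting", "icc_level"])


def test_consistency_matches_hand_count():
    """10 hand-built day rows: 6 of 10 sit in the setting their ICC calls for."""
    rows = toy_day_rows(
        [
            ("low", "Low"),            # consistent
            ("low", "High"),           # roof effect
            ("low", "Low"),            # consistent
            ("medium", "Medium"),      # consistent
            ("medium", "Low"),         # floor effect
            ("medium", "Medium"),      # consistent
            ("high", "High"),          # consistent
            ("high", "Low"),           # floor effect
            ("sub_intensive", "High"), # consistent
            ("sub_intensive", "Medium"),
        ]
    )
    report = consistency_analysis(rows)
    assert report.overall == (6, 10)
    assert report.per_setting["low"] == (2, 3)
    assert report.per_setting["medium"] == (2, 3)
    assert report.proportion() == pytest.approx(0.6)


def test_all_high_icc_in_low_care_scores_zero():
    rows = toy_day_rows([("low", "High")] * 5)
    report = consistency_analysis(rows)
    assert report.proportion("low") == 0.0


# ----------------------------------------------------------- per-patient view


def test_per_patient_summary_matches_hand_tally():
    """Six patients: deaths and upward transfers land in the right ICC rows."""
    def admitted(pid, micd_level, outcome, los=2):
        return make_record(
            pid,
            los=los,
            outcome=outcome,
            micd_series=[flat_micd(ADM, level=micd_level)],
        )

    records = [
        admitted("A", 1, "death"),                      # ICC Low
        admitted("B", 1, "ordinary_discharge"),         # ICC Low
        admitted("C", 2, "death"),                      # level avg -> ICC Medium
        admitted("D", 2, "transfer_to_higher_care"),    # ICC Medium
        admitted("E", 3, "death", los=4),               # level high -> ICC High
        admitted("F", 3, "ordinary_discharge", los=6),  # ICC High
    ]
    table, excluded = per_patient_summary(records)
    assert excluded == []
    assert table.loc["Low", "n_patients"] == 2
    assert table.loc["Low", "deaths"] == 1
    assert table.loc["Medium", "deaths"] == 1
    assert table.loc["Medium", "transfers_to_higher_care"] == 1
    assert table.loc["High", "deaths"] == 1
    assert table.loc["High", "mean_los_days"] == pytest.approx(5.0)


def test_single_patient_summary():
    table, excluded = per_patient_summary([make_record("A", los=4)])
    assert excluded == []
    assert table["n_patients"].sum() == 1
    assert table.loc["Low", "mean_los_days"] == pytest.approx(4.0)


def test_record_without_admission_assessment_is_flagged():
    rec = make_record("A", micd_series=[flat_micd(ADM, context="admission")])
    broken = make_record("B")
    broken.vitals_series = [calm_vitals(ADM + timedelta(days=1))]  # none on admission
    table, excluded = per_patient_summary([rec, broken])
    assert excluded == ["B"]
    assert table["n_patients"].sum() == 1


# ----------------------------------------------------------- group comparison


def test_identical_groups_give_zero_h():
    values = [5.0] * 9
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    result = group_comparison(values, labels)
    assert result["kruskal_h"] == 0.0


def test_kruskal_matches_textbook_hand_value():
    """Groups {1,2,3},{4,5,6},{7,8,9}: H = 12/(9*10) * 3*((2-5)^2+(5-5)^2+(8-5)^2)... = 7.2."""
    values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    result = group_comparison(values, labels)
    assert result["kruskal_h"] == pytest.approx(7.2, rel=1e-12)
    assert result["kruskal_dof"] == 2


def test_shapiro_rejects_uniform_at_study_scale():
    """Uniform draws at n=450 are flagged non-normal in most seeded replicates."""
    rng = np.random.default_rng(12345)
    rejections = 0
    for _ in range(10):
        result = group_comparison(
            np.concatenate([rng.uniform(0, 100, 450), rng.uniform(0, 100, 10)]),
            ["g"] * 450 + ["h"] * 10,
        )
        if result["shapiro"]["g"]["p"] < 0.05:
            rejections += 1
    assert rejections >= 8


def test_small_group_warns_but_returns():
    with pytest.warns(UserWarning, match="4 <= n <= 2000"):
        result = group_comparison([1, 2, 3, 4, 5], ["a", "a", "a", "b", "b"])
    assert np.isfinite(result["kruskal_h"])


def test_group_comparison_input_validation():
    with pytest.raises(ValidationError):
        group_comparison([1, 2, 3], ["a", "a", "a"])
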