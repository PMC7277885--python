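import dataclasses
from datetime import date

import numpy as np
import pandas as pd
import pytest

from carecomplexity.cohort import SETTINGS, consistency_analysis, expand_to_days
from carecomplexity.errors import InfeasibleConfigError
from carecomplexity.micd import score_micd
from carecomplexity.news import score_news
from carecomplexity.simulate import (
    default_paper_config,
    generate_cohort,
    repair_total_days,
)


def small_config(seed=0, **overrides):
    """A scaled-down configuration for fast structural tests."""
    cfg = default_paper_config(seed=seed)
    changes = dict(
        n_patients={"internal_medicine": 20, "neurology": 5, "pneumology": 5},
        total_patient_days=200,
    )
    changes.update(overrides)
    return dataclasses.replace(cfg, **changes)


# --------------------------------------------------------------- configuration


def test_default_config_matches_study_structure():
    cfg = default_paper_config()
    assert cfg.n_patients == {
        "internal_medicine": 349,
        "neurology": 39,
        "pneumology": 62,
    }
    assert sum(cfg.n_patients.values()) == 450
    assert cfg.total_patient_days == 2884
    assert cfg.setting_probs["neurology"]["low"] == 0
    assert cfg.setting_probs["pneumology"]["low"] == 0
    cfg.validate()


def test_infeasible_day_total_rejected():
    cfg = small_config(total_patient_days=10)  # fewer days than patients
    with pytest.raises(InfeasibleConfigError):
        generate_cohort(cfg)


# ------------------------------------------------------------------ repair


def test_repair_identity_when_sum_matches():
    assert repair_total_days([3, 3, 4], 10) == [3, 3, 4]


def test_repair_increments_to_target():
    repaired = repair_total_days([3, 3, 3], 10, rng=1)
    assert sum(repaired) == 10
    assert min(repaired) >= 1
    assert sorted(np.subtract(repaired, [3, 3, 3])) == [0, 0, 1]


def test_repair_decrements_without_going_below_one():
    repaired = repair_total_days([1, 1, 8], 6, rng=2)
    assert sum(repaired) == 6
    assert min(repaired) >= 1


def test_repair_infeasible_target():
    with pytest.raises(InfeasibleConfigError):
        repair_total_days([2, 2], 1)


# ---------------------------------------------------------------- generation


def test_default_cohort_reproduces_ward_sizes_and_day_total():
    records = generate_cohort(default_paper_config(seed=11))
    by_ward = pd.Series([r.ward for r in records]).value_counts()
    assert by_ward["internal_medicine"] == 349
    assert by_ward["neurology"] == 39
    assert by_ward["pneumology"] == 62
    assert sum(r.length_of_stay for r in records) == 2884


def test_generated_records_pass_validation_and_expand():
    records = generate_cohort(small_config(seed=3))
    for rec in records:
        rec.validate()
    days = expand_to_days(records)
    assert len(days) == 200


def test_seeded_runs_are_bit_reproducible():
    cfg = small_config(seed=9)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert a == b


def test_different_seeds_differ():
    assert generate_cohort(small_config(seed=1)) != generate_cohort(small_config(seed=2))


def test_single_patient_single_setting_expands_to_los_days():
    cfg = dataclasses.replace(
        small_config(),
        n_patients={"internal_medicine": 1, "neurology": 0, "pneumology": 0},
        total_patient_days=5,
        transfer_prob=0.0,
    )
    records = generate_cohort(cfg, seed=4)
    assert len(records) == 1
    assert len(records[0].setting_intervals) == 1
    days = expand_to_days(records)
    assert len(days) == 5


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_vitals_round_trip_to_their_latent_band(seed):
    """Every generated observation re-scores into the band it was drawn for."""
    records, latent = generate_cohort(small_config(seed=seed), return_latent=True)
    latent_band = {
        (row.patient_id, row.date): row.news_band for row in latent.itertuples()
    }
    checked = 0
    for rec in records:
        for v in rec.vitals_series:
            band = score_news(v).band
            assert band == latent_band[rec.patient_id, v.observed_at]
            checked += 1
    assert checked == 200


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_micd_round_trip_to_their_latent_level(seed):
    records, latent = generate_cohort(small_config(seed=seed), return_latent=True)
    latent_level = {
        (row.patient_id, row.date): row.micd_level for row in latent.itertuples()
    }
    for rec in records:
        for a in rec.micd_series:
            level = score_micd(a).level
            assert level == latent_level[rec.patient_id, a.assessed_at]


def test_band_mix_per_setting_matches_config_within_3se():
    """Per-setting daily band proportions track the configured targets."""
    cfg = default_paper_config(seed=21)
    days = expand_to_days(generate_cohort(cfg))
    for setting in SETTINGS:
        sub = days[days["setting"] == setting]
        n = len(sub)
        assert n > 0
        for band, target in cfg.news_band_probs[setting].items():
            observed = (sub["news_band"] == band).mean()
            se = np.sqrt(target * (1 - target) / n)
            assert abs(observed - target) <= 3 * se + 1e-9, (setting, band)


def test_zero_mismatch_gives_perfect_consistency():
    cfg = small_config(seed=5, mismatch_rate=0.0)
    days = expand_to_days(generate_cohort(cfg))
    assert consistency_analysis(days).proportion() == 1.0


@pytest.mark.parametrize("m", [0.1, 0.3])
def test_consistency_recovers_one_minus_m(m):
    """Across seeds, measured consistency tracks 1-m within 3 MC standard errors."""
    props = []
    n_days = 0
    for seed in range(5):
        cfg = dataclasses.replace(default_paper_config(seed=seed), mismatch_rate=m)
        days = expand_to_days(generate_cohort(cfg))
        props.append(consistency_analysis(days).proportion())
        n_days = len(days)
    se = np.sqrt(m * (1 - m) / (n_days * len(props)))
    assert abs(np.mean(props) - (1 - m)) <= 3 * se
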