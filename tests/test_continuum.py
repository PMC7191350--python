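"""Care-continuum indicator rules: staging, care, suppression, timing, comorbidity."""

import datetime as dt
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cohortlink.config import CorruptionRates, SimConfig, StudyWindow
from cohortlink.continuum import (
    classify_stage,
    comorbidity_flags,
    derive_indicators,
    derive_indicators_per_person,
    ever_stage3,
    received_care,
    stage_in_year,
    suppression_indicators,
    time_to_suppression,
)
from cohortlink.synthetic import generate_registry, enrollment_mask

WINDOW = StudyWindow()


def labs_frame(rows):
    return pd.DataFrame(
        [
            {"person_id": "P", "lab_date": pd.Timestamp(d), "kind": k, "value": float(v)}
            for d, k, v in rows
        ],
        columns=["person_id", "lab_date", "kind", "value"],
    )


def dx_frame(rows):
    return pd.DataFrame(
        [{"person_id": "P", "event_date": pd.Timestamp(d), "kind": k} for d, k in rows],
        columns=["person_id", "event_date", "kind"],
    )


EMPTY_LABS = labs_frame([])
EMPTY_DX = dx_frame([])


def oracle_stage(count, percent, has_oi):
    """Exhaustive restatement of the CDC staging rules, evaluated literally."""
    if has_oi:
        return 3
    if count is not None:
        return 3 if count < 200 else (1 if count > 500 else 2)
    if percent is not None:
        return 3 if percent < 14 else (1 if percent >= 29 else 2)
    return "unknown"


class TestClassifyStage:
    @pytest.mark.parametrize(
        "count, percent, has_oi, expected",
        [
            (150, None, False, 3),
            (501, None, False, 1),
            (500, None, False, 2),
            (200, None, False, 2),
            (199.9, None, False, 3),
            (650, 12, False, 1),   # count takes precedence over a discordant percent
            (None, 29, False, 1),
            (None, 28.5, False, 2),
            (None, 13.9, False, 3),
            (None, None, False, "unknown"),
            (650, None, True, 3),  # OI forces stage 3 regardless of CD4
        ],
    )
    def test_stated_thresholds(self, count, percent, has_oi, expected):
        assert classify_stage(count, percent, has_oi) == expected

    def test_agrees_with_truth_table_oracle_on_grid(self):
        counts = [None, 0, 150, 199, 200, 350, 500, 501, 650, 1200]
        percents = [None, 0, 13, 14, 20, 28, 29, 35, 60]
        for count, percent, has_oi in itertools.product(counts, percents, [False, True]):
            assert classify_stage(count, percent, has_oi) == oracle_stage(count, percent, has_oi)


class TestStageInYear:
    def test_no_cd4_labs_is_unknown(self):
        labs = labs_frame([("2017-05-01", "viral_load", 50)])
        assert stage_in_year(labs, WINDOW) == "unknown"

    def test_last_lab_rule_both_directions(self):
        worsening = labs_frame([("2016-01-01", "cd4_count", 550), ("2017-06-01", "cd4_count", 180)])
        improving = labs_frame([("2016-01-01", "cd4_count", 180), ("2017-06-01", "cd4_count", 550)])
        assert stage_in_year(worsening, WINDOW) == 3
        assert stage_in_year(improving, WINDOW) == 1

    def test_labs_after_outcome_year_ignored(self):
        labs = labs_frame([("2017-06-01", "cd4_count", 550), ("2018-02-01", "cd4_count", 100)])
        assert stage_in_year(labs, WINDOW) == 1


class TestEverStage3:
    def test_single_historic_low_cd4_is_permanent(self):
        labs = labs_frame([("2012-01-01", "cd4_count", 199), ("2016-01-01", "cd4_count", 800)])
        assert ever_stage3(labs, EMPTY_DX)

    def test_all_cd4_above_200_no_oi_is_false(self):
        labs = labs_frame([("2012-01-01", "cd4_count", 200), ("2016-01-01", "cd4_count", 800)])
        assert not ever_stage3(labs, EMPTY_DX)

    def test_oi_event_alone_suffices(self):
        assert ever_stage3(EMPTY_LABS, dx_frame([("2013-01-01", "oi_aids_defining")]))

    def test_monotone_under_added_history(self):
        base = labs_frame([("2012-01-01", "cd4_count", 150)])
        more = labs_frame([("2012-01-01", "cd4_count", 150), ("2015-01-01", "cd4_count", 900)])
        assert ever_stage3(base, EMPTY_DX) and ever_stage3(more, EMPTY_DX)


class TestReceivedCare:
    def test_boundary_lab_on_last_day_counts(self):
        assert received_care(labs_frame([("2017-12-31", "viral_load", 100)]), 2017)

    def test_labs_only_in_prior_year_do_not_count(self):
        assert not received_care(labs_frame([("2016-06-01", "cd4_count", 400)]), 2017)

    def test_only_cd4_or_vl_labs_count(self):
        # a diagnosis event is not a lab; an empty lab table means no care
        assert not received_care(EMPTY_LABS, 2017)


class TestSuppression:
    def test_threshold_200_is_inclusive(self):
        ever, last, any_ = suppression_indicators(
            labs_frame([("2015-01-01", "viral_load", 200)]), WINDOW
        )
        assert ever and last is None and not any_

    def test_rebound_discriminates_last_lab_from_any(self):
        labs = labs_frame(
            [("2017-03-01", "viral_load", 40), ("2017-11-01", "viral_load", 50000)]
        )
        ever, last, any_ = suppression_indicators(labs, WINDOW)
        assert ever and last is False and any_

    def test_late_year_suppression_sets_both(self):
        labs = labs_frame(
            [("2017-03-01", "viral_load", 50000), ("2017-11-01", "viral_load", 40)]
        )
        ever, last, any_ = suppression_indicators(labs, WINDOW)
        assert ever and last is True and any_

    def test_suppression_outside_window_does_not_count_as_ever(self):
        labs = labs_frame([("2009-01-01", "viral_load", 40)])
        ever, _, _ = suppression_indicators(labs, WINDOW)
        assert not ever


class TestTimeToSuppression:
    def test_six_month_interval(self):
        labs = labs_frame(
            [("2012-01-01", "viral_load", 30000), ("2012-07-01", "viral_load", 100)]
        )
        months, category = time_to_suppression(labs)
        assert months == pytest.approx(182 / 30.4375, abs=1e-9)
        assert category == "0-24"

    def test_three_year_interval_is_slow(self):
        labs = labs_frame(
            [("2011-01-01", "viral_load", 30000), ("2014-01-01", "viral_load", 100)]
        )
        months, category = time_to_suppression(labs)
        assert months == pytest.approx(1096 / 30.4375, abs=1e-9)
        assert category == ">24"

    def test_first_vl_already_suppressed_yields_none(self):
        labs = labs_frame([("2013-01-01", "viral_load", 80)])
        assert time_to_suppression(labs) == (None, None)

    def test_boundary_24_months_is_fast_category(self):
        days = int(24 * 30.4375)
        labs = labs_frame(
            [("2012-01-01", "viral_load", 30000),
             (str((pd.Timestamp("2012-01-01") + pd.Timedelta(days=days)).date()), "viral_load", 100)]
        )
        _, category = time_to_suppression(labs)
        assert category == "0-24"


class TestComorbidity:
    def test_event_before_window_does_not_count(self):
        assert comorbidity_flags(dx_frame([("2010-12-31", "sti")]), WINDOW) == (False, False, False)

    def test_confirmed_hcv_in_window_counts(self):
        assert comorbidity_flags(
            dx_frame([("2013-05-01", "hcv_chronic_confirmed")]), WINDOW
        ) == (False, False, True)

    def test_antibody_only_hepatitis_never_counts(self):
        assert comorbidity_flags(
            dx_frame([("2013-05-01", "hcv_antibody_only")]), WINDOW
        ) == (False, False, False)


class TestDeriveIndicators:
    def test_vectorized_path_matches_per_person_rules(self, noisy_sim):
        _, persons, labs, diagnoses, *_ = noisy_sim
        fast = derive_indicators(persons, labs, diagnoses, WINDOW)
        slow = derive_indicators_per_person(persons, labs, diagnoses, WINDOW)
        pd.testing.assert_frame_equal(fast, slow, check_dtype=False)

    def test_last_lab_suppression_implies_care(self, noisy_sim):
        _, persons, labs, diagnoses, *_ = noisy_sim
        ind = derive_indicators(persons, labs, diagnoses, WINDOW)
        applicable = ind.loc[ind["suppressed_last_lab_2017"].notna()]
        assert applicable["care_2017"].all()

    def test_any_year_suppression_implies_ever(self, noisy_sim):
        _, persons, labs, diagnoses, *_ = noisy_sim
        ind = derive_indicators(persons, labs, diagnoses, WINDOW)
        assert ind.loc[ind["suppressed_any_2017"], "ever_suppressed_2011_2017"].all()

    def test_group_prevalences_recover_outcome_model(self):
        config = SimConfig(
            n_persons=10_000, seed=29, enroll_fraction=0.5,
            corruption_rates=CorruptionRates.zero(),
            stale_lab_fraction=0.0, deceased_fraction=0.0, non_resident_fraction=0.0,
        )
        persons, labs, diagnoses = generate_registry(config)
        enrolled = enrollment_mask(config)
        ind = derive_indicators(persons, labs, diagnoses, WINDOW)
        ind = ind.merge(persons[["person_id"]], on="person_id")
        ind["enrolled"] = enrolled
        with_labs = ind.loc[ind["person_id"].isin(labs["person_id"])]

        for group, flag in (("cohort", True), ("non_cohort", False)):
            probs = config.outcome_model[group]
            sub = with_labs.loc[with_labs["enrolled"] == flag]
            n = len(sub)

            care = sub["care_2017"].mean()
            se = math.sqrt(probs.care_in_year * (1 - probs.care_in_year) / n)
            assert abs(care - probs.care_in_year) < 3 * se, group

            ever = sub["ever_suppressed_2011_2017"].mean()
            se = math.sqrt(probs.ever_suppressed * (1 - probs.ever_suppressed) / n)
            assert abs(ever - probs.ever_suppressed) < 3 * se, group

            has_vl_2017 = sub.loc[sub["suppressed_last_lab_2017"].notna()]
            last = has_vl_2017["suppressed_last_lab_2017"].astype(bool).mean()
            m = len(has_vl_2017)
            se = math.sqrt(probs.suppressed_last_lab * (1 - probs.suppressed_last_lab) / m)
            assert abs(last - probs.suppressed_last_lab) < 3 * se, group
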