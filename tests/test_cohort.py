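"""Eligibility, follow-up construction, person-time, incidence, sampling."""

import numpy as np
import pandas as pd
import pytest

from claimscreen.ascertainment import ascertain_all
from claimscreen.cohort import (
    CohortError,
    assess_eligibility_frame,
    build_cohort,
    incidence_rate,
    person_years,
    sample_nested_case_control,
)


def _base_row(bid, birth, death=None, **overrides):
    row = {
        "beneficiary_id": bid,
        "birth_date": pd.Timestamp(birth),
        "sex": "male",
        "race_ethnicity": "white",
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "us_residence": True,
    }
    for y in range(2009, 2015):
        row[f"part_ab_{y}"] = True
        row[f"non_medicare_{y}"] = False
    row.update(overrides)
    return row


def _statuses(rows=()):
    cols = ["beneficiary_id", "is_case", "diagnosis_date", "n_pd_codes",
            "neurologist_flag", "exclusion_reason", "first_exclusion_date"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(list(rows))[cols]


def _status(bid, dx=None, excl=None, reason="none"):
    return {
        "beneficiary_id": bid, "is_case": dx is not None,
        "diagnosis_date": pd.Timestamp(dx) if dx else pd.NaT,
        "n_pd_codes": 1 if dx else 0, "neurologist_flag": False,
        "exclusion_reason": reason,
        "first_exclusion_date": pd.Timestamp(excl) if excl else pd.NaT,
    }


class TestEligibility:
    def test_age_91_is_over_age(self):
        base = pd.DataFrame([_base_row("B1", "1918-06-01")])
        out = assess_eligibility_frame(base, _statuses(), 2009)
        assert not out.loc[0, "eligible"]
        assert "over_age" in out.loc[0, "reasons"]

    def test_age_66y10m_is_under_age(self):
        base = pd.DataFrame([_base_row("B1", "1943-02-28")])  # 66y10m at 2009-12-31
        out = assess_eligibility_frame(base, _statuses(), 2009)
        assert "under_age" in out.loc[0, "reasons"]

    def test_age_66y11m_is_old_enough(self):
        base = pd.DataFrame([_base_row("B1", "1943-01-15")])
        out = assess_eligibility_frame(base, _statuses(), 2009)
        assert out.loc[0, "eligible"]

    def test_death_before_baseline_disqualifies(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01", death="2009-12-15")])
        out = assess_eligibility_frame(base, _statuses(), 2009)
        assert "not_alive_at_baseline" in out.loc[0, "reasons"]

    def test_prior_pd_disqualifies(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01")])
        st = _statuses([_status("B1", dx="2008-05-01")])
        out = assess_eligibility_frame(base, st, 2009)
        assert "prior_pd" in out.loc[0, "reasons"]

    def test_coverage_and_residence_requirements(self):
        base = pd.DataFrame([
            _base_row("B1", "1940-01-01", part_ab_2009=False),
            _base_row("B2", "1940-01-01", non_medicare_2009=True),
            _base_row("B3", "1940-01-01", us_residence=False),
        ])
        out = assess_eligibility_frame(base, _statuses(), 2009)
        assert list(out["eligible"]) == [False, False, False]

    def test_missing_reference_year_raises(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01")])
        with pytest.raises(CohortError, match="2008"):
            assess_eligibility_frame(base, _statuses(), 2008)


class TestBuildCohort:
    def test_uneventful_follow_up_ends_administratively(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01")])
        row = build_cohort(base, _statuses()).iloc[0]
        assert row["event"] == "admin_end"
        assert row["exit_date"] == pd.Timestamp("2014-12-31")
        assert row["follow_up_years"] == pytest.approx(5.0, abs=0.01)

    def test_pd_event_exits_at_diagnosis(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01")])
        st = _statuses([_status("B1", dx="2012-01-01")])
        row = build_cohort(base, st).iloc[0]
        assert row["event"] == "pd"
        assert row["follow_up_years"] == pytest.approx(2.0, abs=0.01)

    def test_excluded_diagnosis_censors_before_pd(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01")])
        st = _statuses([_status("B1", excl="2011-06-01", reason="lewy_body")])
        row = build_cohort(base, st).iloc[0]
        assert row["event"] == "censored_excluded_dx"
        assert row["exit_date"] == pd.Timestamp("2011-06-01")

    def test_same_day_pd_and_death_counts_as_pd(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01", death="2012-01-01")])
        st = _statuses([_status("B1", dx="2012-01-01")])
        assert build_cohort(base, st).iloc[0]["event"] == "pd"

    def test_pd_before_entry_is_a_consistency_error(self):
        base = pd.DataFrame([_base_row("B1", "1940-01-01")])
        st = _statuses([_status("B1", dx="2009-06-01")])
        with pytest.raises(CohortError, match="before cohort entry"):
            build_cohort(base, st)

    def test_earlier_death_never_lengthens_follow_up(self):
        base_late = pd.DataFrame([_base_row("B1", "1940-01-01", death="2013-06-01")])
        base_early = pd.DataFrame([_base_row("B1", "1940-01-01", death="2011-06-01")])
        late = build_cohort(base_late, _statuses()).iloc[0]["follow_up_years"]
        early = build_cohort(base_early, _statuses()).iloc[0]["follow_up_years"]
        assert early < late


class TestPersonYearsAndIncidence:
    def test_person_years_sums_rows(self):
        cohort = pd.DataFrame({"follow_up_years": [2.0, 3.0]})
        assert person_years(cohort) == 5.0
        assert person_years(pd.DataFrame({"follow_up_years": []})) == 0.0

    def test_person_years_additive_over_partition(self, small_population):
        base, claims, _ = small_population
        statuses = ascertain_all(claims, base["beneficiary_id"])
        elig = assess_eligibility_frame(base, statuses, 2009)
        cohort = build_cohort(base[elig["eligible"].to_numpy()].reset_index(drop=True),
                              statuses)
        half = len(cohort) // 2
        total = person_years(cohort)
        assert total == pytest.approx(
            person_years(cohort.iloc[:half]) + person_years(cohort.iloc[half:])
        )
        # brute-force day-count oracle
        days = (pd.to_datetime(cohort["exit_date"])
                - pd.to_datetime(cohort["entry_date"])).dt.days
        assert total == pytest.approx(float((days / 365.25).sum()), abs=1e-9)

    @pytest.mark.parametrize(
        "events, py, expected",
        [(0, 1000.0, 0.0), (1, 100000.0, 1.0), (50, 10000.0, 500.0)],
    )
    def test_incidence_rate_arithmetic(self, events, py, expected):
        assert incidence_rate(events, py) == pytest.approx(expected)

    def test_incidence_rate_requires_positive_person_years(self):
        with pytest.raises(CohortError):
            incidence_rate(1, 0.0)

    def test_simulated_incidence_near_configured_rate(self, small_population):
        base, claims, _ = small_population
        statuses = ascertain_all(claims, base["beneficiary_id"])
        elig = assess_eligibility_frame(base, statuses, 2009)
        cohort = build_cohort(base[elig["eligible"].to_numpy()].reset_index(drop=True),
                              statuses)
        py = person_years(cohort)
        events = int((cohort["event"] == "pd").sum())
        expected = 0.00461 * py
        assert abs(events - expected) <= 3 * np.sqrt(expected)


class TestNestedCaseControl:
    @pytest.fixture(scope="class")
    def cohort(self, small_population):
        base, claims, _ = small_population
        statuses = ascertain_all(claims, base["beneficiary_id"])
        elig = assess_eligibility_frame(base, statuses, 2009)
        return build_cohort(base[elig["eligible"].to_numpy()].reset_index(drop=True),
                            statuses)

    def test_sampling_is_deterministic(self, cohort):
        s1 = sample_nested_case_control(cohort, 42)
        s2 = sample_nested_case_control(cohort, 42)
        pd.testing.assert_frame_equal(s1, s2)

    def test_cases_keep_their_diagnosis_dates(self, cohort):
        sample = sample_nested_case_control(cohort, 42)
        cases = sample[sample["is_case"]].set_index("beneficiary_id")
        pd_rows = cohort[cohort["event"] == "pd"].set_index("beneficiary_id")
        assert set(cases.index) == set(pd_rows.index)
        assert (
            pd.to_datetime(cases["reference_date"])
            == pd.to_datetime(pd_rows.loc[cases.index, "exit_date"])
        ).all()

    def test_controls_survived_to_their_reference_date(self, cohort):
        sample = sample_nested_case_control(cohort, 42)
        ctrl = sample[~sample["is_case"]].set_index("beneficiary_id")
        exits = cohort.set_index("beneficiary_id").loc[ctrl.index, "exit_date"]
        assert (pd.to_datetime(ctrl["reference_date"])
                <= pd.to_datetime(exits)).all()
        # each beneficiary appears at most once
        assert sample["beneficiary_id"].is_unique

    def test_cohort_without_cases_yields_only_controls(self):
        base = pd.DataFrame([_base_row(f"B{i}", "1940-01-01") for i in range(5)])
        cohort = build_cohort(base, _statuses())
        sample = sample_nested_case_control(cohort, 0)
        assert not sample["is_case"].any()
        assert len(sample) == 5
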