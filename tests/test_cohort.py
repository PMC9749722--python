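"""Eligibility rules, income standardization and person-month expansion."""

import numpy as np
import pandas as pd
import pytest

import bfmsm as B
from conftest import make_persons

TABLE = {2011: 70.0, 2012: 70.0, 2013: 70.0, 2014: 77.0, 2015: 77.0}


class TestStandardizeIncome:
    def test_identity_when_thresholds_equal(self):
        assert B.standardize_income(100.0, 2014, TABLE) == pytest.approx(100.0)

    def test_ratio_formula(self):
        assert B.standardize_income(100.0, 2011, {2011: 70.0, 2015: 77.0}) \
            == pytest.approx(110.0)

    def test_batch_against_hand_computed_vector(self):
        incomes = np.array([50.0, 80.0, 120.0, 200.0, 300.0])
        years = np.array([2011, 2012, 2013, 2014, 2015])
        # by hand: income * 77/threshold(year)
        expected = np.array([50 * 1.1, 88.0, 132.0, 200.0, 300.0])
        out = B.standardize_income(incomes, years, TABLE)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_errors(self):
        with pytest.raises(KeyError):
            B.standardize_income(10.0, 1999, TABLE)
        with pytest.raises(ValueError):
            B.standardize_income(10.0, 2011, {2011: 0.0})


class TestApplyExclusions:
    def test_clean_cohort_untouched(self):
        persons = make_persons([{}, {"entry_age_years": 60.0}])
        kept, rep = B.apply_exclusions(persons)
        assert len(kept) == 2 and rep.retained == 2
        assert all(v == 0 for v in rep.counts.values())

    def test_death_before_registration(self):
        persons = make_persons([{"entry_month": 5, "death_month": 3}])
        kept, rep = B.apply_exclusions(persons)
        assert len(kept) == 0
        assert rep.counts["died_before_registration"] == 1

    def test_each_rule_once_plus_one_clean(self):
        persons = make_persons([
            {"entry_month": 5, "death_month": 3},          # (i)
            {"entry_age_years": 101.0},                    # (ii)
            {"income_brl": 290.0, "application_year": 2011},  # (iii): 290*1.1 > 300
            {"excluded_ethnicity": True},                  # (iv)
            {"entry_month": 7, "death_month": 7},          # (v)
            {},                                            # clean
        ])
        kept, rep = B.apply_exclusions(persons)
        assert [rep.counts[r] for r in
                ("died_before_registration", "age_over_100",
                 "income_over_threshold", "excluded_ethnicity_flag",
                 "applied_on_last_day_or_died_same_day")] == [1, 1, 1, 1, 1]
        assert rep.retained == 1 and kept["person_id"].tolist() == [5]
        assert rep.retained + sum(rep.counts.values()) == rep.total

    def test_first_violated_rule_wins(self):
        persons = make_persons([{"entry_month": 5, "death_month": 3,
                                 "entry_age_years": 105.0,
                                 "excluded_ethnicity": True}])
        _, rep = B.apply_exclusions(persons)
        assert rep.counts["died_before_registration"] == 1
        assert rep.counts["age_over_100"] == 0

    def test_registration_in_final_month_excluded(self):
        persons = make_persons([{"entry_month": 60}])
        _, rep = B.apply_exclusions(persons, admin_end=60)
        assert rep.counts["applied_on_last_day_or_died_same_day"] == 1

    def test_same_month_award_flag(self):
        persons = make_persons([{"entry_month": 4, "treatment_start_month": 4},
                                {"entry_month": 4, "treatment_start_month": 5}])
        kept, rep = B.apply_exclusions(persons, exclude_same_month_award=True)
        assert rep.counts["same_month_award"] == 1 and len(kept) == 1
        kept2, rep2 = B.apply_exclusions(persons)
        assert rep2.counts["same_month_award"] == 0 and len(kept2) == 2

    def test_empty_input(self):
        kept, rep = B.apply_exclusions(make_persons([]).iloc[:0])
        assert len(kept) == 0 and rep.total == 0


class TestExpansion:
    def test_window_entry_below_lower_bound(self):
        persons = make_persons([{"entry_age_years": 29.5}])
        pm = B.expand_person_months(persons, age_window=(30, 70))
        assert pm["t"].iloc[0] == 0
        assert pm["calendar_month"].iloc[0] == 6  # the month they turn 30
        assert pm["age_years"].iloc[0] == pytest.approx(30.0)

    def test_too_old_contributes_no_rows(self):
        persons = make_persons([{"entry_age_years": 71.0}])
        pm = B.expand_person_months(persons, age_window=(30, 70))
        assert len(pm) == 0

    def test_stops_before_upper_age_bound(self):
        persons = make_persons([{"entry_age_years": 69.5}])
        pm = B.expand_person_months(persons, age_window=(30, 70))
        assert (pm["age_years"] < 70).all()
        assert len(pm) == 6

    def test_death_after_three_months(self):
        persons = make_persons([{"death_month": 2}])
        pm = B.expand_person_months(persons)
        assert pm["event"].tolist() == [0, 0, 1]
        assert pm["t"].tolist() == [0, 1, 2]

    def test_treatment_before_risk_start_treated_from_t0(self):
        persons = make_persons([{"entry_age_years": 29.0, "entry_month": 0,
                                 "treatment_start_month": 2}])
        pm = B.expand_person_months(persons, age_window=(30, 70))
        assert (pm["treated"] == 1).all()
        assert not pm["initiation"].any()

    def test_unobserved_death_looks_censored(self):
        persons = make_persons([{"death_month": 2, "death_observed": False}])
        pm = B.expand_person_months(persons, admin_end=10)
        assert len(pm) == 10 and pm["event"].sum() == 0

    def test_cause_specific_events(self):
        persons = make_persons([{"death_month": 2, "death_cause": "ihd"},
                                {"death_month": 3, "death_cause": "non_cvd"}])
        pm = B.expand_person_months(persons, cause="cvd")
        assert pm.groupby("person_id")["event"].sum().tolist() == [1, 0]

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            B.expand_person_months(make_persons([{}]), age_window=(70, 30))


class TestExpansionInvariants:
    def test_totals_match_per_person_loop_oracle(self, mid_cohort):
        persons, _ = B.apply_exclusions(mid_cohort.iloc[:500])
        pm = B.expand_person_months(persons, age_window=(30, 70), admin_end=60)
        # independent slow oracle: iterate persons, walk months
        total, events = 0, 0
        for p in persons.itertuples():
            age, entry = p.entry_age_years, p.entry_month
            start = entry if age >= 30 else entry + int(np.ceil((30 - age) * 12))
            end = min(entry + int(np.ceil((70 - age) * 12)) - 1, 59)
            if p.death_month is not pd.NA and p.death_observed:
                end = min(end, p.death_month)
                if end == p.death_month and end >= start:
                    events += 1
            total += max(0, end - start + 1)
        assert len(pm) == total
        assert pm["event"].sum() == events

    def test_event_only_on_final_row_and_t_contiguous(self, mid_person_months):
        pm = mid_person_months
        g = pm.groupby("person_id")
        last_t = g["t"].max()
        event_t = pm.loc[pm["event"] == 1].set_index("person_id")["t"]
        assert (last_t.loc[event_t.index] == event_t).all()
        assert (g["t"].min() == 0).all()
        assert (g["t"].count() == last_t + 1).all()  # contiguous 0..max
        assert g["treated"].apply(lambda s: s.is_monotonic_increasing).all()

    def test_expand_then_collapse_reproduces_followup(self, mid_cohort):
        persons, _ = B.apply_exclusions(mid_cohort.iloc[:800])
        pm = B.expand_person_months(persons)
        collapsed = pm.groupby("person_id").agg(last=("t", "max"),
                                                died=("event", "max"))
        merged = persons.set_index("person_id").join(collapsed, how="inner")
        obs_death = merged["death_month"].where(merged["death_observed"])
        expected_last = (obs_death.astype("Float64").fillna(np.inf)
                         .clip(upper=59) - merged["entry_month"])
        assert (collapsed["last"] == expected_last.loc[collapsed.index]).all()
        assert (merged["died"].astype(bool)
                == obs_death.notna().loc[collapsed.index]).all()
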