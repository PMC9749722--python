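"""E-values, risk-set matching, adjusted fits and the under-reporting
restriction."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import bfmsm as B
from conftest import COVARIATES, make_person_months, make_persons


class TestEValue:
    @pytest.mark.parametrize("hr,expected", [
        (0.82, 1.74),            # published fifth-quintile premature all-cause HR
        (1.0, 1.0),
        (0.5, 2 + math.sqrt(2)),
    ])
    def test_point_values(self, hr, expected):
        assert B.evalue(hr).point == pytest.approx(expected, abs=5e-3)

    def test_ci_limit_uses_bound_nearer_null(self):
        res = B.evalue(0.82, ci=(0.78, 0.87))
        rr = 1 / 0.87
        assert res.ci_limit == pytest.approx(rr + math.sqrt(rr * (rr - 1)))

    def test_ci_crossing_null_gives_one(self):
        assert B.evalue(0.96, ci=(0.92, 1.00)).ci_limit == 1.0
        assert B.evalue(1.05, ci=(0.95, 1.16)).ci_limit == 1.0

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            B.evalue(0.0)

    @settings(derandomize=True, max_examples=100)
    @given(hr=st.floats(0.01, 100.0))
    def test_inversion_symmetry_and_monotonicity(self, hr):
        assert B.evalue(hr).point == pytest.approx(B.evalue(1 / hr).point,
                                                   rel=1e-9)
        further = hr * 1.1 if hr >= 1 else hr / 1.1
        assert B.evalue(further).point > B.evalue(hr).point or hr == 1.0


class TestRiskSetMatch:
    def test_exact_match_single_pair(self):
        pm = make_person_months([(1, 0, 0, 0), (1, 1, 1, 0),
                                 (2, 0, 0, 0), (2, 1, 0, 0)])
        ps = np.array([0.3, 0.3, 0.3, 0.3])
        pairs, diag = B.risk_set_match(pm, ps, caliper=0.05)
        assert len(pairs) == 1
        assert pairs.loc[0, ["initiator", "control", "distance"]].tolist() \
            == [1, 2, 0.0]
        assert diag["match_rate"] == 1.0

    def test_caliper_excludes_distant_control(self):
        pm = make_person_months([(1, 0, 0, 0), (1, 1, 1, 0),
                                 (2, 0, 0, 0), (2, 1, 0, 0)])
        ps = np.array([0.3, 0.9, 0.3, 0.3])
        pairs, diag = B.risk_set_match(pm, ps, caliper=0.05)
        assert len(pairs) == 0
        assert diag["unmatched"] == [(1, 1, "no control within caliper")]

    def test_five_person_staggered_toy_enumerated_by_hand(self):
        """p1 initiates at t=1, p4 at t=3; constant pre-initiation scores
        .30/.32/.10/.29/.31. Greedy matching with caliper .05: p1 takes p4
        (|.29-.30| ties |.31-.30|, lower id wins); p4 — already used as a
        control but still an initiator — takes p5; p3 is never used."""
        rows, ps = [], []
        scores = {1: 0.30, 2: 0.32, 3: 0.10, 4: 0.29, 5: 0.31}
        inits = {1: 1, 4: 3}
        for pid in range(1, 6):
            for t in range(5):
                started = pid in inits and t >= inits[pid]
                rows.append((pid, t, int(started), 0))
                ps.append(1.0 if (started and t > inits[pid]) else scores[pid])
        pm = make_person_months(rows)
        pm.loc[pm["initiation"], :]  # initiation derived from first treated month
        pairs, diag = B.risk_set_match(pm, np.array(ps), caliper=0.05)
        assert pairs[["month", "initiator", "control"]].values.tolist() \
            == [[1, 1, 4], [3, 4, 5]]
        np.testing.assert_allclose(pairs["distance"], [0.01, 0.02], atol=1e-12)
        assert 3 not in set(pairs["control"])

    def test_nonpositive_caliper_rejected(self, mid_person_months):
        with pytest.raises(ValueError, match="caliper"):
            B.risk_set_match(mid_person_months.head(50), np.full(50, 0.5),
                             caliper=0.0)

    def test_invariants_on_simulation(self, mid_person_months):
        pm = mid_person_months
        model = B.fit_ps_model(pm, COVARIATES)
        ps = B.predict_ps(model, pm)
        pairs, diag = B.risk_set_match(pm, ps)
        assert pairs["control"].is_unique
        assert (pairs["distance"] <= diag["caliper"]).all()
        # every control is untreated through its matching month
        first_treated = pm.loc[pm["treated"] == 1].groupby("person_id")["t"].min()
        starts = first_treated.reindex(pairs["control"]).fillna(np.inf).to_numpy()
        assert (starts > pairs["month"].to_numpy()).all()


class TestMatchedFit:
    def test_recovers_marginal_effect_without_confounding(self):
        """With no confounders initiation is independent of risk, so the
        matched conditional estimate recovers the counterfactual HR."""
        betas, ses = [], []
        cfg0 = B.default_config(8000, baseline_mortality_logit=-5.3,
                                confounder_spec=())
        oracle = math.log(B.counterfactual_marginal_hr(cfg0, 400_000))
        for seed in range(4):
            cfg = dataclasses.replace(cfg0, seed=50 + seed)
            persons, _ = B.apply_exclusions(B.simulate_cohort(cfg))
            pm = B.expand_person_months(persons)
            ps = B.predict_ps(B.fit_ps_model(pm, ()), pm)
            pairs, _ = B.risk_set_match(pm, ps, caliper=0.05)
            res = B.matched_hazard_fit(pairs, pm)
            betas.append(res.beta)
            ses.append(res.se)
        mc_se = np.sqrt(np.mean(np.square(ses)) / len(betas))
        assert abs(np.mean(betas) - oracle) < 3.5 * mc_se

    def test_no_pairs_rejected(self, mid_person_months):
        empty = pd.DataFrame(columns=["set_id", "month", "initiator", "control",
                                      "initiator_ps", "control_ps", "distance"])
        with pytest.raises(ValueError, match="no matched sets"):
            B.matched_hazard_fit(empty, mid_person_months)

    def test_event_free_sets_rejected(self):
        pm = make_person_months([(1, 0, 0, 0), (1, 1, 1, 0),
                                 (2, 0, 0, 0), (2, 1, 0, 0)])
        pairs = pd.DataFrame([{"set_id": 0, "month": 1, "initiator": 1,
                               "control": 2, "initiator_ps": 0.3,
                               "control_ps": 0.3, "distance": 0.0}])
        with pytest.raises(ValueError, match="no matched set contains"):
            B.matched_hazard_fit(pairs, pm)


class TestAdjustedFit:
    def test_agrees_with_weighted_fit_absent_confounding(self):
        cfg = B.default_config(10000, seed=61, baseline_mortality_logit=-5.3,
                               confounder_spec=())
        persons, _ = B.apply_exclusions(B.simulate_cohort(cfg))
        pm = B.expand_person_months(persons)
        adj = B.adjusted_hazard_fit(pm, (), cov_type="nonrobust")
        msm_res, _, _ = B.iptw_msm(pm, (), cov_type="nonrobust")
        assert abs(adj.beta - msm_res.beta) < 2 * adj.se

    def test_omitting_confounders_shifts_estimate(self, big_person_months):
        full = B.adjusted_hazard_fit(big_person_months, COVARIATES,
                                     cov_type="nonrobust")
        naked = B.adjusted_hazard_fit(big_person_months, (),
                                      cov_type="nonrobust")
        # uptake and mortality share risk factors: dropping them biases the
        # estimate upward by a detectable margin
        assert naked.beta - full.beta > 0.05


class TestRestriction:
    def test_zero_underreporting_keeps_everyone(self):
        persons = make_persons([{}, {}])
        assert len(B.restrict_to_low_underreporting(persons)) == 2

    def test_threshold_excludes_everyone(self):
        persons = make_persons([{"underreport_prob": 0.01}] * 3)
        assert len(B.restrict_to_low_underreporting(persons, 0.005)) == 0

    def test_missing_attribute_rejected(self):
        with pytest.raises(KeyError):
            B.restrict_to_low_underreporting(pd.DataFrame({"person_id": [1]}))
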