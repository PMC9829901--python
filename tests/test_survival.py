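"""Stratification, KM/log-rank and Cox against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from splicesig import (CohortSimConfig, cox_multivariate, km_logrank,
                       simulate_cohort, stratify_by_score)

from oracles import cox_grid_maximizer, logrank_oracle


def clinical_frame(times, events, ids=None, **covs):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time": times, "event": events,
                         **covs})


class TestStratify:
    def test_nine_distinct_scores_split_three_ways(self):
        scores = {f"p{i}": float(i) for i in range(9)}
        cohort = stratify_by_score(scores)
        assert len(cohort.stratum("high")) == 3
        assert len(cohort.stratum("mid")) == 3
        assert len(cohort.stratum("low")) == 3
        assert set(cohort.stratum("high")) == {"p8", "p7", "p6"}

    def test_floor_rule_with_ten_samples(self):
        scores = {f"p{i}": float(i) for i in range(10)}
        cohort = stratify_by_score(scores)
        assert len(cohort.stratum("high")) == 3
        assert len(cohort.stratum("low")) == 3
        assert len(cohort.stratum("mid")) == 4

    def test_quartile_mode(self):
        scores = {f"p{i}": float(i) for i in range(10)}
        cohort = stratify_by_score(scores, mode="quartile")
        assert len(cohort.stratum("high")) == 2
        assert len(cohort.stratum("low")) == 2

    def test_all_tied_scores_resolved_by_sample_id(self):
        scores = {f"p{i}": 1.0 for i in range(6)}
        cohort = stratify_by_score(scores)
        assert cohort.tied
        assert cohort.stratum("high") == ["p0", "p1"]
        assert cohort.stratum("low") == ["p4", "p5"]

    def test_scale_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        scores = pd.Series(rng.normal(size=20),
                           index=[f"p{i}" for i in range(20)])
        a = stratify_by_score(scores)
        b = stratify_by_score(np.exp(scores * 3))
        assert a.assignments == b.assignments

    def test_too_few_samples_is_an_error(self):
        with pytest.raises(ValueError):
            stratify_by_score({"a": 1.0, "b": 2.0})


class TestKmLogrank:
    def two_group_cohort(self, high_ids, low_ids):
        from splicesig import StratifiedCohort
        assign = {s: "high" for s in high_ids}
        assign.update({s: "low" for s in low_ids})
        return StratifiedCohort(assign)

    def test_identical_groups_give_zero_statistic(self):
        times = [3.0, 5.0, 7.0, 3.0, 5.0, 7.0]
        events = [1, 1, 0, 1, 1, 0]
        rec = clinical_frame(times, events)
        cohort = self.two_group_cohort(["p0", "p1", "p2"], ["p3", "p4", "p5"])
        res = km_logrank(rec, cohort)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_toy_matches_risk_set_oracle(self):
        # high: 1 (censored), 2, 3 ; low: 4, 5, 6 (censored)
        rec = clinical_frame([1, 2, 3, 4, 5, 6], [0, 1, 1, 1, 1, 0])
        cohort = self.two_group_cohort(["p0", "p1", "p2"], ["p3", "p4", "p5"])
        res = km_logrank(rec, cohort)
        expected = logrank_oracle([1, 2, 3], [0, 1, 1], [4, 5, 6], [1, 1, 0])
        assert res.statistic == pytest.approx(expected, rel=1e-9)
        assert res.p_value == pytest.approx(chi2.sf(expected, 1), rel=1e-9)

    def test_oracle_agreement_on_random_cohorts(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = 30
            times = rng.exponential(10, n).round(3) + 0.001
            events = (rng.random(n) < 0.8).astype(int)
            rec = clinical_frame(list(times), list(events))
            ids = list(rec["sample_id"])
            cohort = self.two_group_cohort(ids[:15], ids[15:])
            res = km_logrank(rec, cohort)
            expected = logrank_oracle(times[:15], events[:15],
                                      times[15:], events[15:])
            assert res.statistic == pytest.approx(expected, rel=1e-6)

    def test_no_events_is_an_error(self):
        rec = clinical_frame([1, 2, 3, 4], [0, 0, 0, 0])
        cohort = self.two_group_cohort(["p0", "p1"], ["p2", "p3"])
        with pytest.raises(ValueError, match="no events"):
            km_logrank(rec, cohort)

    def test_empty_stratum_is_an_error(self):
        rec = clinical_frame([1, 2, 3], [1, 1, 1])
        cohort = self.two_group_cohort(["p0", "p1", "p2"], [])
        with pytest.raises(ValueError, match="no subjects"):
            km_logrank(rec, cohort)

    def test_km_curve_properties(self):
        rec = clinical_frame([2, 4, 4, 6, 8, 9], [1, 1, 0, 1, 1, 1])
        cohort = self.two_group_cohort(["p0", "p1", "p2"], ["p3", "p4", "p5"])
        res = km_logrank(rec, cohort)
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == pytest.approx(1.0)
            assert (np.diff(surv) <= 1e-12).all()

    def test_statistic_invariant_to_group_relabeling(self):
        rec = clinical_frame([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        a = km_logrank(rec, self.two_group_cohort(["p0", "p1", "p2"],
                                                  ["p3", "p4", "p5"]))
        b = km_logrank(rec, self.two_group_cohort(["p3", "p4", "p5"],
                                                  ["p0", "p1", "p2"]))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    def test_median_is_earliest_time_survival_reaches_half(self):
        rec = clinical_frame([2, 4, 6, 8], [1, 1, 1, 1],
                             ids=["a", "b", "c", "d"])
        from splicesig import StratifiedCohort
        cohort = StratifiedCohort({"a": "high", "b": "high",
                                   "c": "low", "d": "low"})
        res = km_logrank(rec, cohort)
        # S drops to 0.5 at the first of the two event times in each stratum
        assert res.medians["high"] == pytest.approx(2.0)
        assert res.medians["low"] == pytest.approx(6.0)


class TestCox:
    def toy(self):
        rng = np.random.default_rng(5)
        n = 40
        x = np.repeat([0, 1], n // 2)
        times = rng.exponential(1.0 / (0.05 * np.exp(0.8 * x)))
        times = np.round(times, 6) + rng.uniform(0, 1e-4, n)  # break ties
        events = (rng.random(n) < 0.85).astype(int)
        return times, events, x

    def cohort_from_x(self, ids, x):
        from splicesig import StratifiedCohort
        return StratifiedCohort(
            {s: ("high" if xi else "low") for s, xi in zip(ids, x)})

    def test_estimate_matches_partial_likelihood_grid_search(self):
        times, events, x = self.toy()
        rec = clinical_frame(list(times), list(events))
        cohort = self.cohort_from_x(rec["sample_id"], x)
        res = cox_multivariate(rec, cohort)
        assert res.converged
        beta_hat = float(res.summary.loc[0, "coef"])
        beta_grid = cox_grid_maximizer(list(times), list(events), list(x))
        assert beta_hat == pytest.approx(beta_grid, abs=1e-4)

    def test_reference_level_flips_sign(self):
        times, events, x = self.toy()
        rec = clinical_frame(list(times), list(events))
        cohort = self.cohort_from_x(rec["sample_id"], x)
        low_ref = cox_multivariate(rec, cohort, reference="low")
        high_ref = cox_multivariate(rec, cohort, reference="high")
        assert float(low_ref.summary.loc[0, "coef"]) == pytest.approx(
            -float(high_ref.summary.loc[0, "coef"]), rel=1e-6)

    def test_zero_variance_covariate_rejected_by_name(self):
        times, events, x = self.toy()
        rec = clinical_frame(list(times), list(events),
                             flat=[1.0] * len(times))
        cohort = self.cohort_from_x(rec["sample_id"], x)
        with pytest.raises(ValueError, match="flat"):
            cox_multivariate(rec, cohort, covariates=["flat"])

    def test_categorical_covariate_is_one_hot_encoded(self):
        times, events, x = self.toy()
        stage = ["I", "II"] * (len(times) // 2)
        rec = clinical_frame(list(times), list(events), stage=stage)
        cohort = self.cohort_from_x(rec["sample_id"], x)
        res = cox_multivariate(rec, cohort, covariates=["stage"])
        assert res.converged
        assert any(t.startswith("stage_") for t in res.summary["term"])

    def test_null_cohort_group_ci_covers_one(self):
        """Group-term HR CI contains 1 in >= 90% of null cohorts."""
        covered = 0
        n_rep = 50
        for k in range(n_rep):
            cohort_sim = simulate_cohort(
                CohortSimConfig(n_samples=90, n_genes=20, signature_size=4,
                                effect_size=0.0, censoring_rate=0.2,
                                seed=7000 + k))
            strat = stratify_by_score(cohort_sim.truth["score"])
            res = cox_multivariate(cohort_sim.clinical, strat)
            lo, hi = res.summary.loc[0, ["ci_lower", "ci_upper"]]
            covered += lo <= 1.0 <= hi
        assert covered / n_rep >= 0.90

    def test_time_zero_records_rejected(self):
        rec = clinical_frame([0.0, 1.0, 2.0, 3.0], [1, 1, 1, 1])
        from splicesig import StratifiedCohort
        cohort = StratifiedCohort({"p0": "high", "p1": "high",
                                   "p2": "low", "p3": "low"})
        with pytest.raises(ValueError, match="positive"):
            km_logrank(rec, cohort)
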