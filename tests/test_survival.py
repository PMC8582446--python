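import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.optimize import brentq

from cfgi._stats import RiskSets, logrank_p
from cfgi.simulate import simulate_cohort, simulate_cutpoint_cohort
from cfgi.survival import (
    association_tests,
    c_index,
    contal_oquigley,
    cox_fit,
    km_logrank,
)


def _table_cohort():
    """Cohort expanded from printed 2x2 low/high contingency tables."""
    rows = []
    for sex, low, high in [("male", 136, 45), ("female", 103, 31)]:
        rows += [{"sex": sex, "group": "low"}] * low + [{"sex": sex, "group": "high"}] * high
    df = pd.DataFrame(rows)
    ecog = ["0+1"] * 234 + ["2+3"] * 5 + ["0+1"] * 75 + ["2+3"] * 1
    df["ecog"] = ecog
    return df


class TestAssociationTests:
    def test_sex_chi_square_matches_printed_value(self):
        res = association_tests(_table_cohort(), "group", ["sex"])
        assert res.loc[0, "test"] == "chi2"
        assert res.loc[0, "p"] == pytest.approx(0.7231, abs=5e-5)

    def test_ecog_switches_to_fisher(self):
        res = association_tests(_table_cohort(), "group", ["ecog"])
        assert res.loc[0, "test"] == "fisher"
        assert res.loc[0, "p"] > 0.9999

    def test_identical_proportions_give_p_one(self):
        df = pd.DataFrame({
            "group": ["low"] * 40 + ["high"] * 40,
            "cat": (["a"] * 20 + ["b"] * 20) * 2,
        })
        res = association_tests(df, "group", ["cat"])
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_chi_square_equals_hand_formula(self):
        df = _table_cohort()
        table = pd.crosstab(df["sex"], df["group"]).to_numpy()
        expected = stats.contingency.expected_freq(table)
        hand = ((table - expected) ** 2 / expected).sum()
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert chi2 == pytest.approx(hand, rel=1e-12)

    def test_continuous_covariate_uses_t_test(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"group": rng.choice(["low", "high"], 60),
                           "age": rng.normal(65, 10, 60)})
        res = association_tests(df, "group", ["age"])
        assert res.loc[0, "test"] == "t"
        a = df.loc[df.group == df.group.iloc[0], "age"]
        b = df.loc[df.group != df.group.iloc[0], "age"]
        assert res.loc[0, "p"] == pytest.approx(
            stats.ttest_ind(a, b, equal_var=True).pvalue, rel=1e-9)


class TestKmLogrank:
    def test_identical_groups_not_significant(self):
        times = np.tile(np.arange(1, 21.0), 2)
        events = np.ones(40, int)
        groups = np.repeat(["a", "b"], 20)
        out = km_logrank(times, events, groups)
        assert out["p"] == pytest.approx(1.0, abs=1e-9)

    def test_six_subject_toy_matches_oracle(self):
        times = np.arange(1, 7.0)
        events = np.ones(6, int)
        groups = np.array(["g0"] * 3 + ["g1"] * 3)
        out = km_logrank(times, events, groups)
        assert out["p"] == pytest.approx(0.0246023, abs=1e-6)

    def test_km_reduces_to_empirical_survival_without_censoring(self):
        times = np.array([1.0, 2, 3, 4, 5])
        events = np.ones(5, int)
        out = km_logrank(times, events, np.repeat("all", 5))
        sf = out["fitters"]["all"].survival_function_
        assert sf.loc[3.0].iloc[0] == pytest.approx(2 / 5)
        assert sf.loc[5.0].iloc[0] == pytest.approx(0.0)

    def test_single_group_returns_curves_only(self):
        out = km_logrank([1.0, 2, 3], [1, 1, 0], ["a", "a", "a"])
        assert out["p"] is None
        assert "a" in out["fitters"]


class TestCoxFit:
    def test_matches_analytic_partial_likelihood_on_tiny_data(self):
        # four subjects, one binary covariate, no ties: the score equation
        # has a root we can find independently of any survival library
        df = pd.DataFrame({"t": [1, 2, 3, 4], "e": [1, 1, 1, 1], "x": [1, 0, 1, 0]})

        def score(b):
            eb = math.exp(b)
            return (1 - 2 * eb / (2 * eb + 2)) - eb / (eb + 2) + (1 - eb / (eb + 1))

        beta_oracle = brentq(score, -5, 5)
        with pytest.warns(UserWarning):
            fit = cox_fit(df, "t", "e", ["x"])
        assert math.log(fit.loc[0, "hr"]) == pytest.approx(beta_oracle, abs=1e-4)

    def test_null_covariate_eliminated_backward(self):
        cohort = simulate_cohort(seed=5)
        cohort["high"] = (cohort["group"] == "high").astype(int)
        rng = np.random.default_rng(6)
        cohort["noise"] = rng.normal(size=len(cohort))
        fit = cox_fit(cohort, "pfs_time", "pfs_event", ["high", "noise"], backward=True)
        assert fit["covariate"].tolist() == ["high"]

    def test_null_covariate_hr_near_one(self):
        hrs = []
        for seed in range(20):
            cohort = simulate_cohort(n_low=150, n_high=150, hr_pfs=1.0,
                                     hr_os=1.0, seed=seed)
            rng = np.random.default_rng(seed)
            cohort["x"] = rng.binomial(1, 0.5, len(cohort))
            hrs.append(cox_fit(cohort, "os_time", "os_event", ["x"]).loc[0, "hr"])
        assert np.mean(hrs) == pytest.approx(1.0, abs=0.1)

    def test_large_sample_bias_below_five_percent(self):
        hrs = []
        for seed in range(10):
            cohort = simulate_cohort(n_low=500, n_high=500, hr_pfs=2.0, hr_os=2.0,
                                     censor_rate=0.3, seed=100 + seed)
            cohort["high"] = (cohort["group"] == "high").astype(int)
            hrs.append(cox_fit(cohort, "os_time", "os_event", ["high"]).loc[0, "hr"])
        assert abs(np.mean(hrs) / 2.0 - 1) < 0.05


class TestContalOQuigley:
    def test_two_point_marker_returns_single_interior_cut(self):
        rng = np.random.default_rng(1)
        marker = np.repeat([1.0, 2.0], 20)
        lam = np.where(marker > 1, 0.3, 0.1)
        times = rng.exponential(1 / lam)
        res = contal_oquigley(marker, times, np.ones(40, int), trim=0.0)
        assert res.cutpoint == 1.0
        assert res.candidates_evaluated == 1

    def test_equivariant_under_monotone_transform(self):
        d = simulate_cutpoint_cohort(seed=3)
        a = contal_oquigley(d["i_score"], d["time"], d["event"])
        b = contal_oquigley(np.exp(d["i_score"] / 2), d["time"], d["event"])
        assert b.cutpoint == pytest.approx(np.exp(a.cutpoint / 2), rel=1e-12)
        assert b.max_statistic == pytest.approx(a.max_statistic, rel=1e-12)

    def test_null_marker_stays_below_significance(self):
        # sup of the standardized statistic: 1.3581 is the 5% critical value
        # for the supremum over the full bridge; trimmed scans sit below it
        below = 0
        for seed in range(30):
            rng = np.random.default_rng(500 + seed)
            marker = rng.uniform(0, 1, 100)
            times = rng.exponential(10, 100)
            events = rng.binomial(1, 0.7, 100)
            res = contal_oquigley(marker, times, events)
            below += res.max_statistic < 1.3581
        assert below >= 27  # >= 90% of null replicates

    def test_planted_cut_recovered(self):
        cuts = [contal_oquigley(*(lambda d: (d["i_score"], d["time"], d["event"]))(
            simulate_cutpoint_cohort(seed=s))).cutpoint for s in range(20)]
        assert abs(np.median(cuts) - 7.3) < 0.2


class TestCIndex:
    def test_perfect_ordering(self):
        times = np.array([5.0, 4, 3, 2, 1])
        risk = np.array([1.0, 2, 3, 4, 5])  # highest risk dies first
        assert c_index(risk, times, np.ones(5, int)) == 1.0

    def test_random_predictions_near_half(self):
        rng = np.random.default_rng(7)
        vals = [c_index(rng.normal(size=200), rng.exponential(1, 200),
                        np.ones(200, int)) for _ in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_five_subject_pair_enumeration_oracle(self):
        times = np.array([2.0, 4, 3, 7, 5])
        events = np.array([1, 0, 1, 1, 0])
        risk = np.array([0.9, 0.1, 0.5, 0.2, 0.4])
        conc = disc = ties = 0
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                # pair comparable if the earlier time is an event
                if times[i] < times[j] and events[i]:
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        ties += 1
                    else:
                        disc += 1
        expected = (conc + 0.5 * ties) / (conc + disc + ties)
        assert c_index(risk, times, events) == pytest.approx(expected, rel=1e-12)


class TestFastLogrankAgainstLifelines:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines_with_censoring_and_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        times = np.round(rng.exponential(10, n), 0) + 1  # forces ties
        events = rng.binomial(1, 0.7, n)
        mask = rng.binomial(1, 0.4, n).astype(bool)
        ref = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
        chi2, p = RiskSets(times, events).statistic(mask)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_degenerate_masks_return_one(self):
        t = np.arange(1, 5.0)
        e = np.ones(4, int)
        assert logrank_p(t, e, np.ones(4, bool)) == 1.0
        assert logrank_p(t, e, np.zeros(4, bool)) == 1.0
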