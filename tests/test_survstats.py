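import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import cindex_bruteforce, cox_grid_hr, km_empirical, logistic_newton

from compera_bpa.errors import (
    DegenerateSample,
    GroupingError,
    ValidationError,
)
from compera_bpa.survstats import (
    fit_logistic,
    fit_proportional_hazards,
    harrell_c,
    km_estimate,
    logrank_test,
    spearman_corr,
)


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, size=40)
        km = km_estimate(t, np.ones(40, bool))
        S = km_empirical(t)
        for x in np.linspace(0, 40, 81):
            assert km.evaluate(x) == pytest.approx(S(x), abs=1e-12)
        assert km.evaluate(2.5) == pytest.approx(S(2.5))

    def test_four_events_midpoint(self):
        km = km_estimate([1, 2, 3, 4], [True] * 4)
        assert km.evaluate(2.5) == 0.5

    def test_all_censored_survival_is_one(self):
        km = km_estimate([3, 5, 9], [False, False, False])
        assert km.times.size == 0
        assert km.evaluate(100.0) == 1.0

    def test_hand_computed_product_limit(self):
        # subjects: events at 1, 3, 5, 6; censored at 2 and 4
        km = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 1])
        assert list(km.times) == [1, 3, 5, 6]
        assert km.survival == pytest.approx([5 / 6, 5 / 8, 5 / 16, 0.0])
        assert list(km.at_risk) == [6, 4, 2, 1]

    def test_curve_invariants(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(5, 60)
        e = rng.uniform(size=60) < 0.6
        if not e.any():
            e[0] = True
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        assert np.all(np.diff(km.at_risk) < 0)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = rng.exponential(8, 50).round(1) + 0.1
        e = rng.uniform(size=50) < 0.7
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx(kmf.predict(et), abs=1e-9)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([0.0, -1.0], [True, True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1] * 2
        g = ["a"] * 4 + ["b"] * 4
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_hand_computed_two_group(self):
        # separated groups, one event at each of t=1..6; O_A=3, E_A=1.15,
        # V=0.6775 -> chi2 = 1.85^2/0.6775
        res = logrank_test([1, 2, 3, 4, 5, 6], [1] * 6, list("AAABBB"))
        assert res.statistic == pytest.approx(1.85**2 / 0.6775, rel=1e-12)
        assert res.p_value == pytest.approx(0.0246, abs=1e-3)

    def test_three_groups_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(9)
        t = rng.exponential(10, 90)
        e = rng.uniform(size=90) < 0.7
        g = np.repeat(["x", "y", "z"], 30)
        res = logrank_test(t, e, g)
        ref = multivariate_logrank_test(pd.Series(t), pd.Series(g), pd.Series(e))
        assert res.df == 2
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(GroupingError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_permutation_null_uniform(self):
        """Permuting group labels makes the log-rank p-value uniform."""
        rng = np.random.default_rng(17)
        t = rng.exponential(10, 40)
        e = rng.uniform(size=40) < 0.7
        g = np.repeat(["a", "b"], 20)
        pvals = []
        for _ in range(1000):
            gp = rng.permutation(g)
            pvals.append(logrank_test(t, e, gp).p_value)
        from scipy import stats as sps

        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestHarrellC:
    def test_perfect_ordering(self):
        res = harrell_c([4, 3, 2, 1], [1, 1, 1, 1], [1, 2, 3, 4])
        assert res.c_index == 1.0
        assert res.usable_pairs == 6

    def test_constant_predictor_is_chance(self):
        res = harrell_c([1, 2, 3, 4], [1, 1, 1, 1], [5, 5, 5, 5])
        assert res.c_index == 0.5
        assert res.tied_predictions == res.usable_pairs

    def test_result_identity(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(5, 30).round(0) + 1
        e = rng.uniform(size=30) < 0.6
        x = rng.integers(1, 5, 30)
        res = harrell_c(t, e, x)
        assert res.usable_pairs == res.concordant + res.discordant + res.tied_predictions
        assert res.c_index == pytest.approx(
            (res.concordant + 0.5 * res.tied_predictions) / res.usable_pairs
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=150, deadline=None)
    def test_equals_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        t = rng.exponential(10, n).round(0) + 1  # rounded -> time ties occur
        e = rng.uniform(size=n) < 0.7
        x = rng.integers(1, 5, n).astype(float)
        try:
            expect = cindex_bruteforce(t, e, x)
        except ZeroDivisionError:
            with pytest.raises(DegenerateSample):
                harrell_c(t, e, x)
            return
        assert harrell_c(t, e, x).c_index == pytest.approx(expect, abs=1e-12)

    def test_antisymmetry_under_predictor_negation(self):
        rng = np.random.default_rng(31)
        t = rng.exponential(10, 40)
        e = rng.uniform(size=40) < 0.6
        x = rng.normal(size=40)
        c = harrell_c(t, e, x).c_index
        c_neg = harrell_c(t, e, -x).c_index
        assert c + c_neg == pytest.approx(1.0)

    def test_matches_lifelines_without_time_ties(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(41)
        t = rng.exponential(10, 60)  # continuous: no time ties
        e = rng.uniform(size=60) < 0.7
        x = rng.normal(size=60)
        c = harrell_c(t, e, x).c_index
        # lifelines orients the predictor the other way around
        assert c == pytest.approx(1.0 - concordance_index(t, x, e), abs=1e-12)

    def test_no_usable_pairs(self):
        with pytest.raises(DegenerateSample):
            harrell_c([5.0, 7.0], [False, False], [1.0, 2.0])


class TestSpearman:
    def test_identical_and_reversed(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_ties_match_scipy_midranks(self):
        from scipy import stats as sps

        x = [1, 2, 2, 3, 3, 3, 4]
        y = [2, 1, 4, 4, 5, 6, 6]
        assert spearman_corr(x, y) == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateSample):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestCox:
    @pytest.fixture()
    def binary_frame(self):
        rng = np.random.default_rng(7)
        n = 80
        x = np.repeat([0, 1], n // 2)
        t = rng.exponential(1.0 / (0.05 * np.exp(1.0 * x)))
        c = rng.uniform(5, 40, n)
        obs = t <= c
        return pd.DataFrame(
            {"time": np.minimum(t, c), "event": obs.astype(int), "grp": x + 1}
        )

    def test_binary_hr_matches_grid_search_oracle(self, binary_frame):
        tab = fit_proportional_hazards(binary_frame, "time", "event", "grp")
        hr = tab.loc[tab["level"] == 2, "hr"].item()
        oracle = cox_grid_hr(
            binary_frame["time"], binary_frame["event"].astype(bool),
            (binary_frame["grp"] == 2).astype(float),
        )
        assert hr == pytest.approx(oracle, rel=2e-3)

    def test_null_predictor_hr_near_one(self):
        rng = np.random.default_rng(13)
        n = 400
        df = pd.DataFrame(
            {
                "time": rng.exponential(10, n),
                "event": (rng.uniform(size=n) < 0.7).astype(int),
                "grp": rng.integers(1, 3, n),
            }
        )
        tab = fit_proportional_hazards(df, "time", "event", "grp")
        assert tab.loc[tab["level"] == 2, "hr"].item() == pytest.approx(1.0, abs=0.25)

    def test_zero_event_level_flagged_not_estimated(self):
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 5, 6, 7, 8],
                "event": [1, 1, 1, 0, 1, 1, 0, 0],
                "grp": [1, 1, 1, 2, 2, 2, 3, 3],  # level 3: no events
            }
        )
        tab = fit_proportional_hazards(df, "time", "event", "grp").set_index("level")
        assert not tab.loc[3, "estimable"]
        assert np.isnan(tab.loc[3, "hr"])
        assert tab.loc[1, "reference"] and tab.loc[1, "hr"] == 1.0

    def test_epv_violation_warns(self):
        few = pd.DataFrame(
            {
                "time": [1, 2, 3, 4, 5, 6],
                "event": [1, 1, 1, 0, 0, 0],
                "grp": [1, 2, 1, 2, 1, 2],
            }
        )
        with pytest.warns(UserWarning, match="event-per-variable"):
            fit_proportional_hazards(few, "time", "event", "grp")


class TestLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        # contingency: exposed 30/20, unexposed 10/40 -> OR = (30*40)/(20*10)
        rows = (
            [{"y": 1, "g": 2}] * 30 + [{"y": 0, "g": 2}] * 20
            + [{"y": 1, "g": 1}] * 10 + [{"y": 0, "g": 1}] * 40
        )
        tab = fit_logistic(pd.DataFrame(rows), "y", "g").set_index("level")
        assert tab.loc[2, "odds_ratio"] == pytest.approx(6.0, rel=1e-6)

    def test_balanced_null_or_near_one(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame(
            {"y": rng.integers(0, 2, 600), "g": rng.integers(1, 3, 600)}
        )
        tab = fit_logistic(df, "y", "g").set_index("level")
        assert tab.loc[2, "odds_ratio"] == pytest.approx(1.0, abs=0.35)

    def test_three_level_matches_newton_oracle(self):
        rng = np.random.default_rng(29)
        n = 300
        g = rng.integers(1, 4, n)
        logit = -1.0 + 0.8 * (g == 2) + 1.5 * (g == 3)
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
        tab = fit_logistic(pd.DataFrame({"y": y, "g": g}), "y", "g").set_index("level")
        X = np.column_stack([np.ones(n), g == 2, g == 3]).astype(float)
        beta = logistic_newton(X, y.astype(float))
        assert tab.loc[2, "odds_ratio"] == pytest.approx(np.exp(beta[1]), rel=1e-6)
        assert tab.loc[3, "odds_ratio"] == pytest.approx(np.exp(beta[2]), rel=1e-6)

    def test_separated_level_flagged(self):
        rows = (
            [{"y": 1, "g": 1}] * 5 + [{"y": 0, "g": 1}] * 5
            + [{"y": 1, "g": 2}] * 6 + [{"y": 0, "g": 2}] * 4
            + [{"y": 1, "g": 3}] * 7  # all events -> separation
        )
        tab = fit_logistic(pd.DataFrame(rows), "y", "g").set_index("level")
        assert not tab.loc[3, "estimable"]
        assert np.isnan(tab.loc[3, "odds_ratio"])
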