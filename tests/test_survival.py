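"""Cox fit oracles, risk-score arithmetic, KM product-limit, log-rank."""

import numpy as np
import pandas as pd
import pytest

from cerna_icb.survival import (
    CoxRiskScore,
    compute_risk_score,
    fit_univariate_cox,
    km_curve,
    logrank_test,
    stratify,
)


def cox_partial_loglik(beta, x, times, events):
    """Independent brute-force partial log-likelihood (no ties)."""
    ll = 0.0
    for i in range(len(x)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(x)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


class TestUnivariateCox:
    def test_four_patient_case_matches_grid_maximization(self):
        x = np.array([0.5, -1.0, 2.0, 0.0])
        times = np.array([2.0, 5.0, 1.0, 7.0])
        events = np.array([1, 1, 1, 1])
        fit = fit_univariate_cox(x, times, events)
        grid = np.linspace(-4, 4, 8001)
        ll = [cox_partial_loglik(b, x, times, events) for b in grid]
        best = grid[int(np.argmax(ll))]
        assert fit["coef"] == pytest.approx(best, abs=2e-3)

    def test_constant_expression_untestable(self):
        fit = fit_univariate_cox(
            np.ones(6), np.arange(1.0, 7.0), np.ones(6, dtype=int)
        )
        assert fit["flag"] == "untestable"
        assert fit["coef"] == 0.0

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(ValueError, match="two events"):
            fit_univariate_cox(np.arange(4.0), np.arange(1.0, 5.0),
                               np.array([1, 0, 0, 0]))

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 60
        x = rng.normal(size=n)
        t = np.round(rng.exponential(1 / (0.1 * np.exp(0.8 * x))), 1) + 0.1
        e = (rng.random(n) > 0.3).astype(int)
        fit = fit_univariate_cox(x, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
        )
        assert fit["coef"] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert fit["se"] == pytest.approx(
            cph.standard_errors_.iloc[0], abs=1e-6
        )

    def test_permuted_covariate_estimates_center_on_zero(self):
        rng = np.random.default_rng(0)
        n = 100
        t = rng.exponential(10, size=n)
        e = (rng.random(n) > 0.3).astype(int)
        x = rng.normal(size=n)
        coefs = []
        for _ in range(100):
            xp = rng.permutation(x)
            coefs.append(fit_univariate_cox(xp, t, e)["coef"])
        assert abs(np.mean(coefs)) < 0.1

    def test_separation_capped_and_flagged(self):
        # covariate perfectly orders the event times
        x = np.array([3.0, 2.0, 1.0, 0.0, -1.0, -2.0])
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.ones(6, dtype=int)
        fit = fit_univariate_cox(x, t, e)
        assert fit["flag"] == "separation"
        assert abs(fit["coef"]) == pytest.approx(10.0)


class TestRiskScore:
    def test_zero_coefficients_zero_scores(self):
        expr = pd.DataFrame(np.ones((3, 4)), index=list("abc"),
                            columns=list("wxyz"))
        scores = compute_risk_score(expr, pd.Series(0.0, index=list("abc")))
        assert (scores == 0).all()

    def test_single_feature_product(self):
        expr = pd.DataFrame([[3.0]], index=["f"], columns=["p"])
        scores = compute_risk_score(expr, pd.Series({"f": 2.0}))
        assert scores["p"] == pytest.approx(6.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(5, 7)),
                            index=[f"f{i}" for i in range(5)],
                            columns=[f"p{j}" for j in range(7)])
        coef = pd.Series(rng.normal(size=5), index=expr.index)
        scores = compute_risk_score(expr, coef)
        for p in expr.columns:
            expected = sum(expr.loc[f, p] * coef[f] for f in expr.index)
            assert scores[p] == pytest.approx(expected)

    def test_missing_feature_names_it(self):
        expr = pd.DataFrame([[1.0]], index=["f"], columns=["p"])
        with pytest.raises(ValueError, match="ghost"):
            compute_risk_score(expr, pd.Series({"ghost": 1.0}))

    def test_coefficient_scaling_preserves_stratification(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(4, 8)),
                            index=[f"f{i}" for i in range(4)],
                            columns=[f"p{j}" for j in range(8)])
        coef = pd.Series(rng.normal(size=4), index=expr.index)
        s1 = compute_risk_score(expr, coef)
        s2 = compute_risk_score(expr, 3.0 * coef)
        assert np.allclose(3.0 * s1, s2)
        g1, _ = stratify(s1)
        g2, _ = stratify(s2)
        pd.testing.assert_series_equal(g1, g2)


class TestStratify:
    def test_even_median_split(self):
        g, cut = stratify(pd.Series({"a": 1, "b": 2, "c": 3, "d": 4}))
        assert cut == 2.5
        assert list(g) == ["low", "low", "high", "high"]

    def test_odd_median_patient_goes_low(self):
        g, _ = stratify(pd.Series({"a": 1, "b": 2, "c": 3}))
        assert g["b"] == "low"

    def test_identical_scores_error(self):
        with pytest.raises(ValueError, match="identical"):
            stratify(pd.Series([1.0, 1.0, 1.0]))

    def test_matches_brute_force_median_comparison(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=11),
                           index=[f"p{i}" for i in range(11)])
        g, cut = stratify(scores)
        med = float(np.median(scores))
        assert cut == med
        for p in scores.index:
            assert g[p] == ("high" if scores[p] > med else "low")

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=10),
                           index=[f"p{i}" for i in range(10)])
        g1, _ = stratify(scores)
        g2, _ = stratify(np.exp(scores))
        pd.testing.assert_series_equal(g1, g2)


class TestKaplanMeier:
    def test_three_deaths_no_censoring(self):
        km = km_curve([1, 2, 3], [1, 1, 1], ["g"] * 3)["g"]
        surv = km["survival"].set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_curve_median_unreached(self):
        km = km_curve([5, 6, 7], [0, 0, 0], ["g"] * 3)["g"]
        assert (km["survival"]["survival"] == 1.0).all()
        assert np.isinf(km["median"])

    def test_five_observation_hand_product_limit(self):
        # deaths at 1, 3, 4; censor at 2
        km = km_curve([1, 2, 3, 4, 6], [1, 0, 1, 1, 0], ["g"] * 5)["g"]
        surv = km["survival"].set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(4 / 5)
        assert surv.loc[3.0] == pytest.approx(4 / 5 * 2 / 3)
        assert surv.loc[4.0] == pytest.approx(4 / 5 * 2 / 3 * 1 / 2)

    def test_curve_monotone_from_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, 40)
        e = (rng.random(40) > 0.3).astype(int)
        km = km_curve(t, e, ["g"] * 40)["g"]
        s = km["survival"]["survival"].to_numpy()
        assert s[0] <= 1.0 + 1e-12
        assert np.all(np.diff(s) <= 1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 1, 1]
        stat, p = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_computed_o_minus_e(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 1, 1])
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        # brute-force O-E and hypergeometric variance per event time
        o_minus_e = 0.0
        var = 0.0
        for tt in times:
            at_risk = times >= tt
            n = at_risk.sum()
            n_a = (at_risk & (groups == "a")).sum()
            d = (times == tt).sum()
            d_a = ((times == tt) & (groups == "a")).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / var
        stat, _ = logrank_test(times, events, groups)
        assert stat == pytest.approx(expected, rel=1e-6)

    def test_invariant_to_label_swap(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 30)
        e = (rng.random(30) > 0.2).astype(int)
        g = np.array(["a"] * 15 + ["b"] * 15)
        s1, p1 = logrank_test(t, e, g)
        swapped = np.where(g == "a", "b", "a")
        s2, p2 = logrank_test(t, e, swapped)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestCoxRiskScoreEstimator:
    def test_small_sample_warning_when_features_exceed_patients(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 10)),
                         index=[f"f{i}" for i in range(20)],
                         columns=[f"p{j}" for j in range(10)])
        t = rng.exponential(10, 10)
        e = np.ones(10, dtype=int)
        with pytest.warns(UserWarning, match="unstable"):
            CoxRiskScore().fit(X, t, e)

    def test_end_to_end_recovery_on_strong_signal(self):
        """A one-feature signature driving an exponential hazard yields a
        clearly separated high/low split at n=100."""
        rng = np.random.default_rng(7)
        n = 100
        signal = rng.normal(size=n)
        t = rng.exponential(1 / (0.05 * np.exp(1.0 * signal)))
        e = np.ones(n, dtype=int)
        X = pd.DataFrame([signal], index=["sig"],
                         columns=[f"p{j}" for j in range(n)])
        model = CoxRiskScore().fit(X, t, e)
        assert model.coef_["sig"] == pytest.approx(1.0, abs=0.3)
        ev = model.evaluate(t, e)
        assert ev["logrank_p"] < 0.01
        assert ev["km"]["high"]["median"] < ev["km"]["low"]["median"]

    def test_predict_reuses_training_normalization(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(3, 30)),
                         index=["a", "b", "c"],
                         columns=[f"p{j}" for j in range(30)])
        t = rng.exponential(10, 30)
        e = (rng.random(30) > 0.3).astype(int)
        model = CoxRiskScore().fit(X, t, e)
        pd.testing.assert_series_equal(
            model.predict(X), model.risk_scores_, check_names=False
        )
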