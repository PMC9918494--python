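import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from immureg.io_formats import SurvivalTable
from immureg.prognosis import (
    RiskModel,
    breslow_partial_loglik,
    fit_lasso_cox,
    kaplan_meier,
    logrank,
    risk_score,
    score_samples,
    stratify_by_median,
    time_dependent_auc,
)


def _surv(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame({"time": times, "event": events}, index=ids))


def _sim_cohort(seed, coef, n=200, p_noise=10):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    cols = ["x1"] + [f"z{i}" for i in range(p_noise)]
    X = pd.DataFrame(rng.standard_normal((n, len(cols))), index=ids, columns=cols)
    t_true = rng.exponential(1000 * np.exp(-coef * X["x1"].to_numpy()))
    censor = rng.uniform(1, 2500, n)
    return X, _surv(
        np.maximum(np.minimum(t_true, censor), 1.0),
        (t_true <= censor).astype(int), ids,
    )


class TestRiskScore:
    # the fitted Cluster-1 risk model coefficients (ETS1, YY1)
    MODEL = RiskModel(
        features=["ETS1", "YY1"],
        zeta={"ETS1": 2.1940e-4, "YY1": 3.1814e-4},
        zeta_std={}, lambda_=0.0, train_fraction=0.7, seed=0,
    )

    def test_unit_expressions_reproduce_hand_sum(self):
        score = risk_score(self.MODEL, {"ETS1": 1.0, "YY1": 1.0})
        assert score == pytest.approx(5.3754e-4, rel=1e-12)

    def test_zero_expression_scores_zero(self):
        assert risk_score(self.MODEL, {"ETS1": 0.0, "YY1": 0.0}) == 0.0

    def test_linearity_in_expression(self):
        rng = np.random.default_rng(0)
        a = {"ETS1": rng.normal(), "YY1": rng.normal()}
        b = {"ETS1": rng.normal(), "YY1": rng.normal()}
        ab = {k: a[k] + b[k] for k in a}
        assert risk_score(self.MODEL, ab) == pytest.approx(
            risk_score(self.MODEL, a) + risk_score(self.MODEL, b)
        )

    def test_missing_feature_named_in_error(self):
        with pytest.raises(KeyError, match="YY1"):
            risk_score(self.MODEL, {"ETS1": 1.0})


class TestStratification:
    def test_even_split_at_median(self):
        groups = stratify_by_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_odd_n_median_sample_goes_low(self):
        groups = stratify_by_median(pd.Series([5.0, 1.0, 3.0, 2.0, 4.0]))
        assert (groups == "low").sum() == 3 and (groups == "high").sum() == 2

    def test_all_equal_scores_all_low_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="immureg"):
            groups = stratify_by_median(pd.Series([2.0, 2.0, 2.0]))
        assert (groups == "low").all()


class TestKaplanMeier:
    def test_all_events_no_censoring_product_limit(self):
        fit = kaplan_meier(_surv([1.0, 2.0, 3.0], [1, 1, 1]))
        np.testing.assert_allclose(fit.times, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(fit.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_reduces_risk_set(self):
        # events at 1 and 3, censored at 2: S(1)=2/3, S(3)=0
        fit = kaplan_meier(_surv([1.0, 2.0, 3.0], [1, 0, 1]))
        np.testing.assert_allclose(fit.times, [1.0, 3.0])
        np.testing.assert_allclose(fit.survival, [2 / 3, 0.0])

    def test_no_events_keeps_survival_at_one(self):
        fit = kaplan_meier(_surv([5.0, 7.0], [0, 0]))
        assert fit.survival_at(10.0) == 1.0

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(10, 50)
        fit = kaplan_meier(_surv(times, np.ones(50, dtype=int)))
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            assert fit.survival_at(t) == pytest.approx((times > t).mean())


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        stat, p = logrank(g, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_returns_unit_p_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="immureg"):
            stat, p = logrank(_surv([1.0, 2.0], [0, 0]), _surv([3.0], [0]))
        assert (stat, p) == (0.0, 1.0)

    def test_separated_exponentials_strongly_significant(self):
        rng = np.random.default_rng(2)
        fast = _surv(rng.exponential(1.0, 100), np.ones(100, int),
                     [f"a{i}" for i in range(100)])
        slow = _surv(rng.exponential(5.0, 100), np.ones(100, int),
                     [f"b{i}" for i in range(100)])
        _, p = logrank(fast, slow)
        assert p < 1e-3

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(3)
        times = np.concatenate([rng.exponential(1.0, 12), rng.exponential(2.5, 12)])
        events = np.ones(24, int)
        a = _surv(times[:12], events[:12], [f"a{i}" for i in range(12)])
        b = _surv(times[12:], events[12:], [f"b{i}" for i in range(12)])
        stat_obs, p_chi2 = logrank(a, b)
        perm_ge = 0
        n_perm = 400
        for _ in range(n_perm):
            idx = rng.permutation(24)
            pa = _surv(times[idx[:12]], events[idx[:12]], [f"a{i}" for i in range(12)])
            pb = _surv(times[idx[12:]], events[idx[12:]], [f"b{i}" for i in range(12)])
            stat, _ = logrank(pa, pb)
            perm_ge += stat >= stat_obs
        p_perm = (perm_ge + 1) / (n_perm + 1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_chi2 - p_perm) < max(mc_err, 0.02)


class TestBreslowLoglik:
    def test_single_covariate_mle_matches_newton_oracle(self):
        """Maximizing the Breslow likelihood matches lifelines' unpenalized Cox."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 80
        x = rng.standard_normal(n)
        t_true = rng.exponential(np.exp(-0.8 * x))
        censor = rng.uniform(0.1, 3.0, n)
        time = np.minimum(t_true, censor)
        event = (t_true <= censor).astype(float)
        res = minimize_scalar(
            lambda b: -breslow_partial_loglik(b * x, time, event),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        df = pd.DataFrame({"t": time, "e": event, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.x == pytest.approx(float(cph.params_["x"]), abs=1e-5)

    def test_tied_event_times_use_full_risk_set(self):
        eta = np.array([0.5, -0.5, 0.0, 1.0])
        time = np.array([1.0, 1.0, 2.0, 3.0])
        event = np.array([1.0, 1.0, 0.0, 1.0])
        lse_all = np.log(np.exp(eta).sum())
        expected = (eta[0] - lse_all) + (eta[1] - lse_all) + (eta[3] - eta[3])
        assert breslow_partial_loglik(eta, time, event) == pytest.approx(expected)


class TestLassoCox:
    def test_planted_prognostic_feature_recovered(self):
        hits = 0
        for s in range(15):
            X, surv = _sim_cohort(s, coef=1.0)
            model = fit_lasso_cox(X, surv, seed=s)
            hits += "x1" in model.features and model.zeta_std["x1"] > 0
        assert hits >= 14

    def test_pure_noise_feature_shrunk_to_zero(self):
        ok = 0
        for s in range(15):
            X, surv = _sim_cohort(100 + s, coef=0.0, p_noise=0)
            model = fit_lasso_cox(X[["x1"]], surv, seed=s)
            ok += abs(model.zeta_std.get("x1", 0.0)) < 0.1
        assert ok >= 14

    def test_penalty_above_lambda_max_gives_empty_model(self):
        X, surv = _sim_cohort(7, coef=1.0)
        model = fit_lasso_cox(X, surv, lambda_grid=[1e4, 5e3], seed=0)
        assert model.features == []

    def test_no_events_rejected(self):
        X, _ = _sim_cohort(8, coef=0.0)
        surv = _surv(np.full(200, 100.0), np.zeros(200, int), list(X.index))
        with pytest.raises(ValueError, match="event"):
            fit_lasso_cox(X, surv, seed=0)

    def test_score_samples_matches_risk_score(self):
        X, surv = _sim_cohort(9, coef=1.0)
        model = fit_lasso_cox(X, surv, seed=1)
        if not model.features:
            pytest.skip("empty model for this draw")
        scores = score_samples(model, X)
        one = X.iloc[3]
        assert scores.iloc[3] == pytest.approx(risk_score(model, one.to_dict()))


class TestTimeDependentAUC:
    def test_perfect_ranking_gives_unit_auc(self):
        rng = np.random.default_rng(5)
        times = rng.uniform(1, 100, 60)
        surv = _surv(times, np.ones(60, int))
        scores = pd.Series(-times, index=surv.sample_ids)
        auc = time_dependent_auc(scores, surv, np.quantile(times, [0.3, 0.5, 0.7]))
        assert all(a == pytest.approx(1.0) for a in auc.values())

    def test_uninformative_score_near_half(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(50, 400)
        surv = _surv(times, np.ones(400, int))
        scores = pd.Series(rng.standard_normal(400), index=surv.sample_ids)
        auc = time_dependent_auc(scores, surv, [np.median(times)])
        assert abs(next(iter(auc.values())) - 0.5) < 0.1

    def test_sign_reversal_maps_auc_to_complement(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(50, 100)
        surv = _surv(times, np.ones(100, int))
        scores = pd.Series(-times + rng.normal(0, 10, 100), index=surv.sample_ids)
        t_eval = [float(np.median(times))]
        auc = time_dependent_auc(scores, surv, t_eval)
        auc_rev = time_dependent_auc(-scores, surv, t_eval)
        assert next(iter(auc.values())) == pytest.approx(
            1.0 - next(iter(auc_rev.values())), abs=1e-9
        )

    def test_times_outside_followup_dropped(self, caplog):
        surv = _surv([10.0, 20.0, 30.0], [1, 1, 1])
        scores = pd.Series([3.0, 2.0, 1.0], index=surv.sample_ids)
        with caplog.at_level("WARNING", logger="immureg"):
            auc = time_dependent_auc(scores, surv, [5.0, 15.0, 500.0])
        assert set(auc) == {15.0}
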