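import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from lncfuse.estimators import (
    CoxRiskModel,
    LassoCoxSelector,
    RSFImportanceSelector,
    UnivariateCoxSelector,
    breslow_loglik,
    cox_score_test,
)
from lncfuse.simulate import simulate_survival
from lncfuse.survival import (
    SurvivalTable,
    assign_risk,
    independence_cox,
    km_curve,
    lasso_cox_select,
    multivariate_cox,
    risk_scores,
    split_cohort,
    univariate_cox_screen,
)


def _expr(n, p, seed=0, prefix="LNC"):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(p, n)),
        index=[f"{prefix}{i}" for i in range(p)],
        columns=[f"s{j}" for j in range(n)],
    )


def _surv_table(expr, surv):
    return SurvivalTable(
        expression=expr.T,
        os_days=surv["os_days"],
        event=surv["event"].astype(int),
    )


class TestScoreTest:
    def test_null_pvalues_roughly_uniform(self):
        expr = _expr(200, 40, seed=1)
        surv = simulate_survival(expr.iloc[:1] * 0, pd.Series(dtype=float), censor_rate=0.2, seed=1)
        _, p = cox_score_test(expr.T.to_numpy(), surv["os_days"].to_numpy(), surv["event"].to_numpy(dtype=bool))
        assert 0.01 < np.mean(p < 0.05) < 0.12

    def test_agrees_with_lifelines_wald_on_strong_signal(self):
        from lifelines import CoxPHFitter

        expr = _expr(150, 1, seed=2)
        beta = pd.Series({"LNC0": 0.8})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=2)
        chi2, p = cox_score_test(
            expr.T.to_numpy(), surv["os_days"].to_numpy(), surv["event"].to_numpy(dtype=bool)
        )
        df = pd.DataFrame({"x": expr.iloc[0], "t": surv["os_days"], "e": surv["event"]})
        cph = CoxPHFitter().fit(df, "t", "e")
        wald_p = cph.summary.loc["x", "p"]
        assert (p[0] < 0.01) == (wald_p < 0.01)
        assert abs(np.log10(p[0] + 1e-300) - np.log10(wald_p + 1e-300)) < 2


class TestBreslowLoglik:
    def test_hand_computed_two_samples(self):
        # events at t=1 (eta a) then t=2 (eta b):
        # ll = a - log(e^a + e^b) + b - log(e^b)
        eta = np.array([0.5, -0.3])
        ll = breslow_loglik(eta, [1.0, 2.0], [True, True])
        expected = 0.5 - np.log(np.exp(0.5) + np.exp(-0.3)) + (-0.3) - np.log(np.exp(-0.3))
        assert ll[0] == pytest.approx(expected)

    def test_zero_eta_closed_form(self):
        # all events, no ties, eta=0: ll = -sum log(n-i+1) = -log(n!)
        n = 5
        ll = breslow_loglik(np.zeros(n), np.arange(1, n + 1, dtype=float), np.ones(n, bool))
        assert ll[0] == pytest.approx(-np.sum(np.log(np.arange(1, n + 1))))


class TestUnivariateScreen:
    def test_planted_feature_retained(self):
        expr = _expr(300, 20, seed=3)
        beta = pd.Series({"LNC0": 1.0})
        surv = simulate_survival(expr, beta, censor_rate=0.3, seed=3)
        hits = univariate_cox_screen(_surv_table(expr, surv), list(expr.index))
        assert "LNC0" in hits

    def test_null_retention_near_alpha(self):
        rates = []
        for seed in range(30):
            expr = _expr(120, 20, seed=seed + 100)
            surv = simulate_survival(expr.iloc[:1] * 0, pd.Series(dtype=float), censor_rate=0.2, seed=seed)
            hits = univariate_cox_screen(_surv_table(expr, surv), list(expr.index))
            rates.append(len(hits) / 20)
        assert abs(np.mean(rates) - 0.05) < 0.03

    def test_empty_candidates(self):
        expr = _expr(50, 3, seed=4)
        surv = simulate_survival(expr.iloc[:1] * 0, pd.Series(dtype=float), seed=4)
        assert univariate_cox_screen(_surv_table(expr, surv), []) == []

    def test_constant_feature_warns_not_raises(self):
        expr = _expr(60, 3, seed=5)
        expr.iloc[0] = 1.0
        surv = simulate_survival(expr.iloc[1:2] * 0, pd.Series(dtype=float), seed=5)
        with pytest.warns(UserWarning, match="constant"):
            hits = univariate_cox_screen(_surv_table(expr, surv), list(expr.index))
        assert "LNC0" not in hits


class TestRSFScreen:
    def _fit(self, seed=11, thresh=9.0):
        expr = _expr(150, 20, seed=6)
        beta = pd.Series({"LNC0": 1.5})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=6)
        sel = RSFImportanceSelector(
            importance_threshold=thresh, n_trees=100, n_repeats=2, random_state=seed
        )
        sel.fit(expr.T, (surv["os_days"].to_numpy(), surv["event"].to_numpy()))
        return sel

    def test_planted_feature_ranks_high(self):
        sel = self._fit()
        rank = np.argsort(-sel.importances_)
        assert np.where(sel.feature_names_in_[rank] == "LNC0")[0][0] < 2

    def test_threshold_above_max_gives_empty(self):
        sel = self._fit(thresh=1e9)
        assert sel.selected_features_ == []

    def test_deterministic_under_seed(self):
        a, b = self._fit(seed=11), self._fit(seed=11)
        np.testing.assert_array_equal(a.importances_, b.importances_)

    def test_invalid_tree_count_errors(self):
        expr = _expr(30, 2, seed=7)
        surv = simulate_survival(expr.iloc[:1] * 0, pd.Series(dtype=float), seed=7)
        sel = RSFImportanceSelector(n_trees=0)
        with pytest.raises(ValueError):
            sel.fit(expr.T, (surv["os_days"].to_numpy(), surv["event"].to_numpy()))


class TestLassoSelect:
    def test_strong_feature_selected(self):
        expr = _expr(250, 10, seed=8)
        beta = pd.Series({"LNC0": 1.2})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=8)
        sel = lasso_cox_select(_surv_table(expr, surv), list(expr.index), seed=8)
        assert "LNC0" in sel

    def test_huge_penalty_selects_nothing(self):
        expr = _expr(100, 5, seed=9)
        beta = pd.Series({"LNC0": 1.0})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=9)
        sel = LassoCoxSelector(alpha=1e6)
        with pytest.warns(UserWarning, match="coefficients are zero"):
            sel.fit(expr.T, (surv["os_days"].to_numpy(), surv["event"].to_numpy()))
        assert sel.selected_features_ == []

    def test_deterministic_under_seed(self):
        expr = _expr(150, 8, seed=10)
        beta = pd.Series({"LNC0": 0.8, "LNC3": -0.8})
        surv = simulate_survival(expr, beta, censor_rate=0.3, seed=10)
        st = _surv_table(expr, surv)
        assert lasso_cox_select(st, list(expr.index), seed=5) == lasso_cox_select(
            st, list(expr.index), seed=5
        )

    def test_too_few_events_errors(self):
        expr = _expr(20, 3, seed=11)
        y = (np.full(20, 100.0), np.zeros(20))
        sel = LassoCoxSelector()
        with pytest.raises(ValueError, match="events"):
            sel.fit(expr.T, y)


class TestMultivariateCox:
    def test_recovers_unit_coefficient(self):
        expr = _expr(500, 1, seed=12)
        beta = pd.Series({"LNC0": 1.0})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=12)
        model = multivariate_cox(_surv_table(expr, surv), ["LNC0"])
        assert model.coef_["LNC0"] == pytest.approx(1.0, abs=0.2)

    def test_sign_recovery_six_features(self):
        expr = _expr(400, 6, seed=13)
        truth = pd.Series(
            {"LNC0": 0.5, "LNC1": 0.5, "LNC2": 0.5, "LNC3": -0.5, "LNC4": 0.5, "LNC5": -0.5}
        )
        surv = simulate_survival(expr, truth, censor_rate=0.2, seed=13)
        model = multivariate_cox(_surv_table(expr, surv), list(truth.index))
        assert set(model.signature_) == set(truth.index)
        assert (np.sign(model.coef_[truth.index]) == np.sign(truth)).all()

    def test_single_noise_feature_gives_empty_signature(self):
        expr = _expr(100, 2, seed=14)
        surv = simulate_survival(expr.iloc[:1] * 0, pd.Series(dtype=float), seed=14)
        model = multivariate_cox(_surv_table(expr, surv), ["LNC1"])
        p = model.summary_["p"].iloc[0]
        assert (len(model.signature_) == 0) == (p >= 0.05)

    def test_collinear_duplicates_error_names_pair(self):
        expr = _expr(80, 2, seed=15)
        expr.iloc[1] = expr.iloc[0]
        surv = simulate_survival(expr.iloc[:1] * 0, pd.Series(dtype=float), seed=15)
        with pytest.raises(ValueError, match="LNC0 and LNC1"):
            multivariate_cox(_surv_table(expr, surv), ["LNC0", "LNC1"])

    def test_sklearn_clone_compatible(self):
        model = CoxRiskModel(drop_p=0.7)
        cloned = clone(model)
        assert cloned.get_params()["drop_p"] == 0.7
        sel = clone(UnivariateCoxSelector(p_threshold=0.1))
        assert sel.get_params() == {"p_threshold": 0.1}
        assert "rule" in clone(LassoCoxSelector()).get_params()


class TestRiskScores:
    def _model(self):
        return CoxRiskModel.from_coefficients({"a": 0.5, "b": -0.25})

    def test_zero_expression_zero_score(self):
        model = self._model()
        X = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        assert (risk_scores(model, X) == 0).all()

    def test_linearity(self):
        model = self._model()
        rng = np.random.default_rng(16)
        X1 = pd.DataFrame(rng.normal(size=(4, 2)), columns=["a", "b"])
        X2 = pd.DataFrame(rng.normal(size=(4, 2)), columns=["a", "b"])
        np.testing.assert_allclose(
            risk_scores(model, X1 + X2), risk_scores(model, X1) + risk_scores(model, X2)
        )

    def test_missing_feature_errors(self):
        model = self._model()
        with pytest.raises(ValueError, match="lacks"):
            risk_scores(model, pd.DataFrame({"a": [1.0]}))


class TestAssignRisk:
    def test_median_default(self):
        levels = assign_risk(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(levels) == ["low", "low", "high", "high"]

    def test_tie_at_cutoff_is_high(self):
        levels = assign_risk(pd.Series([1.0, 2.0, 3.0]), cut_off=2.0)
        assert list(levels) == ["low", "high", "high"]

    def test_matches_entrywise_comparison(self):
        rng = np.random.default_rng(17)
        s = pd.Series(rng.normal(size=101))
        levels = assign_risk(s)
        med = np.median(s)
        np.testing.assert_array_equal(levels.to_numpy(), np.where(s >= med, "high", "low"))


class TestKMCurve:
    def test_no_events_survival_stays_one(self):
        curves, _, _ = km_curve([5, 6, 7], [0, 0, 0], ["g", "g", "g"])
        assert (curves["g"]["survival"] == 1.0).all()

    def test_hand_product_limit_three_events(self):
        curves, _, _ = km_curve([1, 2, 3], [1, 1, 1], ["g"] * 3)
        surv = curves["g"].set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_identical_groups_logrank_p_one(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 0, 1, 1, 0]
        times = t + t
        events = e + e
        groups = ["a"] * 5 + ["b"] * 5
        _, stat, p = km_curve(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_km_matches_brute_force_product_limit(self):
        rng = np.random.default_rng(18)
        t = rng.integers(1, 20, size=40).astype(float)
        e = rng.integers(0, 2, size=40)
        curves, _, _ = km_curve(t, e, ["g"] * 40)
        surv = curves["g"].set_index("time")["survival"]
        # brute force product-limit
        s = 1.0
        for tau in sorted(set(t)):
            at_risk = np.sum(t >= tau)
            deaths = np.sum((t == tau) & (e == 1))
            s *= 1 - deaths / at_risk
            assert surv.loc[tau] == pytest.approx(s)

    def test_zero_sample_group_errors(self):
        with pytest.raises(ValueError):
            km_curve([], [], [])


class TestIndependence:
    def test_risk_only_significant_when_clinical_is_noise(self):
        rng = np.random.default_rng(19)
        expr = _expr(400, 1, seed=20)
        beta = pd.Series({"LNC0": 1.0})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=20)
        clinical = pd.DataFrame(
            {
                "age": rng.integers(40, 80, size=400),
                "gender": rng.integers(0, 2, size=400),
                "stage": rng.integers(1, 5, size=400),
            },
            index=expr.columns,
        )
        risk = pd.Series(surv["true_lp"].to_numpy(), index=expr.columns)
        uni, multi = independence_cox(
            (surv["os_days"].to_numpy(), surv["event"].to_numpy()), risk, clinical
        )
        assert multi.loc["risk_score", "p"] < 0.01
        assert (multi.drop(index="risk_score")["p"] > 0.05).all()
        assert uni.loc["risk_score", "p"] < 0.01

    def test_empty_clinical_returns_risk_row_only(self):
        expr = _expr(150, 1, seed=21)
        beta = pd.Series({"LNC0": 1.0})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=21)
        risk = pd.Series(surv["true_lp"].to_numpy(), index=expr.columns)
        uni, multi = independence_cox(
            (surv["os_days"].to_numpy(), surv["event"].to_numpy()),
            risk,
            pd.DataFrame(index=expr.columns),
        )
        assert list(uni.index) == ["risk_score"]
        assert list(multi.index) == ["risk_score"]

    def test_confounded_stage_attenuates_risk(self):
        expr = _expr(400, 1, seed=22)
        beta = pd.Series({"LNC0": 1.0})
        surv = simulate_survival(expr, beta, censor_rate=0.2, seed=22)
        risk = pd.Series(surv["true_lp"].to_numpy(), index=expr.columns)
        # stage nearly collinear with risk
        rng = np.random.default_rng(23)
        stage = pd.Series(
            np.digitize(risk + rng.normal(scale=0.1, size=400), np.quantile(risk, [0.25, 0.5, 0.75])) + 1,
            index=expr.columns,
        )
        y = (surv["os_days"].to_numpy(), surv["event"].to_numpy())
        _, multi_conf = independence_cox(y, risk, pd.DataFrame({"stage": stage}))
        rng2 = np.random.default_rng(24)
        _, multi_free = independence_cox(
            y, risk, pd.DataFrame({"stage": rng2.permutation(stage.to_numpy())}, index=expr.columns)
        )
        assert multi_conf.loc["risk_score", "p"] > multi_free.loc["risk_score", "p"]


class TestSplitCohort:
    def test_even_split(self):
        train, test = split_cohort([f"s{i}" for i in range(100)], seed=1)
        assert len(train) == 50 and len(test) == 50
        assert set(train).isdisjoint(test)
        assert len(set(train) | set(test)) == 100

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(30)]
        assert split_cohort(ids, seed=7)[0].tolist() == split_cohort(ids, seed=7)[0].tolist()

    def test_stratification_balances_event_rate(self):
        rng = np.random.default_rng(25)
        events = rng.integers(0, 2, size=400)
        ids = [f"s{i}" for i in range(400)]
        train, test = split_cohort(ids, stratify=events, seed=2)
        ev = pd.Series(events, index=ids)
        assert abs(ev.loc[train].mean() - ev.loc[test].mean()) < 0.05

    def test_singleton_stratum_to_train_with_warning(self):
        with pytest.warns(UserWarning, match="size 1"):
            train, test = split_cohort(["a", "b", "c"], stratify=[0, 0, 1], seed=3)
        assert "c" in set(train)

    def test_invalid_proportion_errors(self):
        with pytest.raises(ValueError):
            split_cohort(["a", "b"], proportion=1.5)
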