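"""CPM feature selection, univariate-ensemble fitting and cross-validation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import lesioncpm as lc


def _df(arr, cols=None):
    arr = np.asarray(arr, float)
    cols = cols or list(range(1, arr.shape[1] + 1))
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=cols)


class TestSelectFeatures:
    def test_perfect_predictor_selected_under_positive_only(self, rng):
        y = rng.standard_normal(10)
        X = _df(np.column_stack([y, rng.standard_normal(10)]))
        sel = lc.select_features(X, y, alpha=0.01, sign_policy="positive_only")
        assert sel.selected_roi_ids == [1]
        assert sel.p[0] < 1e-10

    def test_negative_correlation_excluded_by_sign_rule(self, rng):
        n = 30
        x = rng.standard_normal(n)
        y = -0.95 * x + 0.1 * rng.standard_normal(n)
        X = _df(x[:, None])
        pos = lc.select_features(X, y, sign_policy="positive_only")
        two = lc.select_features(X, y, sign_policy="two_sided")
        assert pos.p[0] < 0.01 and not pos.selected[0]
        assert two.selected[0]

    def test_constant_roi_never_selected(self, rng):
        X = _df(np.column_stack([np.full(12, 3.0), rng.standard_normal(12)]))
        sel = lc.select_features(X, rng.standard_normal(12))
        assert not sel.selected[0] and sel.r[0] == 0.0 and sel.p[0] == 1.0

    def test_t_statistic_closed_form(self):
        # r = 0.5 at n = 27 -> t = 0.5 * sqrt(25 / 0.75)
        sel_t = 0.5 * np.sqrt(25 / 0.75)
        assert sel_t == pytest.approx(2.8868, abs=1e-4)

    def test_alignment_mismatch_rejected(self, rng):
        X = _df(rng.standard_normal((8, 2)))
        with pytest.raises(ValueError):
            lc.select_features(X, rng.standard_normal(9))


class TestRoiTscores:
    def test_zero_correlation_gives_zero_t(self):
        X = _df(np.array([[1.0], [2.0], [1.0], [2.0]]))
        y = np.array([1.0, 1.0, -1.0, -1.0])
        t = lc.roi_tscores(X, y)
        assert t.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_slope_t(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 40))
            X = _df(rng.standard_normal((n, 5)))
            y = rng.standard_normal(n)
            ours = lc.roi_tscores(X, y)
            for col in X.columns:
                fit = sm.OLS(y, sm.add_constant(X[col].to_numpy())).fit()
                assert ours[col] == pytest.approx(fit.tvalues[1], abs=1e-8)


class TestFitPredict:
    def test_exact_linear_relation_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2.0 * x + 1.0
        X = _df(x[:, None])
        sel = lc.select_features(X, y)
        model = lc.fit_cpm(X, y, sel)
        assert model.slopes[0] == pytest.approx(2.0)
        assert model.intercepts[0] == pytest.approx(1.0)
        pred = lc.predict_cpm(model, _df(np.array([[3.0]])))
        assert pred.y_hat[0] == pytest.approx(7.0)

    def test_degenerate_model_predicts_training_mean(self, rng):
        X = _df(rng.standard_normal((20, 3)))
        y = rng.standard_normal(20)
        sel = lc.select_features(X, y, alpha=1e-12)
        model = lc.fit_cpm(X, y, sel)
        assert model.degenerate
        pred = lc.predict_cpm(model, _df(rng.standard_normal((5, 3))))
        np.testing.assert_allclose(pred.y_hat, y.mean())

    def test_two_roi_coefficients_match_hand_ols(self):
        # 4-subject fixture; per-ROI univariate OLS computed by hand
        X = _df(np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0]]))
        y = np.array([2.0, 3.0, 6.0, 7.0])
        sel = lc.select_features(X, y, alpha=0.5)
        assert list(sel.selected) == [True, True]
        model = lc.fit_cpm(X, y, sel)
        for j, col in enumerate(X.columns):
            xj = X[col].to_numpy()
            slope = np.cov(xj, y, ddof=1)[0, 1] / np.var(xj, ddof=1)
            intercept = y.mean() - slope * xj.mean()
            assert model.slopes[j] == pytest.approx(slope)
            assert model.intercepts[j] == pytest.approx(intercept)
        # prediction = average of the two univariate predictions
        pred = lc.predict_cpm(model, X)
        per_roi = model.intercepts + model.slopes * X.to_numpy()
        np.testing.assert_allclose(pred.y_hat, per_roi.mean(axis=1))

    def test_prediction_is_equal_weight_average(self):
        model = lc.CPMModel(
            roi_ids=[1, 2],
            intercepts=np.array([0.0, 0.0]),
            slopes=np.array([1.0, 1.0]),
            training_n=10,
            fallback_mean=0.0,
            alpha=0.01,
            sign_policy="positive_only",
        )
        pred = lc.predict_cpm(model, _df(np.array([[4.0, 6.0]])))
        assert pred.y_hat[0] == pytest.approx(5.0)

    def test_duplicated_roi_shifts_the_average(self, rng):
        # guards against silent column dedup: duplicating a selected ROI
        # must pull the averaged prediction toward it
        model2 = lc.CPMModel(
            roi_ids=[1, 2], intercepts=np.zeros(2), slopes=np.ones(2),
            training_n=10, fallback_mean=0.0, alpha=0.01, sign_policy="positive_only",
        )
        model3 = lc.CPMModel(
            roi_ids=[1, 2, 2], intercepts=np.zeros(3), slopes=np.ones(3),
            training_n=10, fallback_mean=0.0, alpha=0.01, sign_policy="positive_only",
        )
        X = _df(np.array([[4.0, 6.0]]))
        p2 = lc.predict_cpm(model2, X).y_hat[0]
        p3 = lc.predict_cpm(model3, X).y_hat[0]
        assert p3 == pytest.approx((4 + 6 + 6) / 3) and p3 > p2

    def test_missing_roi_column_rejected(self, rng):
        model = lc.CPMModel(
            roi_ids=[99], intercepts=np.zeros(1), slopes=np.ones(1),
            training_n=5, fallback_mean=0.0, alpha=0.01, sign_policy="positive_only",
        )
        with pytest.raises(ValueError, match="99"):
            lc.predict_cpm(model, _df(np.zeros((2, 1))))

    def test_single_roi_in_sample_equals_ols_fitted_values(self, rng):
        n = 25
        x = rng.standard_normal(n)
        y = 1.5 * x + 0.3 * rng.standard_normal(n)
        X = _df(x[:, None])
        sel = lc.select_features(X, y)
        model = lc.fit_cpm(X, y, sel)
        pred = lc.predict_cpm(model, X)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(pred.y_hat, fit.fittedvalues, atol=1e-10)

    def test_model_json_roundtrip(self, tmp_path, rng):
        model = lc.CPMModel(
            roi_ids=[3, 7], intercepts=np.array([0.1, -0.2]),
            slopes=np.array([1.5, 2.5]), training_n=40, fallback_mean=0.05,
            alpha=0.01, sign_policy="positive_only",
        )
        model.to_json(tmp_path / "m.json")
        back = lc.CPMModel.from_json(tmp_path / "m.json")
        assert back.roi_ids == [3, 7]
        np.testing.assert_allclose(back.slopes, model.slopes)


class TestCrossval:
    def test_loo_with_noise_free_perfect_predictor(self, rng):
        n = 30
        x = rng.standard_normal(n)
        y = 3.0 * x - 1.0
        X = _df(x[:, None])
        pred = lc.crossval_cpm(X, y, scheme="loo")
        np.testing.assert_allclose(pred.y_hat, y, atol=1e-9)

    def test_shuffled_outcome_gives_null_centred_cv_correlation(self, rng):
        n = 60
        X = _df(rng.standard_normal((n, 10)))
        rs = []
        for _ in range(60):
            y = rng.standard_normal(n)
            pred = lc.crossval_cpm(X, y, scheme="loo", alpha=0.2)
            if pred.y_hat.std() > 0:
                rs.append(np.corrcoef(pred.y, pred.y_hat)[0, 1])
        # out-of-fold correlation under the null centres at (or below) zero
        assert np.mean(rs) < 0.1

    def test_kfold_deterministic_given_seed(self, rng):
        n = 40
        X = _df(rng.standard_normal((n, 6)))
        y = X[1].to_numpy() + 0.5 * rng.standard_normal(n)
        p1 = lc.crossval_cpm(X, y, scheme="kfold", k=5, seed=11)
        p2 = lc.crossval_cpm(X, y, scheme="kfold", k=5, seed=11)
        np.testing.assert_array_equal(p1.y_hat, p2.y_hat)

    def test_k_larger_than_n_rejected(self, rng):
        X = _df(rng.standard_normal((12, 2)))
        with pytest.raises(ValueError):
            lc.crossval_cpm(X, rng.standard_normal(12), scheme="kfold", k=13)
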