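"""QSPR engine: screening, stepwise selection, fitting, validation."""

import numpy as np
import pandas as pd
import pytest

import flavoperm as fp
from flavoperm.qspr import CorrelationMatrix, QsprModel, QsprRegressor

DESC = list(fp.DESCRIPTOR_NAMES)

#: The published model weights (original descriptor units).
PUBLISHED = QsprModel(
    intercept=4.715,
    coefficients={"QC3p": 1.358, "E_sol": 0.059, "SlogP_V3": 0.020, "vsurf_ID1": 0.056},
)


def _linear_data(n=20, k=3, noise=0.0, seed=0, beta=None, intercept=2.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"d{j}" for j in range(k)])
    beta = np.asarray(beta if beta is not None else [3.0, -1.0, 0.5][:k])
    y = intercept + X.to_numpy() @ beta + noise * rng.normal(size=n)
    return X, pd.Series(y)


# ---------------------------------------------------------------------------
# correlation screening


class TestCorrelationMatrix:
    def test_study_training_block_entries(self, train_Xy):
        X, y = train_Xy
        cm = fp.correlation_matrix(y, X)
        assert round(cm.entry("ppapp_exp", "SlogP_V3"), 3) == 0.738
        assert round(cm.entry("ppapp_exp", "QC3p"), 3) == 0.576
        assert round(cm.entry("ppapp_exp", "E_sol"), 3) == 0.045
        assert round(cm.entry("ppapp_exp", "vsurf_ID1"), 3) == 0.407

    def test_unit_diagonal_and_symmetry(self, train_Xy):
        X, y = train_Xy
        v = fp.correlation_matrix(y, X).values
        assert np.allclose(np.diag(v), 1.0)
        assert np.allclose(v, v.T)
        assert np.all(np.abs(v) <= 1.0 + 1e-12)

    def test_affine_rescaling_invariance(self, train_Xy):
        X, y = train_Xy
        before = fp.correlation_matrix(y, X).values
        X2 = X.copy()
        X2["E_sol"] = 7.0 * X2["E_sol"] - 3.0
        after = fp.correlation_matrix(y, X2).values
        assert np.allclose(before, after, atol=1e-12)

    def test_exactly_collinear_columns(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        y = [2.0, 4.0, 6.0, 8.0]
        cm = fp.correlation_matrix(y, X, response_name="y")
        assert cm.entry("y", "a") == pytest.approx(1.0)

    def test_constant_column_error_names_column(self, train_Xy):
        X, y = train_Xy
        X2 = X.copy()
        X2["SlogP_V3"] = 1.0
        with pytest.raises(ValueError, match="SlogP_V3"):
            fp.correlation_matrix(y, X2)


class TestCollinearityFilter:
    def test_study_descriptors_all_retained(self, train_Xy):
        # largest inter-descriptor |r| in the study block is 0.363 < 0.7
        X, y = train_Xy
        retained, dropped = fp.filter_collinear(fp.correlation_matrix(y, X))
        assert retained == DESC
        assert dropped == []

    def test_identical_descriptors_drop_exactly_one(self, train_Xy):
        X, y = train_Xy
        X2 = X.copy()
        X2["QC3p_copy"] = X2["QC3p"]
        retained, dropped = fp.filter_collinear(fp.correlation_matrix(y, X2))
        assert len(retained) == len(DESC)
        assert len(dropped) == 1
        assert {dropped[0][1], dropped[0][0]} == {"QC3p", "QC3p_copy"}

    def test_three_mutually_collinear_keep_one(self):
        # brute-force check of the stopping condition: no remaining pair
        # above threshold, member closest to the response survives
        names = ("y", "a", "b", "c")
        values = np.array(
            [
                [1.0, 0.5, 0.4, 0.3],
                [0.5, 1.0, 0.9, 0.9],
                [0.4, 0.9, 1.0, 0.9],
                [0.3, 0.9, 0.9, 1.0],
            ]
        )
        retained, dropped = fp.filter_collinear(
            CorrelationMatrix(names=names, values=values), threshold=0.7
        )
        assert retained == ["a"]
        assert len(dropped) == 2


# ---------------------------------------------------------------------------
# stepwise selection


class TestStepwiseSelection:
    def test_study_training_set_selects_all_four(self, train_Xy):
        X, y = train_Xy
        assert sorted(fp.stepwise_select(X, y)) == sorted(DESC)

    def test_noiseless_single_signal_with_decoys(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(
            rng.normal(size=(30, 6)), columns=["signal", "n1", "n2", "n3", "n4", "n5"]
        )
        y = 1.0 + 2.5 * X["signal"]
        assert fp.stepwise_select(X, y) == ["signal"]

    def test_null_selection_rate(self):
        """Pure-noise y: median selected-set size over seeds is 0 and the
        false-entry rate is consistent with the 0.05 entry threshold."""
        sizes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(25, 4)), columns=DESC)
            y = pd.Series(rng.normal(size=25))
            try:
                sizes.append(len(fp.stepwise_select(X, y)))
            except ValueError:
                sizes.append(0)
        assert np.median(sizes) == 0
        # 4 candidates at enter_p=0.05: expect ~18% of runs select anything
        assert np.mean(np.asarray(sizes) > 0) < 0.40

    def test_empty_selection_error(self):
        X = pd.DataFrame({"a": [0.1, 0.2, 0.3, 0.25, 0.15, 0.05, 0.4, 0.35]})
        y = pd.Series([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="entry threshold"):
            fp.stepwise_select(X, y)


# ---------------------------------------------------------------------------
# fitting


class TestFitModel:
    def test_exact_linear_data(self):
        X, y = _linear_data(n=12, k=2)
        model, stats = fp.fit_model(X, y, with_q2=False)
        assert model.intercept == pytest.approx(2.0, abs=1e-10)
        assert model.coefficients["d0"] == pytest.approx(3.0, abs=1e-10)
        assert model.coefficients["d1"] == pytest.approx(-1.0, abs=1e-10)
        assert stats.r2 == pytest.approx(1.0, abs=1e-12)

    def test_study_training_fit_matches_published_statistics(self, train_Xy):
        X, y = train_Xy
        model, stats = fp.fit_model(X, y)
        assert stats.r2 >= 0.881
        assert round(stats.r2, 3) == 0.881
        assert round(stats.rmse, 3) == 0.141
        assert round(stats.q2, 2) == 0.81
        for name, published in PUBLISHED.coefficients.items():
            assert model.coefficients[name] == pytest.approx(published, abs=5e-3)
        assert model.intercept == pytest.approx(PUBLISHED.intercept, abs=5e-3)

    def test_ols_agrees_with_statsmodels_oracle(self, train_Xy):
        sm = pytest.importorskip("statsmodels.api")
        X, y = train_Xy
        est = QsprRegressor().fit(X, y)
        ref = sm.OLS(np.asarray(y), sm.add_constant(X.to_numpy())).fit()
        assert est.intercept_ == pytest.approx(ref.params[0], rel=1e-9)
        assert np.allclose(est.coef_, ref.params[1:], rtol=1e-9)
        assert est.r2_ == pytest.approx(ref.rsquared, abs=1e-12)
        assert est.r2_adj_ == pytest.approx(ref.rsquared_adj, abs=1e-12)
        assert est.f_stat_ == pytest.approx(ref.fvalue, rel=1e-9)

    def test_pls_full_components_equals_ols(self, train_Xy):
        X, y = train_Xy
        ols = QsprRegressor(method="ols").fit(X, y)
        pls = QsprRegressor(method="pls", n_components=4).fit(X, y)
        assert np.allclose(pls.predict(X), ols.predict(X), atol=1e-8)
        assert np.allclose(pls.coef_, ols.coef_, atol=1e-8)

    def test_pls_agrees_with_sklearn_oracle(self, train_Xy):
        from sklearn.cross_decomposition import PLSRegression

        X, y = train_Xy
        for ncomp in (1, 2, 3):
            ours = QsprRegressor(method="pls", n_components=ncomp).fit(X, y)
            ref = PLSRegression(n_components=ncomp, scale=True).fit(
                X.to_numpy(), np.asarray(y)
            )
            assert np.allclose(
                ours.predict(X), ref.predict(X.to_numpy()).ravel(), atol=1e-8
            )

    def test_ols_r2_dominates_pls_r2(self, train_Xy):
        X, y = train_Xy
        r2_ols = QsprRegressor().fit(X, y).r2_
        for ncomp in (1, 2, 3, 4):
            r2_pls = QsprRegressor(method="pls", n_components=ncomp).fit(X, y).r2_
            assert r2_ols >= r2_pls - 1e-12

    def test_rank_deficient_design_raises(self):
        X, y = _linear_data(n=10, k=2)
        X["dup"] = X["d0"]
        with pytest.raises(np.linalg.LinAlgError):
            QsprRegressor().fit(X, y)

    def test_too_many_components_raises(self, train_Xy):
        X, y = train_Xy
        with pytest.raises(ValueError):
            QsprRegressor(method="pls", n_components=5).fit(X, y)

    def test_missing_values_rejected(self):
        X, y = _linear_data(n=10, k=2)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            QsprRegressor().fit(X, y)


# ---------------------------------------------------------------------------
# cross-validation / external validation


class TestLooQ2:
    def test_perfect_model(self):
        X, y = _linear_data(n=10, k=2)
        q2, press = fp.loo_q2(X, y)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert press == pytest.approx(0.0, abs=1e-10)

    def test_brute_force_oracle_small_n(self):
        """Exact agreement with an independent fold-by-fold lstsq refit."""
        for n, k, seed in [(4, 1, 0), (8, 2, 1), (12, 3, 2)]:
            X, y = _linear_data(n=n, k=k, noise=0.5, seed=seed)
            Xa, ya = X.to_numpy(), y.to_numpy()
            press = 0.0
            for i in range(n):
                mask = np.arange(n) != i
                X1 = np.column_stack([np.ones(mask.sum()), Xa[mask]])
                beta, *_ = np.linalg.lstsq(X1, ya[mask], rcond=None)
                press += (ya[i] - (beta[0] + Xa[i] @ beta[1:])) ** 2
            expected_q2 = 1 - press / np.sum((ya - ya.mean()) ** 2)
            q2, got_press = fp.loo_q2(X, y)
            assert got_press == pytest.approx(press, rel=1e-10)
            assert q2 == pytest.approx(expected_q2, rel=1e-10)

    def test_y_scrambling_destroys_q2(self, train_Xy):
        X, y = train_Xy
        q2s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            q2s.append(fp.loo_q2(X, y_perm)[0])
        assert np.median(q2s) < 0.2

    def test_q2_not_above_r2_on_study_data(self, train_Xy):
        X, y = train_Xy
        est = QsprRegressor().fit(X, y)
        q2, _ = fp.loo_q2(X, y)
        assert q2 <= est.r2_

    def test_small_n_rejected(self):
        X, y = _linear_data(n=3, k=1)
        with pytest.raises(ValueError):
            fp.loo_q2(X, y)


class TestRmse:
    def test_identical_vectors(self):
        assert fp.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert fp.rmse([0.3, 0.0], [0.0, 0.4]) == pytest.approx(0.35355, abs=1e-5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fp.rmse([1.0, 2.0], [1.0])


class TestExternalValidation:
    def test_perfect_prediction(self, train_Xy, test_Xy):
        X, y = train_Xy
        Xt, yt = test_Xy
        ident = QsprModel(intercept=0.0, coefficients={"QC3p": 0.0})

        class Perfect:
            def predict(self, X_):
                return yt.to_numpy()

        r2_pred, err = fp.validate_external(Perfect(), Xt, yt, float(y.mean()))
        assert r2_pred == pytest.approx(1.0)
        assert err == 0.0

    def test_train_mean_predictor_scores_zero(self, train_Xy, test_Xy):
        X, y = train_Xy
        Xt, yt = test_Xy
        mean = float(y.mean())
        null_model = QsprModel(intercept=mean, coefficients={"QC3p": 0.0})
        r2_pred, _ = fp.validate_external(null_model, Xt, yt, mean)
        assert r2_pred == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generating_model(self):
        """Synthetic truth, noise sd 0.1, n_test=50: R^2_pred lands in
        [0.8, 1.0] in at least 19 of 20 fixed seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
            beta = np.array([1.0, -0.5, 0.25])
            y = pd.Series(2.0 + X.to_numpy() @ beta + 0.1 * rng.normal(size=30))
            Xt = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
            yt = pd.Series(2.0 + Xt.to_numpy() @ beta + 0.1 * rng.normal(size=50))
            est = QsprRegressor().fit(X, y)
            r2_pred, _ = fp.validate_external(est, Xt, yt, float(y.mean()))
            hits += 0.8 <= r2_pred <= 1.0
        assert hits >= 19

    def test_degenerate_test_set(self, train_Xy):
        X, y = train_Xy
        est = QsprRegressor().fit(X, y)
        flat = pd.Series([5.0, 5.0])
        with pytest.raises(ValueError, match="degenerate"):
            fp.validate_external(est, X.iloc[:2], flat, 5.0)


class TestOutlierScreen:
    def test_no_outliers_empty_exclusion(self):
        X, y = _linear_data(n=20, k=2, noise=0.05, seed=3)
        screen = fp.screen_outliers(X, y)
        assert screen.excluded == []

    def test_planted_outlier_recovered(self):
        # n large enough that one +5 shift cannot drag other residuals
        # past the threshold in the single all-data fit
        X, y = _linear_data(n=60, k=2, noise=0.05, seed=4)
        y = y.copy()
        y.iloc[7] += 5.0
        screen = fp.screen_outliers(X, y)
        assert screen.excluded == [7]

    def test_degenerate_threshold_insufficient_data(self):
        X, y = _linear_data(n=12, k=2, noise=0.3, seed=5)
        with pytest.raises(ValueError, match="outlier screen leaves"):
            fp.screen_outliers(X, y, residual_threshold=0.0)


class TestPredict:
    def test_intercept_at_origin(self):
        values = {n: 0.0 for n in DESC}
        assert fp.predict(PUBLISHED, values) == pytest.approx(4.715)

    def test_direct_arithmetic_on_published_weights(self, study):
        # compound 1 descriptors through the published equation
        got = fp.predict(PUBLISHED, study.descriptors[1])
        assert got == pytest.approx(4.723, abs=5e-4)

    def test_higher_descriptor_lowers_permeability(self, study):
        base = fp.predict(PUBLISHED, {n: 0.0 for n in DESC})
        for name in DESC:
            bumped = {n: 0.0 for n in DESC}
            bumped[name] = 1.0
            ppapp = fp.predict(PUBLISHED, bumped)
            assert ppapp > base  # higher pPapp = lower Papp = less absorbed
            assert fp.ppapp_to_papp(ppapp) < fp.ppapp_to_papp(base)

    def test_missing_descriptor_named(self):
        with pytest.raises(KeyError, match="vsurf_ID1"):
            fp.predict(PUBLISHED, {"QC3p": 0.0, "E_sol": 0.0, "SlogP_V3": 0.0})


class TestSklearnEstimatorShape:
    def test_selector_pipeline_reproduces_study_fit(self, train_Xy):
        """CollinearityFilter -> StepwiseSelector -> QsprRegressor composes
        as a sklearn pipeline and reproduces the direct fit."""
        from sklearn.pipeline import Pipeline

        X, y = train_Xy
        pipe = Pipeline(
            [
                ("collinear", fp.CollinearityFilter(threshold=0.7)),
                ("stepwise", fp.StepwiseSelector()),
                ("model", QsprRegressor()),
            ]
        ).set_output(transform="pandas").fit(X, y)
        assert sorted(pipe.named_steps["stepwise"].selected_) == sorted(DESC)
        direct = QsprRegressor().fit(X, y)
        assert np.allclose(pipe.predict(X), direct.predict(X), atol=1e-10)

    def test_collinearity_filter_transform_drops_duplicate(self, train_Xy):
        X, y = train_Xy
        X2 = X.copy()
        X2["dup"] = X2["SlogP_V3"] * 2.0 + 1.0
        sel = fp.CollinearityFilter().fit(X2, y)
        assert sel.transform(X2).shape[1] == 4
        assert len(sel.dropped_pairs_) == 1

    def test_get_params_clone_round_trip(self):
        from sklearn.base import clone

        est = QsprRegressor(method="pls", n_components=2)
        assert clone(est).get_params() == {"method": "pls", "n_components": 2}
        sel = fp.StepwiseSelector(enter_p=0.01)
        assert clone(sel).get_params()["enter_p"] == 0.01


class TestModelSerialization:
    def test_json_round_trip(self, train_Xy):
        X, y = train_Xy
        model, stats = fp.fit_model(X, y)
        again = QsprModel.from_json(model.to_json(stats))
        assert again == model
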