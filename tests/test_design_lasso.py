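import numpy as np
import pandas as pd
import pytest

from adaptmap import (
    GenotypeMatrix,
    ModelTermSet,
    TermKey,
    build_design,
    fit_lasso,
    predict,
    r_squared,
)


class TestBuildDesign:
    def test_binary_product_is_logical_and(self):
        cov = pd.DataFrame({"A": [0.0, 1.0, 1.0, 0.0], "B": [0.0, 1.0, 0.0, 1.0]})
        ts = ModelTermSet({"A", "B"}, {TermKey(("A", "B"))}).close_marginality()
        dm = build_design(cov, ts)
        assert dm.X["A:B"].tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_three_level_factor_gives_two_reference_coded_dummies(self):
        cov = pd.DataFrame({"smoke": ["1", "3", "2", "1"]})
        dm = build_design(cov, ModelTermSet({"smoke"}, set()))
        assert list(dm.X.columns) == ["smoke.2", "smoke.3"]  # level "1" dropped
        assert dm.X["smoke.3"].tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_triple_product_matches_row_loop_oracle(self, rng):
        cov = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
        ts = ModelTermSet(set("abc"), {TermKey(("a", "b", "c"))})
        dm = build_design(cov, ts)
        oracle = [cov.iloc[i]["a"] * cov.iloc[i]["b"] * cov.iloc[i]["c"]
                  for i in range(50)]
        assert np.allclose(dm.X["a:b:c"], oracle)

    def test_categorical_interaction_expands_dummy_levels(self):
        cov = pd.DataFrame({"g": ["u", "v", "u", "v"], "x": [1.0, 2.0, 3.0, 4.0]})
        ts = ModelTermSet({"g", "x"}, {TermKey(("g", "x"))})
        dm = build_design(cov, ts)
        assert "g.v:x" in dm.X.columns
        assert dm.X["g.v:x"].tolist() == [0.0, 2.0, 0.0, 4.0]

    def test_snp_main_is_dosage_column(self, rng):
        cov = pd.DataFrame({"x": rng.standard_normal(10)})
        geno = GenotypeMatrix(["rs1"], rng.binomial(2, 0.4, (10, 1)).astype(float))
        ts = ModelTermSet({"x", "rs1"}, set())
        dm = build_design(cov, ts, geno)
        assert np.array_equal(dm.X["rs1"], geno.dosages[:, 0])

    def test_levels_pinning_aligns_test_encoding(self):
        tr = pd.DataFrame({"g": ["a", "b", "c", "a"]})
        te = pd.DataFrame({"g": ["a", "a"]})  # levels b, c absent in test
        ts = ModelTermSet({"g"}, set())
        dm_tr = build_design(tr, ts)
        dm_te = build_design(te, ts, levels=dm_tr.levels)
        assert list(dm_te.X.columns) == list(dm_tr.X.columns)

    def test_unknown_feature_named_in_error(self):
        cov = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(KeyError, match="ghost"):
            build_design(cov, ModelTermSet({"ghost"}, set()))

    def test_re_encoding_bit_identical(self, rng):
        cov = pd.DataFrame({"x": rng.standard_normal(20),
                            "g": rng.choice(["u", "v"], 20)})
        ts = ModelTermSet({"x", "g"}, {TermKey(("g", "x"))})
        a = build_design(cov, ts)
        b = build_design(cov, ts)
        pd.testing.assert_frame_equal(a.X, b.X)


def design_from(X: np.ndarray) -> "object":
    from adaptmap.design import DesignMatrix

    cols = [f"c{j}" for j in range(X.shape[1])]
    return DesignMatrix(pd.DataFrame(X, columns=cols),
                        {c: TermKey((c,)) for c in cols})


class TestFitLasso:
    def test_null_response_selects_almost_nothing(self, rng):
        sparse_runs = 0
        for s in range(30):
            X = rng.standard_normal((300, 40))
            y = rng.standard_normal(300)
            fit = fit_lasso(design_from(X), y, inner_folds=5, seed=s)
            sparse_runs += len(fit.active) <= 2
        assert sparse_runs >= 24  # >= 80%

    def test_orthonormal_design_soft_thresholds(self, rng):
        # columns orthogonal to each other and to the intercept, unit norm
        n, p = 64, 6
        M = rng.standard_normal((n, p + 1))
        M[:, 0] = 1.0
        Q, _ = np.linalg.qr(M)
        X = Q[:, 1:]  # mean-zero orthonormal columns
        y = rng.standard_normal(n)
        lam = 0.05
        fit = fit_lasso(design_from(X), y, penalty=lam)
        # standardized columns are sqrt(n) * x_j, so X_s'X_s / n = I and the
        # lasso solution is soft(X_s'y / n, lam), mapped back by the scales
        s = X.std(axis=0)
        Xs = (X - X.mean(0)) / s
        ols = Xs.T @ y / n
        soft = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0)
        assert np.allclose(fit.coef.to_numpy(), soft / s, atol=1e-6)

    def test_perfect_predictor_limit(self, rng):
        y = rng.standard_normal(100)
        fit = fit_lasso(design_from(y[:, None]), y, penalty=1e-10)
        assert fit.coef.iloc[0] == pytest.approx(1.0, abs=1e-4)
        assert fit.intercept == pytest.approx(0.0, abs=1e-4)

    def test_zero_penalty_reproduces_least_squares(self, rng):
        X = rng.standard_normal((200, 5))
        beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
        y = X @ beta + 0.5 * rng.standard_normal(200)
        fit = fit_lasso(design_from(X), y, penalty=0)
        Xi = np.column_stack([np.ones(200), X])
        ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
        assert np.allclose(fit.coef.to_numpy(), ols[1:], rtol=1e-4, atol=1e-8)
        assert fit.intercept == pytest.approx(ols[0], rel=1e-4)

    def test_zero_variance_columns_dropped_with_warning(self, rng):
        X = rng.standard_normal((50, 2))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_lasso(design_from(X), rng.standard_normal(50), penalty=0.1)
        assert fit.coef.iloc[1] == 0.0
        assert fit.dropped == ["c1"]


class TestPredict:
    def test_all_zero_coefficients_give_intercept(self, rng):
        X = rng.standard_normal((20, 3))
        dm = design_from(X)
        fit = fit_lasso(dm, rng.standard_normal(20), penalty=10.0)
        assert len(fit.active) == 0
        assert np.allclose(predict(fit, dm), fit.intercept)

    def test_kkt_stationarity_on_training_data(self, rng):
        n, p = 200, 8
        X = rng.standard_normal((n, p))
        y = X[:, 0] * 2 + rng.standard_normal(n)
        dm = design_from(X)
        lam = 0.1
        fit = fit_lasso(dm, y, penalty=lam)
        resid = y - predict(fit, dm)
        Xs = (X - X.mean(0)) / X.std(0)
        for j, c in enumerate(dm.X.columns):
            grad = Xs[:, j] @ resid / n
            if fit.coef[c] != 0:
                assert grad == pytest.approx(lam * np.sign(fit.coef[c]), abs=1e-4)
            else:
                assert abs(grad) <= lam + 1e-4

    def test_unused_extra_column_ignored(self, rng):
        X = rng.standard_normal((50, 2))
        dm = design_from(X)
        y = X[:, 0] + 0.1 * rng.standard_normal(50)
        fit = fit_lasso(dm, y, penalty=0.05)
        wide = design_from(np.column_stack([X, rng.standard_normal(50)]))
        assert np.allclose(predict(fit, wide), predict(fit, dm))

    def test_missing_required_column_errors(self, rng):
        X = rng.standard_normal((50, 2))
        y = X[:, 0] + X[:, 1]
        fit = fit_lasso(design_from(X), y, penalty=1e-4)
        assert set(fit.active.index) == {"c0", "c1"}
        with pytest.raises(KeyError):
            predict(fit, design_from(X[:, :1]))


class TestRSquared:
    def test_perfect_and_sign_flipped_predictions(self, rng):
        y = rng.standard_normal(100)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(-y, y) == pytest.approx(1.0)  # squared correlation

    def test_noise_attenuation_half(self, rng):
        y = rng.standard_normal(10000)
        pred = y + rng.standard_normal(10000)
        assert r_squared(pred, y) == pytest.approx(0.5, abs=0.03)

    def test_constant_predictions_zero_with_warning(self, rng):
        with pytest.warns(UserWarning):
            assert r_squared(np.ones(10), rng.standard_normal(10)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0, 3.0])
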