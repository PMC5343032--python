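"""PCR, PLSR, ridge, and SVR: oracles, limits, and determinism contracts."""

import numpy as np
import pandas as pd
import pytest

import spectraits as st
from spectraits.evaluation import r_squared
from spectraits.preprocess import normalize
from spectraits.regression import (ComponentSpec, RidgeSpec, _ridge_path,
                                   default_lambda_grid, predict)


def _ols_predictions(X, y):
    """Least-squares oracle with intercept, via numpy lstsq."""
    A = np.column_stack([np.ones(len(X)), np.asarray(X, float)])
    beta, *_ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)
    return A @ beta


def _random_xy(n, p, seed, noise=1.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"f{i}" for i in range(p)])
    y = pd.Series(X.to_numpy() @ rng.normal(size=p)
                  + noise * rng.normal(size=n), name="y")
    return X, y


class TestRidgeGrid:
    def test_grid_contract(self):
        g = default_lambda_grid()
        assert len(g) == 100
        assert g[0] == pytest.approx(1e-2) and g[-1] == pytest.approx(1e10)
        assert np.all(np.diff(g) > 0)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            RidgeSpec(lambda_grid=np.array([1.0, 0.5, 2.0]))

    def test_smallest_lambda_matches_ols(self):
        X, y = _random_xy(200, 5, seed=0)
        Xn, _ = normalize(X, "zscore")
        betas, _ = _ridge_path(Xn.to_numpy(), y.to_numpy(), np.array([1e-2]))
        A = np.column_stack([np.ones(len(X)), Xn.to_numpy()])
        beta_ols = np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0][1:]
        np.testing.assert_allclose(betas[:, 0], beta_ols, rtol=1e-4)

    def test_huge_lambda_shrinks_to_zero(self):
        X, y = _random_xy(100, 4, seed=1)
        Xn, _ = normalize(X, "zscore")
        small, _ = _ridge_path(Xn.to_numpy(), y.to_numpy(), np.array([1e-2]))
        big, _ = _ridge_path(Xn.to_numpy(), y.to_numpy(), np.array([1e10]))
        assert np.abs(big).max() < 1e-6 * np.abs(small).max()

    def test_singular_wide_matrix_stays_finite(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(10, 30)))
        y = pd.Series(rng.normal(size=10))
        Xn, _ = normalize(X, "zscore")
        betas, _ = _ridge_path(Xn.to_numpy(), y.to_numpy(),
                               default_lambda_grid())
        assert np.isfinite(betas).all()

    def test_fold_determinism(self, gy_gf):
        X, y = gy_gf
        a = st.fit_ridge(X, y, seed=7)
        b = st.fit_ridge(X, y, seed=7)
        assert a.cv_rmse_path == b.cv_rmse_path
        assert a.selected == b.selected

    def test_prediction_matches_hand_linear_algebra(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0.5, 1.5, 0.7, 2.0]})
        y = pd.Series([1.0, 2.5, 2.0, 4.0])
        lam = 3.0
        fit = st.fit_ridge(X, y, RidgeSpec(lambda_grid=np.array([lam, lam * 2])),
                           folds=np.array([0, 1, 0, 1]))
        Xn, _ = normalize(X, "zscore")
        A = Xn.to_numpy()
        beta = np.linalg.solve(A.T @ A + fit.selected["lambda"] * np.eye(2),
                               A.T @ (y - y.mean()).to_numpy())
        expected = A @ beta + y.mean()
        np.testing.assert_allclose(predict(fit, X), expected, rtol=1e-10)


class TestComponentModels:
    def test_pcr_recovers_pc1_signal(self):
        # one dominant latent factor survives the per-column z-scoring, so
        # PC1 of the normalized data tracks it; y is that factor
        rng = np.random.default_rng(3)
        factor = rng.normal(size=60)
        loadings = rng.uniform(0.5, 1.5, size=8)
        X = pd.DataFrame(np.outer(factor, loadings)
                         + 0.05 * rng.normal(size=(60, 8)))
        y = pd.Series(factor, name="y")
        fit = st.fit_pcr(X, y, ComponentSpec("PCR", fixed_n=1), seed=0)
        assert r_squared(y, fit.cv_predictions) >= 0.99

    @pytest.mark.parametrize("fitter", [st.fit_pcr, st.fit_plsr])
    def test_full_rank_equals_ols(self, fitter):
        X, y = _random_xy(40, 5, seed=4)
        fit = fitter(X, y, ComponentSpec(fixed_n=5), seed=0)
        np.testing.assert_allclose(fit.fitted_values.to_numpy(),
                                   _ols_predictions(X, y), rtol=1e-8)

    @pytest.mark.parametrize("fitter", [st.fit_pcr, st.fit_plsr])
    def test_permuted_response_has_no_skill(self, fitter):
        X, y = _random_xy(60, 5, seed=5, noise=0.2)
        r2s = []
        for s in range(20):
            rng = np.random.default_rng(s)
            y_perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            fit = fitter(X, y_perm,
                         ComponentSpec(n_components_search=range(1, 4)), seed=s)
            r2s.append(r_squared(y_perm, fit.cv_predictions))
        assert np.mean(r2s) <= 0.1

    def test_pls_first_factor_beats_pca_on_y_covariance(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(80, 10)) * np.linspace(3, 0.3, 10))
        # response aligned with a low-variance direction
        y = pd.Series(X.to_numpy()[:, -1] + 0.1 * rng.normal(size=80))
        from spectraits.regression import _pca_scores, _pls_scores
        Xn, _ = normalize(X, "zscore")
        yc = (y - y.mean()).to_numpy()
        T_pca, _ = _pca_scores(Xn.to_numpy(), 1)
        T_pls, _ = _pls_scores(Xn.to_numpy(), yc, 1)
        cov_pca = abs(np.cov(T_pca[:, 0], yc)[0, 1])
        cov_pls = abs(np.cov(T_pls[:, 0], yc)[0, 1])
        assert cov_pls >= cov_pca - 1e-12

    def test_zero_variance_response_rejected_by_plsr(self):
        X, _ = _random_xy(20, 3, seed=7)
        with pytest.raises(st.errors.ModelError):
            st.fit_plsr(X, pd.Series(np.ones(20)), seed=0)

    def test_column_permutation_leaves_predictions_unchanged(self):
        X, y = _random_xy(50, 6, seed=8)
        fit = st.fit_pcr(X, y, ComponentSpec("PCR", fixed_n=3), seed=0)
        shuffled = X[[c for c in reversed(X.columns)]]
        np.testing.assert_allclose(predict(fit, shuffled),
                                   predict(fit, X), rtol=1e-10)


class TestSvr:
    def test_linear_target_fit_within_tube(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.uniform(-2, 2, 80)})
        y = pd.Series(0.8 * X["a"])
        fit = st.fit_svr(X, y, st.SvrSpec(kernel_candidates=("linear",)), seed=0)
        residual_rmse = float(np.sqrt(np.mean(
            (fit.fitted_values - y) ** 2)))
        assert residual_rmse <= fit.selected["epsilon"]

    def test_rbf_beats_linear_on_smooth_nonlinearity(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            X = pd.DataFrame(rng.uniform(-2, 2, size=(80, 3)),
                             columns=list("abc"))
            # smooth, symmetric nonlinearity: no linear component at all
            y = pd.Series(X["a"] ** 2 + 0.05 * rng.normal(size=80))
            fit = st.fit_svr(X, y, st.SvrSpec(
                kernel_candidates=("linear", "rbf")), seed=s)
            wins += fit.selected["kernel"] == "rbf"
        assert wins >= 8

    def test_duplicated_training_rows_leave_predictions_stable(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"a": rng.uniform(-2, 2, 40)})
        y = pd.Series(0.5 * X["a"])
        spec = st.SvrSpec(kernel_candidates=("linear",))
        fit1 = st.fit_svr(X, y, spec, seed=0)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = pd.concat([y, y], ignore_index=True)
        fit2 = st.fit_svr(X2, y2, spec, seed=0)
        queries = pd.DataFrame({"a": np.linspace(-1.5, 1.5, 7)})
        np.testing.assert_allclose(predict(fit1, queries),
                                   predict(fit2, queries), atol=1e-6)

    def test_schema_mismatch_rejected(self):
        X, y = _random_xy(30, 3, seed=11)
        fit = st.fit_ridge(X, y, seed=0)
        with pytest.raises(st.errors.SchemaError):
            predict(fit, X.drop(columns=["f0"]))


class TestCrossMethodAgreement:
    def test_all_families_agree_on_exact_linear_single_feature(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        y = pd.Series(2.0 * X["a"] + 1.0)
        preds = {}
        for name, fn in [("PCR", st.fit_pcr), ("PLSR", st.fit_plsr),
                         ("RR", st.fit_ridge), ("SVR", st.fit_svr)]:
            fit = fn(X, y, seed=0)
            preds[name] = predict(fit, X).to_numpy()
        spread = np.max([np.abs(preds[a] - preds["RR"]).max()
                         for a in preds])
        assert spread < 0.2  # within the SVR ε-tube of the exact fit
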