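"""Metrics (r², RMSE, index of agreement, classification rates), the CV
harness, and spectral-index screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

import spectraits as st
from spectraits.errors import ModelError
from spectraits.evaluation import (CLASS1, CLASS2, classification_metrics,
                                   error_rate_from_rates, index_of_agreement,
                                   kfold_cv, make_folds, r_squared,
                                   regression_metrics, rmse, screen_indices)


class TestIndexOfAgreement:
    def test_perfect_fit_is_exactly_one(self):
        o = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert index_of_agreement(o, o) == 1.0

    def test_mean_prediction_scores_zero(self):
        o = np.array([1.0, 2.0, 6.0])
        p = np.full(3, o.mean())
        assert index_of_agreement(o, p) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        # numerator 1, denominator 13
        assert index_of_agreement([1, 2, 3], [1, 2, 4]) == pytest.approx(1 - 1 / 13)

    def test_identical_observed_undefined(self):
        with pytest.raises(ValueError):
            index_of_agreement([2.0, 2.0], [1.0, 3.0])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(seed=hyp.integers(0, 10 ** 6), n=hyp.integers(2, 50))
    def test_bounded_on_random_pairs(self, seed, n):
        rng = np.random.default_rng(seed)
        o = rng.normal(size=n)
        if np.ptp(o) == 0:
            o[0] += 1.0
        p = rng.normal(size=n) * rng.uniform(0, 5)
        assert 0.0 <= index_of_agreement(o, p) <= 1.0


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.rmse, m.ia) == (1.0, 0.0, 1.0)

    def test_rmse_hand_value(self):
        assert rmse([0, 0, 3, 3], [1, 1, 2, 2]) == 1.0

    def test_affine_invariance_of_r2_only(self):
        o = np.array([1.0, 2.0, 4.0, 7.0])
        p = np.array([1.1, 2.2, 3.7, 6.5])
        p2 = 2.0 * p + 3.0
        assert r_squared(o, p2) == pytest.approx(r_squared(o, p))
        assert rmse(o, p2) != pytest.approx(rmse(o, p))
        assert index_of_agreement(o, p2) != pytest.approx(index_of_agreement(o, p))


class TestClassificationMetrics:
    def test_all_correct(self):
        labels = [CLASS1, CLASS1, CLASS2]
        m = classification_metrics(labels, labels)
        assert m.accuracy == 1.0 and m.error_rate == 0.0
        assert m.prediction_rate_class1 == m.prediction_rate_class2 == 1.0

    def test_printed_rate_pairs_reproduce_average_errors(self):
        assert error_rate_from_rates(0.96, 0.21) == pytest.approx(0.42, abs=0.01)
        assert error_rate_from_rates(0.70, 0.71) == pytest.approx(0.30, abs=0.01)

    def test_confusion_hand_example(self):
        labels = [CLASS1] * 10 + [CLASS2] * 2
        pred = [CLASS1] * 8 + [CLASS2] * 2 + [CLASS2, CLASS1]
        m = classification_metrics(labels, pred)
        assert m.accuracy == pytest.approx(9 / 12)
        assert m.prediction_rate_class1 == pytest.approx(0.8)
        assert m.prediction_rate_class2 == pytest.approx(0.5)
        assert m.error_rate == pytest.approx(0.35)
        assert sum(m.confusion.values()) == 12

    def test_macro_error_equals_one_minus_accuracy_only_when_balanced(self):
        labels = [CLASS1] * 5 + [CLASS2] * 5
        pred = [CLASS1] * 4 + [CLASS2] + [CLASS2] * 4 + [CLASS1]
        m = classification_metrics(labels, pred)
        assert m.error_rate == pytest.approx(m.error_rate_1m_accuracy)
        labels_u = [CLASS1] * 8 + [CLASS2] * 2
        pred_u = [CLASS1] * 8 + [CLASS1, CLASS2]
        mu = classification_metrics(labels_u, pred_u)
        assert mu.error_rate != pytest.approx(mu.error_rate_1m_accuracy)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([CLASS1, CLASS2], [CLASS1, "Class3"])


class TestFolds:
    def test_partition_properties(self):
        folds = make_folds(20, k=10, seed=3)
        sizes = np.bincount(folds, minlength=10)
        assert (sizes == 2).all()

    def test_same_seed_same_assignment(self):
        a = make_folds(57, 10, seed=11)
        b = make_folds(57, 10, seed=11)
        assert (a == b).all()
        c = make_folds(57, 10, seed=12)
        assert (a != c).any()

    def test_too_few_rows_raise(self):
        with pytest.raises(ModelError):
            make_folds(5, k=10, seed=0)


class TestKfoldCv:
    @staticmethod
    def _lstsq_fit(X, y):
        A = np.column_stack([np.ones(len(X)), X.to_numpy()])
        beta, *_ = np.linalg.lstsq(A, y.to_numpy(), rcond=None)
        return beta

    @staticmethod
    def _lstsq_predict(beta, X):
        return np.column_stack([np.ones(len(X)), X.to_numpy()]) @ beta

    def test_overfit_prone_data_validates_worse_than_calibrates(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 25)))
        y = pd.Series(rng.normal(size=30))
        oof, models, folds = kfold_cv(X, y, self._lstsq_fit,
                                      self._lstsq_predict, k=10, seed=0)
        cal = self._lstsq_predict(self._lstsq_fit(X, y), X)
        assert r_squared(y, oof) < r_squared(y, cal)

    def test_each_row_predicted_once_from_unseen_model(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        y = pd.Series(rng.normal(size=20))
        oof, models, folds = kfold_cv(X, y, self._lstsq_fit,
                                      self._lstsq_predict, k=10, seed=0)
        assert oof.notna().all() and len(models) == 10
        assert sorted(np.bincount(folds)) == [2] * 10

    def test_training_fold_statistics_ignore_validation_rows(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        y = pd.Series(rng.normal(size=20))
        recorded = []

        def fit(Xtr, ytr):
            stats = Xtr.mean()
            recorded.append(stats)
            return self._lstsq_fit(Xtr, ytr)

        _, _, folds = kfold_cv(X, y, fit, self._lstsq_predict, k=5, seed=1)
        first_run = [s.copy() for s in recorded]
        recorded.clear()
        X2 = X.copy()
        X2.loc[folds == 0] += 100.0  # perturb one validation fold
        kfold_cv(X2, y, fit, self._lstsq_predict, k=5, folds=folds)
        # the model whose validation fold was perturbed trained without it
        pd.testing.assert_series_equal(first_run[0], recorded[0])


class TestScreenIndices:
    def test_constructed_signal_ranks_first(self):
        rng = np.random.default_rng(8)
        n = 150
        table = pd.DataFrame(rng.normal(size=(n, 10)),
                             columns=[f"idx{i}" for i in range(9)] + ["NWI-3"])
        trait = pd.Series(2.0 * table["NWI-3"] + 1e-6 * rng.normal(size=n),
                          index=table.index)
        ranked = screen_indices(table, trait)
        assert ranked.iloc[0]["index"] == "NWI-3"
        assert ranked.iloc[0]["r2"] >= 0.999

    def test_null_trait_keeps_r2_small(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.normal(size=(200, 50)))
        table.columns = [f"idx{i}" for i in range(50)]
        trait = pd.Series(rng.normal(size=200), index=table.index)
        ranked = screen_indices(table, trait)
        assert ranked["r2"].max() <= 0.2
        assert ranked.attrs["n_indices_tested"] == 50

    def test_three_collinear_points_give_exact_fit(self):
        table = pd.DataFrame({"only": [1.0, 2.0, 3.0]})
        trait = pd.Series([2.0, 4.0, 6.0], index=table.index)
        ranked = screen_indices(table, trait)
        assert ranked.iloc[0]["r2"] == pytest.approx(1.0)

    def test_sign_flip_of_index_preserves_r2(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        table = pd.DataFrame({"NDSI(a;b)": x, "NDSI(b;a)": -x})
        trait = pd.Series(x + 0.3 * rng.normal(size=100), index=table.index)
        ranked = screen_indices(table, trait).set_index("index")
        assert ranked.loc["NDSI(a;b)", "r2"] == pytest.approx(
            ranked.loc["NDSI(b;a)", "r2"])

    def test_all_missing_column_excluded_with_note(self):
        table = pd.DataFrame({"good": [1.0, 2.0, 3.0, 4.0],
                              "bad": [np.nan] * 4})
        trait = pd.Series([1.0, 2.1, 2.9, 4.2], index=table.index)
        ranked = screen_indices(table, trait)
        note = ranked.set_index("index").loc["bad", "note"]
        assert "excluded" in note
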