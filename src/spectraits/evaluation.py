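"""Cross-validation harness and evaluation metrics.

Regression models are scored by the coefficient of determination (r² between
observed and predicted, calibration and validation), the root mean square
error (RMSE, trait units), and Willmott's Index of Agreement

    d = 1 − Σ(Pᵢ−Oᵢ)² / Σ(|Pᵢ−Ō| + |Oᵢ−Ō|)² ∈ [0, 1],

0 a faulty model and 1 a perfect fit.  Classifiers are scored by accuracy,
per-class prediction rates (class-wise sensitivity), and an error rate
defined as 1 − macro-averaged prediction rate: the printed benchmark pairs
(accuracy 0.81 with error 0.42) are mutually consistent only under the macro
definition, so macro is canonical here and 1 − accuracy is reported alongside.

Validation metrics are always computed on pooled out-of-fold predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ModelError

CLASS1 = "Class1"
CLASS2 = "Class2"


# ---------------------------------------------------------------------------
# folds


def make_folds(n: int, k: int = 10, seed: int = 0,
               stratify_labels=None) -> np.ndarray:
    """Seeded assignment of ``n`` observations to ``k`` cross-validation folds.

    Plain uniform random partition by default; with ``stratify_labels`` each
    label's members are spread round-robin across folds so rare classes reach
    every fold.  Deterministic for a given seed.
    """
    if n < k:
        raise ModelError(f"n={n} < k={k}: lower k to at most n")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if stratify_labels is None:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % k
    else:
        labels = np.asarray(stratify_labels)
        offset = 0
        for lab in pd.unique(labels):
            idx = np.flatnonzero(labels == lab)
            perm = rng.permutation(len(idx))
            folds[idx[perm]] = (np.arange(len(idx)) + offset) % k
            offset += len(idx)
    return folds


def kfold_cv(X: pd.DataFrame, y: pd.Series, fit, predict, k: int = 10,
             seed: int = 0, stratify: bool = False, folds=None):
    """Generic k-fold loop: each observation predicted exactly once by a model
    not trained on it; fold models are returned for inspection.

    ``fit(X_train, y_train) -> model`` and ``predict(model, X_test) -> array``
    own all preprocessing, so per-fold statistics are refit on training rows
    only.  Returns ``(out_of_fold: pd.Series, fold_models: list, folds)``.
    """
    if folds is None:
        folds = make_folds(len(X), k, seed,
                           stratify_labels=y if stratify else None)
    folds = np.asarray(folds)
    oof = pd.Series(index=X.index, dtype=object if stratify else float)
    models = []
    for f in range(int(folds.max()) + 1):
        test = folds == f
        model = fit(X.loc[~test], y.loc[~test])
        pred = predict(model, X.loc[test])
        oof.loc[test] = np.asarray(pred)
        models.append(model)
    if not stratify:
        oof = oof.astype(float)
    return oof, models, folds


# ---------------------------------------------------------------------------
# regression metrics


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    ia: float

    def to_dict(self):
        return {"r2": self.r2, "rmse": self.rmse, "ia": self.ia}


def index_of_agreement(observed, predicted) -> float:
    """Willmott's index of agreement d ∈ [0, 1] (1 = perfect fit)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    if np.ptp(o) == 0.0:
        raise ValueError("index of agreement undefined: observed values all identical")
    obar = o.mean()
    denom = ((np.abs(p - obar) + np.abs(o - obar)) ** 2).sum()
    return float(1.0 - ((p - o) ** 2).sum() / denom)


def rmse(observed, predicted) -> float:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if np.std(o) == 0.0 or np.std(p) == 0.0:
        return float("nan")
    return float(np.corrcoef(o, p)[0, 1] ** 2)


def regression_metrics(observed, predicted) -> RegressionMetrics:
    return RegressionMetrics(r2=r_squared(observed, predicted),
                             rmse=rmse(observed, predicted),
                             ia=index_of_agreement(observed, predicted))


# ---------------------------------------------------------------------------
# classification metrics


@dataclass
class ClassificationMetrics:
    accuracy: float
    error_rate: float          # 1 − macro-averaged per-class prediction rate
    error_rate_1m_accuracy: float
    prediction_rate_class1: float
    prediction_rate_class2: float
    confusion: dict

    def to_dict(self):
        return {
            "accuracy": self.accuracy,
            "error_rate": self.error_rate,
            "error_rate_1m_accuracy": self.error_rate_1m_accuracy,
            "prediction_rate_class1": self.prediction_rate_class1,
            "prediction_rate_class2": self.prediction_rate_class2,
            "confusion": self.confusion,
        }


def error_rate_from_rates(rate_class1: float, rate_class2: float) -> float:
    """Macro error: 1 − mean of the two per-class prediction rates."""
    return 1.0 - (rate_class1 + rate_class2) / 2.0


def classification_metrics(labels, predicted_labels) -> ClassificationMetrics:
    t = np.asarray(labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    valid = {CLASS1, CLASS2}
    seen = set(t) | set(p)
    if not seen <= valid:
        raise ValueError(f"unexpected label values {sorted(seen - valid)}")
    if CLASS1 not in set(t) or CLASS2 not in set(t):
        raise ValueError("each true class must be present")
    conf = {}
    for a in (CLASS1, CLASS2):
        for b in (CLASS1, CLASS2):
            conf[f"true_{a}_pred_{b}"] = int(((t == a) & (p == b)).sum())
    acc = float((t == p).mean())
    rate1 = float((p[t == CLASS1] == CLASS1).mean())
    rate2 = float((p[t == CLASS2] == CLASS2).mean())
    return ClassificationMetrics(
        accuracy=acc,
        error_rate=error_rate_from_rates(rate1, rate2),
        error_rate_1m_accuracy=1.0 - acc,
        prediction_rate_class1=rate1,
        prediction_rate_class2=rate2,
        confusion=conf)


# ---------------------------------------------------------------------------
# SRI linear screening


def screen_indices(index_table: pd.DataFrame, trait_values: pd.Series,
                   min_n: int = 3) -> pd.DataFrame:
    """Simple linear regression trait ~ index for every index column.

    Returns a table ``(index, slope, intercept, r2, rmse, n)`` ranked by r²
    descending, ties by RMSE ascending then name; all-missing columns are
    excluded with a note column.  No multiplicity correction is applied; the
    number of indices tested is recorded in ``attrs['n_indices_tested']``.
    """
    y_all = trait_values.loc[index_table.index]
    rows = []
    for name in index_table.columns:
        x = index_table[name]
        ok = x.notna() & y_all.notna()
        n = int(ok.sum())
        if n < min_n:
            rows.append({"index": name, "slope": np.nan, "intercept": np.nan,
                         "r2": np.nan, "rmse": np.nan, "n": n,
                         "note": "excluded: fewer than min_n paired values"})
            continue
        xv = x[ok].to_numpy(dtype=float)
        yv = y_all[ok].to_numpy(dtype=float)
        if np.std(xv) == 0.0:
            rows.append({"index": name, "slope": np.nan, "intercept": np.nan,
                         "r2": np.nan, "rmse": np.nan, "n": n,
                         "note": "excluded: constant index"})
            continue
        slope, intercept = np.polyfit(xv, yv, 1)
        pred = slope * xv + intercept
        rows.append({"index": name, "slope": float(slope),
                     "intercept": float(intercept),
                     "r2": r_squared(yv, pred), "rmse": rmse(yv, pred),
                     "n": n, "note": ""})
    out = pd.DataFrame(rows)
    ranked = out[out["note"] == ""].sort_values(
        ["r2", "rmse", "index"], ascending=[False, True, True])
    excluded = out[out["note"] != ""]
    result = pd.concat([ranked, excluded]).reset_index(drop=True)
    result.attrs["n_indices_tested"] = int((out["note"] == "").sum())
    return result
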