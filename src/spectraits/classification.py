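"""Elite-genotype dichotomization and categorical models.

Observations are split on the trait *range*: with fraction f (default 0.80)
the threshold is ``min + f·(max − min)`` over the modeled dataset; values
below it are Class1, values at or above it are Class2 — the "elite" upper
20% of the range.  Thresholds are computed per modeled dataset (trait ×
stage × environment set), never globally, so pooling the two hydric regimes
changes the cut.

Three classifiers, all on mean-centered spectra with hyperparameters chosen
by 10-fold cross-validated error rate (stratified folds so the rare elite
class reaches every fold):

* **PCA-LDA** — linear discriminant on the leading 1–20 principal-component
  scores (class means, pooled covariance);
* **PLS-DA** — PLS regression of the class indicator on the spectra with
  1–20 latent variables; class assignment by maximum posterior under
  class-conditional Gaussians fitted to the calibration scores (toolbox-style
  probability rule; a plain 0.5-threshold argmax rule is available by flag);
* **kNN** — Euclidean k-nearest-neighbour majority vote, k in 1–10, with
  deterministic tie rules: equal distances rank by training order (stable
  sort); tied votes go to the nearer neighbour's label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import DegenerateLabelingError, ModelError, SchemaError
from .evaluation import CLASS1, CLASS2, error_rate_from_rates, make_folds
from .preprocess import NormStats, normalize
from .regression import _pca_scores, _pls_scores


@dataclass
class ClassLabeling:
    """Per-observation elite labels with the range threshold that made them."""

    labels: pd.Series            # values in {Class1, Class2}
    threshold: float
    fraction: float
    trait_min: float
    trait_max: float

    def to_frame(self) -> pd.DataFrame:
        out = self.labels.rename("class").to_frame()
        out["threshold"] = self.threshold
        out["fraction"] = self.fraction
        out.index.name = "observation_id"
        return out


def dichotomize(values: pd.Series, fraction: float = 0.8) -> ClassLabeling:
    """Range-based two-class labeling: Class2 = upper (1−fraction) of the range.

    Values exactly at the threshold are Class2 (the elite tail is closed), so
    the maximum is always Class2 and the minimum always Class1.  Invariant to
    increasing affine transforms of the trait.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    v = values.dropna()
    if v.nunique() < 2:
        raise DegenerateLabelingError("trait range is zero: all values identical")
    lo, hi = float(v.min()), float(v.max())
    threshold = lo + fraction * (hi - lo)
    labels = pd.Series(np.where(v >= threshold, CLASS2, CLASS1),
                       index=v.index, name="class")
    if (labels == CLASS1).sum() == 0 or (labels == CLASS2).sum() == 0:
        raise DegenerateLabelingError("dichotomization produced an empty class")
    return ClassLabeling(labels=labels, threshold=threshold, fraction=fraction,
                         trait_min=lo, trait_max=hi)


@dataclass
class ClassifierSpec:
    family: str = "PLS_DA"  # PCA_LDA | PLS_DA | KNN
    search_range: range = dc_field(default_factory=lambda: range(1, 21))
    fixed: int | None = None
    cv_folds: int = 10
    plsda_rule: str = "gaussian"  # or "argmax" (0.5 threshold on the indicator)

    def __post_init__(self):
        if self.family == "KNN" and max(self.search_range) > 20:
            raise ValueError("kNN search range too large")


@dataclass
class ClassifierFit:
    family: str
    selected: dict
    feature_names: list
    norm: NormStats                    # mean-centering statistics
    payload: dict
    cv_predictions: pd.Series | None = None
    cv_error_path: dict | None = None
    folds: np.ndarray | None = None
    fitted_labels: pd.Series | None = None

    def to_summary(self) -> dict:
        return {"family": self.family, "selected": dict(self.selected),
                "n_features": len(self.feature_names),
                "normalization": self.norm.mode}


def _macro_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    r1 = float((y_pred[y_true == CLASS1] == CLASS1).mean()) \
        if (y_true == CLASS1).any() else np.nan
    r2 = float((y_pred[y_true == CLASS2] == CLASS2).mean()) \
        if (y_true == CLASS2).any() else np.nan
    return error_rate_from_rates(np.nan_to_num(r1, nan=0.0),
                                 np.nan_to_num(r2, nan=0.0))


def _check_classes(labels: pd.Series) -> None:
    present = set(labels.unique())
    if present != {CLASS1, CLASS2}:
        raise ModelError(f"need both classes present, got {sorted(present)}")


# ---------------------------------------------------------------------------
# family-specific fold fitters: fit(X_train_centered_numpy, y_train) -> state,
# predict(state, X_test_centered_numpy) -> labels; parametrized by hyperparam


def _lda_prepare(Xc, ylab, kmax):
    T, R = _pca_scores(Xc, kmax)
    return {"T": T, "R": R}


def _lda_fit(cache, Xc, ylab, k):
    k = min(k, cache["T"].shape[1])
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear-score warnings
        lda.fit(cache["T"][:, :k], ylab)
    return {"R": cache["R"][:, :k], "lda": lda}


def _lda_predict(state, Xc):
    return state["lda"].predict(Xc @ state["R"])


def _plsda_prepare(Xc, ylab, kmax, rule="gaussian"):
    ind = (ylab == CLASS2).astype(float)
    T, R = _pls_scores(Xc, ind - ind.mean(), kmax)
    ss = (T ** 2).sum(axis=0)
    ss[ss == 0] = np.inf
    c = (T * (ind - ind.mean())[:, None]).sum(axis=0) / ss
    return {"T": T, "R": R, "c": c, "ind": ind, "rule": rule}


def _plsda_fit(cache, Xc, ylab, k):
    k = min(k, cache["T"].shape[1])
    ind = cache["ind"]
    beta = cache["R"][:, :k] @ cache["c"][:k]
    scores = Xc @ beta + ind.mean()
    state = {"beta": beta, "intercept": float(ind.mean()),
             "rule": cache["rule"]}
    if cache["rule"] == "gaussian":
        for cls, mask in ((CLASS1, ind == 0), (CLASS2, ind == 1)):
            s = scores[mask]
            mu = float(s.mean())
            sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
            state[cls] = (mu, max(sd, 1e-6))
    return state


def _plsda_predict(state, Xc):
    scores = Xc @ state["beta"] + state["intercept"]
    if state["rule"] == "argmax":
        return np.where(scores >= 0.5, CLASS2, CLASS1)
    mu1, sd1 = state[CLASS1]
    mu2, sd2 = state[CLASS2]
    # equal-prior class-conditional Gaussian log-likelihoods
    ll1 = -np.log(sd1) - 0.5 * ((scores - mu1) / sd1) ** 2
    ll2 = -np.log(sd2) - 0.5 * ((scores - mu2) / sd2) ** 2
    return np.where(ll2 > ll1, CLASS2, CLASS1)


def knn_predict(X_train: np.ndarray, y_train: np.ndarray, X_query: np.ndarray,
                k: int) -> np.ndarray:
    """Euclidean kNN majority vote with deterministic tie rules.

    Distance ties rank by training order (stable sort); vote ties resolve to
    the nearer (best-ranked) neighbour's label.
    """
    X_query = np.asarray(X_query, float)
    X_train = np.asarray(X_train, float)
    if not np.isfinite(X_query).all():
        raise ModelError("non-finite features in kNN query")
    if not np.isfinite(X_train).all():
        raise ModelError("non-finite features in kNN training data")
    d = cdist(X_query, X_train)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    labels = np.asarray(y_train, dtype=object)[order]
    out = np.empty(len(X_query), dtype=object)
    for i in range(len(X_query)):
        votes = pd.Series(labels[i]).value_counts()
        top = votes[votes == votes.max()].index
        if len(top) == 1:
            out[i] = top[0]
        else:  # tie: the nearest neighbour among the tied labels decides
            for lab in labels[i]:
                if lab in set(top):
                    out[i] = lab
                    break
    return out


def _generic_fit(X: pd.DataFrame, labels: pd.Series, spec: ClassifierSpec,
                 seed: int, folds, fold_prepare, fold_fit, fold_predict,
                 param_name: str) -> ClassifierFit:
    labels = labels.loc[X.index]
    _check_classes(labels)
    yv = labels.to_numpy(dtype=object)
    if folds is None:
        folds = make_folds(len(X), spec.cv_folds, seed, stratify_labels=yv)
    params = [spec.fixed] if spec.fixed is not None else list(spec.search_range)

    oof = {p: np.empty(len(X), dtype=object) for p in params}
    for f in np.unique(folds):
        te = folds == f
        Xtr_c, stats = normalize(X.loc[~te], "mean_center")
        Xte_c = stats.apply(X.loc[te]).to_numpy()
        Xtr = Xtr_c.to_numpy()
        cache = fold_prepare(Xtr, yv[~te], max(params))
        for p in params:
            state = fold_fit(cache, Xtr, yv[~te], p)
            oof[p][te] = fold_predict(state, Xte_c)
    err = {p: _macro_error(yv, oof[p]) for p in params}
    best = min(err, key=lambda p: (err[p], p))

    Xc, stats = normalize(X, "mean_center")
    Xca = Xc.to_numpy()
    cache = fold_prepare(Xca, yv, best)
    state = fold_fit(cache, Xca, yv, best)
    fitted = fold_predict(state, Xca)
    return ClassifierFit(
        family=spec.family, selected={param_name: int(best)},
        feature_names=list(X.columns), norm=stats, payload=state,
        cv_predictions=pd.Series(oof[best], index=X.index),
        cv_error_path={int(p): float(e) for p, e in err.items()}, folds=folds,
        fitted_labels=pd.Series(fitted, index=X.index))


def fit_pca_lda(X: pd.DataFrame, labels: pd.Series,
                spec: ClassifierSpec | None = None, seed: int = 0,
                folds=None) -> ClassifierFit:
    """PCA scores feeding a linear discriminant; PCs searched over 1–20."""
    spec = spec or ClassifierSpec(family="PCA_LDA")
    fit = _generic_fit(X, labels, spec, seed, folds,
                       _lda_prepare, _lda_fit, _lda_predict, "n_components")
    fit.family = "PCA_LDA"
    return fit


def fit_plsda(X: pd.DataFrame, labels: pd.Series,
              spec: ClassifierSpec | None = None, seed: int = 0,
              folds=None) -> ClassifierFit:
    """PLS-DA: indicator PLS regression, LVs searched over 1–20."""
    spec = spec or ClassifierSpec(family="PLS_DA")

    def prepare(Xtr, ytr, kmax):
        return _plsda_prepare(Xtr, ytr, kmax, rule=spec.plsda_rule)

    fit = _generic_fit(X, labels, spec, seed, folds,
                       prepare, _plsda_fit, _plsda_predict,
                       "n_latent_variables")
    fit.family = "PLS_DA"
    return fit


def fit_knn(X: pd.DataFrame, labels: pd.Series,
            spec: ClassifierSpec | None = None, seed: int = 0,
            folds=None) -> ClassifierFit:
    """Euclidean kNN; k searched over 1–10 by CV error rate."""
    spec = spec or ClassifierSpec(family="KNN",
                                  search_range=range(1, 11))
    if max(spec.search_range) > 10 and spec.fixed is None:
        spec.search_range = range(1, 11)

    def prepare(Xtr, ytr, kmax):
        if not np.isfinite(Xtr).all():
            raise ModelError("non-finite features in kNN training data")
        return {}

    def fold_fit(cache, Xtr, ytr, k):
        return {"X": Xtr, "y": ytr, "k": k}

    def fold_predict(state, Xq):
        if not np.isfinite(np.asarray(Xq, float)).all():
            raise ModelError("non-finite features in kNN query")
        return knn_predict(state["X"], state["y"], Xq, state["k"])

    fit = _generic_fit(X, labels, spec, seed, folds, prepare, fold_fit,
                       fold_predict, "k")
    fit.family = "KNN"
    return fit


def predict_class(model: ClassifierFit, X_new: pd.DataFrame) -> pd.Series:
    """Deterministic labels on new data; features aligned by name."""
    missing = [c for c in model.feature_names if c not in X_new.columns]
    if missing:
        raise SchemaError(f"missing features: {missing[:5]}"
                          f"{'...' if len(missing) > 5 else ''}")
    X = X_new.loc[:, model.feature_names]
    Xc = model.norm.apply(X).to_numpy(dtype=float)
    state = model.payload
    if model.family == "PCA_LDA":
        pred = _lda_predict(state, Xc)
    elif model.family == "PLS_DA":
        pred = _plsda_predict(state, Xc)
    elif model.family == "KNN":
        pred = knn_predict(state["X"], state["y"], Xc, state["k"])
    else:  # pragma: no cover
        raise ModelError(f"unknown family {model.family}")
    return pd.Series(pred, index=X_new.index, name="class")


CLASSIFIER_FITTERS = {
    "PCA_LDA": fit_pca_lda,
    "PLS_DA": fit_plsda,
    "KNN": fit_knn,
}
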