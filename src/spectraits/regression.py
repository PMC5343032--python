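"""Multivariate regressors for full-spectrum trait prediction.

Four families, each tuned by 10-fold cross-validated RMSE on seeded folds and
refit on all data at the selected hyperparameter:

* **PCR** — principal component analysis followed by ordinary least squares on
  the leading scores; component count searched over 1–20.
* **PLSR** — partial least squares latent factors maximizing X–y covariance
  (NIPALS, via scikit-learn); factor count searched over 1–20.
* **RR** — ridge regression over a grid of 100 penalties λ log-spaced on
  [1e−2, 1e10]; the full coefficient path comes from one SVD per fold.
* **SVR** — ε-insensitive support vector regression with C = 1, ε = 0.1;
  linear / polynomial (degree 3) / radial-basis / sigmoid kernels are each
  cross-validated and the minimum-CV-RMSE kernel is kept.  Kernel scale γ is
  set by the median heuristic on pairwise distances.

Inputs are z-scored inside each training fold (statistics replayed on the
held-out fold), so hyperparameter selection sees no leakage.  Validation
metrics are computed on the pooled out-of-fold predictions of the selected
hyperparameter — selection and validation share the same folds, the usual
chemometrics protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.svm import SVR

from .errors import ModelError, SchemaError
from .evaluation import make_folds, rmse
from .preprocess import NormStats, normalize

RIDGE_GRID_SIZE = 100
RIDGE_GRID_BOUNDS = (1e-2, 1e10)
SVR_KERNELS = ("linear", "poly", "rbf", "sigmoid")


def default_lambda_grid() -> np.ndarray:
    """100 ridge penalties log-spaced on [1e−2, 1e10] (endpoints exact)."""
    return np.logspace(np.log10(RIDGE_GRID_BOUNDS[0]),
                       np.log10(RIDGE_GRID_BOUNDS[1]), RIDGE_GRID_SIZE)


@dataclass
class ComponentSpec:
    """Search space for PCR / PLSR component counts."""

    family: str = "PLSR"  # "PCR" or "PLSR"
    n_components_search: range = dc_field(default_factory=lambda: range(1, 21))
    fixed_n: int | None = None  # skip the search and use exactly this many
    cv_folds: int = 10


@dataclass
class RidgeSpec:
    lambda_grid: np.ndarray = dc_field(default_factory=default_lambda_grid)
    cv_folds: int = 10

    def __post_init__(self):
        g = np.asarray(self.lambda_grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        self.lambda_grid = g


@dataclass
class SvrSpec:
    C: float = 1.0
    epsilon: float = 0.1
    kernel_candidates: tuple = SVR_KERNELS
    degree: int = 3
    cv_folds: int = 10


@dataclass
class FitResult:
    """A fitted regressor with everything needed to predict and to report.

    ``coef``/``intercept`` are on the z-scored feature scale for the linear
    families (PCR, PLSR, RR); SVR keeps its kernel machine in ``payload``.
    """

    family: str
    selected: dict
    feature_names: list
    norm: NormStats
    coef: np.ndarray | None = None
    intercept: float | None = None
    payload: object = None
    cv_predictions: pd.Series | None = None   # out-of-fold, selected hyperparam
    cv_rmse_path: dict | None = None          # hyperparam value -> CV RMSE
    folds: np.ndarray | None = None
    fitted_values: pd.Series | None = None    # in-sample predictions

    def to_summary(self) -> dict:
        out = {"family": self.family, "selected": {
            k: (v if not isinstance(v, (np.floating, np.integer)) else v.item())
            for k, v in self.selected.items()},
            "n_features": len(self.feature_names),
            "normalization": self.norm.mode}
        if self.coef is not None:
            out["coef"] = [float(c) for c in np.ravel(self.coef)]
            out["intercept"] = float(self.intercept)
        return out


def predict(model: FitResult, X_new: pd.DataFrame) -> pd.Series:
    """Deterministic predictions on new data; features aligned by name."""
    missing = [c for c in model.feature_names if c not in X_new.columns]
    if missing:
        raise SchemaError(f"missing features: {missing[:5]}"
                          f"{'...' if len(missing) > 5 else ''}")
    X = X_new.loc[:, model.feature_names]
    Xn = model.norm.apply(X).to_numpy(dtype=float)
    if model.coef is not None:
        yhat = Xn @ np.ravel(model.coef) + model.intercept
    else:
        yhat = model.payload.predict(Xn)
    return pd.Series(yhat, index=X_new.index, name="predicted")


# ---------------------------------------------------------------------------
# component models (PCR / PLSR): cumulative predictions over orthogonal scores


def _pca_scores(Xn: np.ndarray, kmax: int):
    """Centered-PCA scores and the rotation mapping new data to scores."""
    U, s, Vt = np.linalg.svd(Xn, full_matrices=False)
    k = min(kmax, int((s > s[0] * 1e-12).sum()) if s.size else 0)
    T = U[:, :k] * s[:k]
    return T, Vt[:k].T  # scores, loadings (p x k)


def _pls_scores(Xn: np.ndarray, yc: np.ndarray, kmax: int):
    """NIPALS PLS1 x-scores and rotations via scikit-learn (scale disabled)."""
    from sklearn.cross_decomposition import PLSRegression

    k = min(kmax, Xn.shape[1], Xn.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # component capping warnings
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(Xn, yc)
    R = pls.x_rotations_              # p x k, X_c @ R = scores
    T = Xn @ R
    return T, R


def _component_predictions(T_tr, y_tr, T_te):
    """OLS of y on leading score columns, cumulatively for every k.

    Scores are orthogonal (PCA exactly; PLS x-scores by construction), so the
    k-component fit is the cumulative sum of univariate projections.
    Returns (pred_te[k], pred_tr[k]) arrays of shape (n, kmax).
    """
    ybar = y_tr.mean()
    yc = y_tr - ybar
    ss = (T_tr ** 2).sum(axis=0)
    ss[ss == 0] = np.inf
    c = (T_tr * yc[:, None]).sum(axis=0) / ss
    pred_te = ybar + np.cumsum(T_te * c[None, :], axis=1)
    pred_tr = ybar + np.cumsum(T_tr * c[None, :], axis=1)
    return pred_te, pred_tr


def _fit_component_family(X: pd.DataFrame, y: pd.Series, spec: ComponentSpec,
                          seed: int = 0, folds=None) -> FitResult:
    if len(X) < 3:
        raise ModelError("need at least 3 observations")
    if spec.family == "PLSR" and float(np.std(y)) == 0.0:
        raise ModelError("degenerate response: y has zero variance")
    y = y.loc[X.index]
    kmax_global = max(spec.n_components_search) if spec.fixed_n is None else spec.fixed_n
    if folds is None:
        folds = make_folds(len(X), spec.cv_folds, seed)

    def scores_fn(Xn, yc, kmax):
        if spec.family == "PCR":
            return _pca_scores(Xn, kmax)
        return _pls_scores(Xn, yc, kmax)

    # cross-validated predictions for every component count at once
    n = len(X)
    oof = np.full((n, kmax_global), np.nan)
    yv = y.to_numpy(dtype=float)
    for f in np.unique(folds):
        te = folds == f
        Xtr_n, stats = normalize(X.loc[~te], "zscore")
        Xte_n = stats.apply(X.loc[te])
        ytr = yv[~te]
        T_tr, R = scores_fn(Xtr_n.to_numpy(), ytr - ytr.mean(), kmax_global)
        T_te = Xte_n.to_numpy() @ R
        pred_te, _ = _component_predictions(T_tr, ytr, T_te)
        k_here = pred_te.shape[1]
        oof[np.flatnonzero(te)[:, None], np.arange(k_here)[None, :]] = pred_te
        if k_here < kmax_global:  # rank-limited fold: pad with its best model
            oof[te, k_here:] = pred_te[:, [-1]]

    cv_rmse = {k: rmse(yv, oof[:, k - 1]) for k in range(1, kmax_global + 1)
               if (spec.fixed_n is None and k in spec.n_components_search)
               or (spec.fixed_n is not None and k == spec.fixed_n)}
    selected_n = min(cv_rmse, key=cv_rmse.get) if spec.fixed_n is None else spec.fixed_n

    # final refit on all data
    Xn, stats = normalize(X, "zscore")
    T, R = scores_fn(Xn.to_numpy(), yv - yv.mean(), selected_n)
    if T.shape[1] < selected_n:
        warnings.warn(f"{spec.family}: component count reduced to rank "
                      f"{T.shape[1]}", stacklevel=2)
        selected_n = T.shape[1]
    _, pred_tr = _component_predictions(T, yv, T)
    ybar = yv.mean()
    yc = yv - ybar
    ss = (T ** 2).sum(axis=0)
    ss[ss == 0] = np.inf
    c = (T * yc[:, None]).sum(axis=0) / ss
    beta = R[:, :selected_n] @ c[:selected_n]

    return FitResult(
        family=spec.family,
        selected={"n_components": int(selected_n)},
        feature_names=list(X.columns), norm=stats,
        coef=beta, intercept=float(ybar),
        cv_predictions=pd.Series(oof[:, selected_n - 1], index=X.index),
        cv_rmse_path=cv_rmse, folds=folds,
        fitted_values=pd.Series(pred_tr[:, selected_n - 1], index=X.index))


def fit_pcr(X: pd.DataFrame, y: pd.Series, spec: ComponentSpec | None = None,
            seed: int = 0, folds=None) -> FitResult:
    """Principal component regression (PCA + OLS on leading scores)."""
    spec = spec or ComponentSpec(family="PCR")
    if spec.family != "PCR":
        spec = ComponentSpec("PCR", spec.n_components_search, spec.fixed_n,
                             spec.cv_folds)
    return _fit_component_family(X, y, spec, seed, folds)


def fit_plsr(X: pd.DataFrame, y: pd.Series, spec: ComponentSpec | None = None,
             seed: int = 0, folds=None) -> FitResult:
    """Partial least squares regression (NIPALS latent factors)."""
    spec = spec or ComponentSpec(family="PLSR")
    if spec.family != "PLSR":
        spec = ComponentSpec("PLSR", spec.n_components_search, spec.fixed_n,
                             spec.cv_folds)
    return _fit_component_family(X, y, spec, seed, folds)


# ---------------------------------------------------------------------------
# ridge


def _ridge_path(Xn: np.ndarray, yv: np.ndarray, lams: np.ndarray):
    """Closed-form ridge coefficients for every λ from one SVD.

    β(λ) = V diag(s/(s²+λ)) Uᵀ (y − ȳ); the intercept is ȳ (X columns are
    centered).  Returns (betas p×L, ybar).
    """
    ybar = yv.mean()
    U, s, Vt = np.linalg.svd(Xn, full_matrices=False)
    a = U.T @ (yv - ybar)                       # (r,)
    d = s[:, None] / (s[:, None] ** 2 + lams[None, :])  # (r, L)
    betas = Vt.T @ (d * a[:, None])             # (p, L)
    return betas, ybar


def fit_ridge(X: pd.DataFrame, y: pd.Series, spec: RidgeSpec | None = None,
              seed: int = 0, folds=None) -> FitResult:
    """Ridge regression; λ selected by 10-fold CV RMSE over the 100-point grid."""
    spec = spec or RidgeSpec()
    y = y.loc[X.index]
    yv = y.to_numpy(dtype=float)
    lams = spec.lambda_grid
    if folds is None:
        folds = make_folds(len(X), spec.cv_folds, seed)
    oof = np.empty((len(X), len(lams)))
    for f in np.unique(folds):
        te = folds == f
        Xtr_n, stats = normalize(X.loc[~te], "zscore")
        Xte_n = stats.apply(X.loc[te]).to_numpy()
        betas, ybar = _ridge_path(Xtr_n.to_numpy(), yv[~te], lams)
        oof[te] = Xte_n @ betas + ybar
    cv = np.sqrt(np.mean((oof - yv[:, None]) ** 2, axis=0))
    best = int(np.argmin(cv))
    lam = float(lams[best])

    Xn, stats = normalize(X, "zscore")
    betas, ybar = _ridge_path(Xn.to_numpy(), yv, np.array([lam]))
    beta = betas[:, 0]
    return FitResult(
        family="RR", selected={"lambda": lam},
        feature_names=list(X.columns), norm=stats,
        coef=beta, intercept=float(ybar),
        cv_predictions=pd.Series(oof[:, best], index=X.index),
        cv_rmse_path={float(l): float(v) for l, v in zip(lams, cv)},
        folds=folds,
        fitted_values=pd.Series(Xn.to_numpy() @ beta + ybar, index=X.index))


# ---------------------------------------------------------------------------
# SVR


def median_heuristic_gamma(Xn: np.ndarray, max_rows: int = 200,
                           seed: int = 0) -> float:
    """γ = 1/(2 m²) with m the median pairwise Euclidean distance."""
    rng = np.random.default_rng(seed)
    if len(Xn) > max_rows:
        Xn = Xn[rng.choice(len(Xn), max_rows, replace=False)]
    d = pdist(Xn)
    m = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return float(1.0 / (2.0 * m ** 2))


def fit_svr(X: pd.DataFrame, y: pd.Series, spec: SvrSpec | None = None,
            seed: int = 0, folds=None) -> FitResult:
    """ε-insensitive SVR; the kernel minimizing 10-fold CV RMSE is kept."""
    spec = spec or SvrSpec()
    y = y.loc[X.index]
    yv = y.to_numpy(dtype=float)
    if folds is None:
        folds = make_folds(len(X), spec.cv_folds, seed)

    def make_svr(kernel, gamma):
        return SVR(kernel=kernel, C=spec.C, epsilon=spec.epsilon,
                   degree=spec.degree, gamma=gamma, coef0=0.0, max_iter=200000)

    oof_by_kernel, failures = {}, {}
    for kernel in spec.kernel_candidates:
        oof = np.empty(len(X))
        try:
            for f in np.unique(folds):
                te = folds == f
                Xtr_n, stats = normalize(X.loc[~te], "zscore")
                Xtr = Xtr_n.to_numpy()
                gamma = ("scale" if kernel == "linear"
                         else median_heuristic_gamma(Xtr, seed=seed))
                m = make_svr(kernel, gamma)
                m.fit(Xtr, yv[~te])
                oof[te] = m.predict(stats.apply(X.loc[te]).to_numpy())
        except Exception as exc:  # noqa: BLE001 - candidate skipped with warning
            warnings.warn(f"SVR kernel {kernel!r} failed: {exc}", stacklevel=2)
            failures[kernel] = str(exc)
            continue
        oof_by_kernel[kernel] = oof
    if not oof_by_kernel:
        raise ModelError(f"all SVR kernels failed: {failures}")

    cv = {k: rmse(yv, o) for k, o in oof_by_kernel.items()}
    kernel = min(cv, key=cv.get)

    Xn, stats = normalize(X, "zscore")
    Xa = Xn.to_numpy()
    gamma = "scale" if kernel == "linear" else median_heuristic_gamma(Xa, seed=seed)
    final = make_svr(kernel, gamma)
    final.fit(Xa, yv)
    return FitResult(
        family="SVR",
        selected={"kernel": kernel, "C": spec.C, "epsilon": spec.epsilon},
        feature_names=list(X.columns), norm=stats, payload=final,
        cv_predictions=pd.Series(oof_by_kernel[kernel], index=X.index),
        cv_rmse_path=cv, folds=folds,
        fitted_values=pd.Series(final.predict(Xa), index=X.index))


FAMILY_FITTERS = {
    "PCR": fit_pcr,
    "PLSR": fit_plsr,
    "RR": fit_ridge,
    "SVR": fit_svr,
}
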