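"""Missing-value exclusion, Local Outlier Factor screening, and normalization.

The canonical modeling order is: drop rows with any missing predictor or
response, score the remainder with LOF and drop points above the outlier
threshold, then normalize (z-score for regression pipelines, mean-centering
for classification pipelines — the only normalization detail stated per
method family).  Normalization statistics are always estimated on training
data and replayed on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from .errors import EmptyDatasetError

#: common LOF defaults; the screening method is named without parameters in
#: the protocol this mirrors, so these are configurable.
DEFAULT_LOF_NEIGHBORS = 20
DEFAULT_LOF_THRESHOLD = 1.5

NORMALIZATION_MODES = ("zscore", "mean_center", "none")


@dataclass
class NormStats:
    """Per-column statistics sufficient to replay a transform on new data."""

    mode: str
    mean: pd.Series
    sd: pd.Series | None = None  # sample (n-1) standard deviation

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.loc[:, self.mean.index]
        if self.mode == "none":
            return X.copy()
        out = X - self.mean
        if self.mode == "zscore":
            sd = self.sd.replace(0.0, 1.0)  # zero-variance columns: center only
            out = out / sd
        return out


@dataclass
class PreprocessReport:
    n_input: int = 0
    n_missing_dropped: int = 0
    n_outliers_dropped: int = 0
    n_retained: int = 0
    outlier_scores: pd.Series | None = None
    normalization: str = "none"
    pipeline_order: tuple[str, ...] = ("drop_missing", "lof", "normalize")
    dropped_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_missing_dropped": self.n_missing_dropped,
            "n_outliers_dropped": self.n_outliers_dropped,
            "n_retained": self.n_retained,
            "normalization": self.normalization,
            "pipeline_order": list(self.pipeline_order),
            "dropped_ids": [str(i) for i in self.dropped_ids],
        }


def drop_missing(X: pd.DataFrame, y: pd.Series):
    """Remove rows with any missing predictor or a missing response.

    Returns ``(X_kept, y_kept, report)``; raises :class:`EmptyDatasetError`
    when nothing survives.
    """
    y = y.loc[X.index]
    keep = X.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptyDatasetError("all rows removed by missing-value screening")
    report = PreprocessReport(
        n_input=len(X), n_missing_dropped=n_dropped,
        n_retained=int(keep.sum()),
        dropped_ids=list(X.index[~keep]))
    return X.loc[keep], y.loc[keep], report


def lof_scores(X: pd.DataFrame | np.ndarray,
               n_neighbors: int = DEFAULT_LOF_NEIGHBORS) -> pd.Series:
    """Local Outlier Factor per row (Euclidean metric).

    Scores are ~1 for points inside homogeneous regions and grow for isolated
    points; duplicate-heavy data is handled by the standard reachability
    convention (no division by zero).
    """
    arr = np.asarray(X, dtype=float)
    if n_neighbors >= len(arr):
        raise ValueError(f"n_neighbors={n_neighbors} must be < n rows={len(arr)}")
    lof = LocalOutlierFactor(n_neighbors=n_neighbors, metric="euclidean")
    lof.fit(arr)
    scores = -lof.negative_outlier_factor_
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(arr))
    return pd.Series(scores, index=index, name="lof")


def drop_outliers(X: pd.DataFrame, y: pd.Series,
                  n_neighbors: int = DEFAULT_LOF_NEIGHBORS,
                  threshold: float = DEFAULT_LOF_THRESHOLD):
    """LOF-screen rows (scores computed on z-scored columns); drop score > threshold."""
    Xn, _ = normalize(X, "zscore")
    scores = lof_scores(Xn, min(n_neighbors, len(X) - 1))
    keep = scores <= threshold
    if not keep.any():
        raise EmptyDatasetError("LOF screening removed every row")
    report = PreprocessReport(
        n_input=len(X), n_outliers_dropped=int((~keep).sum()),
        n_retained=int(keep.sum()), outlier_scores=scores,
        dropped_ids=list(X.index[~keep]))
    return X.loc[keep], y.loc[keep], report


def normalize(X: pd.DataFrame, mode: str = "zscore"):
    """Column-wise normalization with stored statistics for replay.

    ``zscore``: (x − mean)/sd with sample (n−1) sd, zero-variance columns are
    centered only; ``mean_center``: x − mean; ``none``: identity.
    Returns ``(X_transformed, NormStats)``.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1).fillna(0.0) if mode == "zscore" else None
    stats = NormStats(mode=mode, mean=mean, sd=sd)
    return stats.apply(X), stats


def preprocess(X: pd.DataFrame, y: pd.Series, *,
               lof_neighbors: int = DEFAULT_LOF_NEIGHBORS,
               lof_threshold: float = DEFAULT_LOF_THRESHOLD,
               normalization: str = "zscore"):
    """Canonical pipeline: drop_missing -> LOF screen -> record normalization.

    The returned X is *not* yet normalized — model fits estimate normalization
    statistics inside each training fold to avoid leakage — but the report
    records the mode the downstream fit will use.
    """
    X1, y1, rep_missing = drop_missing(X, y)
    if len(X1) > max(3, lof_neighbors):
        X2, y2, rep_lof = drop_outliers(X1, y1, lof_neighbors, lof_threshold)
    else:
        X2, y2 = X1, y1
        rep_lof = PreprocessReport(n_input=len(X1), n_retained=len(X1))
    report = PreprocessReport(
        n_input=rep_missing.n_input,
        n_missing_dropped=rep_missing.n_missing_dropped,
        n_outliers_dropped=rep_lof.n_outliers_dropped,
        n_retained=rep_lof.n_retained,
        outlier_scores=rep_lof.outlier_scores,
        normalization=normalization,
        dropped_ids=rep_missing.dropped_ids + rep_lof.dropped_ids)
    return X2, y2, report
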