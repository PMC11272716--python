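"""Layer-specific preprocessing.

Transcript counts: low-count gene filtering and median-of-ratios size-factor
normalisation (the standard count-normalisation used by differential
expression tools).  Intensity layers: log transformation.  All layers:
PCA-based sample outlier removal using a Hotelling's T-squared limit on the
leading principal-component scores, applied substance by substance.

The estimators follow scikit-learn conventions (``fit``/``transform``,
fitted attributes with trailing underscores) and operate on plain
samples x features arrays or DataFrames; the module-level functions are thin
wrappers that work on :class:`~grouprax.matrix.FeatureMatrix` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted, validate_data

from .matrix import FeatureMatrix

__all__ = [
    "LowCountFilter",
    "MedianRatioNormalizer",
    "PCAOutlierDetector",
    "OutlierReport",
    "filter_low_counts",
    "normalize_median_ratio",
    "log_transform",
    "pca_outlier_removal",
]

log = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    """Record of a PCA outlier-removal pass on one layer."""

    layer: str
    removed: list[str]
    confidence: float
    scores: pd.DataFrame | None = None
    t2: pd.Series | None = field(default=None, repr=False)
    t2_limit: float | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t2": self.t2})
        df["removed"] = df.index.isin(self.removed)
        df["t2_limit"] = self.t2_limit
        df["layer"] = self.layer
        return df


class LowCountFilter(TransformerMixin, BaseEstimator):
    """Drop features whose total count over all samples is below a threshold.

    The default reading of a "low counts (< 10 across all samples)" prefilter:
    a feature is kept iff its column sum over all samples is >= ``min_total``.
    ``mode="max"`` switches to the alternative per-sample-maximum reading.
    Samples are never removed.
    """

    def __init__(self, min_total: int = 10, mode: str = "sum"):
        self.min_total = min_total
        self.mode = mode

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=1)
        if (X < 0).any():
            raise ValueError("negative counts")
        if self.mode not in ("sum", "max"):
            raise ValueError(f"unknown mode {self.mode!r}")
        stat = X.sum(axis=0) if self.mode == "sum" else X.max(axis=0)
        self.keep_mask_ = stat >= self.min_total
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X[:, self.keep_mask_]


class MedianRatioNormalizer(TransformerMixin, BaseEstimator):
    """Median-of-ratios count normalisation.

    Per-sample size factor = median over reference features of
    count / geometric-mean-of-that-feature, where reference features are
    those with a strictly positive count in every sample.  Each sample's
    counts are divided by its size factor, making samples comparable in
    sequencing depth.  This is the classical size-factor estimator of
    count-based differential-expression analysis.
    """

    def fit(self, X, y=None):
        X = validate_data(self, X)
        self.size_factors_ = self._size_factors(X)
        return self

    def fit_transform(self, X, y=None):
        # size factors depend on the same matrix being transformed
        X = validate_data(self, X)
        self.size_factors_ = self._size_factors(X)
        return X / self.size_factors_[:, None]

    @staticmethod
    def _size_factors(X: np.ndarray) -> np.ndarray:
        if (X < 0).any():
            raise ValueError("negative counts")
        ref = (X > 0).all(axis=0)
        if not ref.any():
            raise ValueError(
                "no feature has a positive count in every sample; "
                "consider adding a pseudo-count before normalisation"
            )
        logX = np.log(X[:, ref])
        log_gm = logX.mean(axis=0)  # log geometric mean per reference feature
        sf = np.exp(np.median(logX - log_gm, axis=1))
        return sf

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X / self._size_factors(X)[:, None]


class PCAOutlierDetector(BaseEstimator):
    """Flag samples outside a Hotelling's T-squared confidence limit on PC scores.

    The matrix is mean-centred, projected onto the first ``n_components``
    principal components, and each sample's T-squared statistic
    ``sum(score_k^2 / eigval_k)`` is compared with the F-distribution based
    limit at level ``conf``.  One removal pass per call.

    Attributes
    ----------
    t2_ : ndarray
        Per-sample T-squared statistics.
    t2_limit_ : float
        The confidence limit.
    outlier_mask_ : ndarray of bool
        True for samples beyond the limit.
    """

    def __init__(self, conf: float = 0.95, n_components: int = 2):
        self.conf = conf
        self.n_components = n_components

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_samples=self.n_components + 2)
        if not 0 < self.conf < 1:
            raise ValueError("conf must be in (0, 1)")
        n = X.shape[0]
        k = self.n_components
        # full SVD: exact and deterministic regardless of matrix shape
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(X)
        # eigenvalues of the score covariance (ddof=1, matching PCA convention)
        eig = pca.explained_variance_
        eig = np.where(eig > 0, eig, np.inf)  # collapsed components carry no signal
        self.t2_ = (scores**2 / eig).sum(axis=1)
        # Hotelling's T2 ~ k(n-1)(n+1)/(n(n-k)) * F(k, n-k) for a new observation;
        # the in-sample variant k(n-1)/(n-k) F is the conventional score-plot ellipse
        self.t2_limit_ = (
            k * (n - 1) / (n - k) * stats.f.ppf(self.conf, k, n - k)
        )
        self.outlier_mask_ = self.t2_ > self.t2_limit_
        self.scores_ = scores
        return self

    def predict(self, X=None):
        """Return +1 for inliers, -1 for outliers of the fitted matrix."""
        check_is_fitted(self)
        return np.where(self.outlier_mask_, -1, 1)


# -- FeatureMatrix wrappers ----------------------------------------------------


def filter_low_counts(counts: FeatureMatrix, min_total: int = 10, mode: str = "sum") -> FeatureMatrix:
    """Drop low-count features from a transcript-count layer."""
    vals = counts.values.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("count matrix must be integer-valued")
    f = LowCountFilter(min_total=min_total, mode=mode).fit(vals)
    kept = counts.values.columns[f.keep_mask_]
    log.info("low-count filter: kept %d/%d features", len(kept), counts.n_features)
    return counts.subset_features(kept)


def normalize_median_ratio(counts: FeatureMatrix) -> FeatureMatrix:
    """Median-of-ratios normalisation of a count layer; size factors logged."""
    norm = MedianRatioNormalizer()
    out = norm.fit_transform(counts.values.to_numpy(dtype=float))
    log.info(
        "median-of-ratios size factors: %s",
        np.array2string(norm.size_factors_, precision=4),
    )
    fm = FeatureMatrix(
        counts.layer,
        pd.DataFrame(out, index=counts.values.index, columns=counts.values.columns),
        counts.meta,
    )
    fm.size_factors = pd.Series(norm.size_factors_, index=counts.values.index)
    return fm


def log_transform(fm: FeatureMatrix, base: float = 2.0) -> FeatureMatrix:
    """Log-transform intensities with offset = half the minimum positive value."""
    vals = fm.values.to_numpy(dtype=float)
    pos = vals[vals > 0]
    offset = pos.min() / 2 if pos.size else 1.0
    out = np.log(vals + offset) / np.log(base)
    return FeatureMatrix(
        fm.layer,
        pd.DataFrame(out, index=fm.values.index, columns=fm.values.columns),
        fm.meta,
        raw=False,
    )


def pca_outlier_removal(
    fm: FeatureMatrix,
    conf: float = 0.95,
    n_components: int = 2,
    per_substance: bool = True,
) -> tuple[FeatureMatrix, list[OutlierReport]]:
    """Remove PCA outliers beyond the T-squared confidence limit.

    With ``per_substance=True`` (default) the detector is applied to each
    substance's samples (treated plus its controls) separately, matching a
    per-substance quality-control pass; samples flagged in any pass are
    removed.  At most one removal pass per call.
    """
    reports: list[OutlierReport] = []
    removed: list[str] = []
    groups = (
        [(s, fm.meta.index[fm.meta["substance"] == s]) for s in fm.meta["substance"].unique()]
        if per_substance
        else [("all", fm.meta.index)]
    )
    for label, idx in groups:
        sub = fm.values.loc[idx].to_numpy(dtype=float)
        det = PCAOutlierDetector(conf=conf, n_components=n_components).fit(sub)
        hits = list(pd.Index(idx)[det.outlier_mask_])
        removed.extend(hits)
        reports.append(
            OutlierReport(
                layer=fm.layer,
                removed=hits,
                confidence=conf,
                scores=pd.DataFrame(det.scores_, index=idx),
                t2=pd.Series(det.t2_, index=idx),
                t2_limit=det.t2_limit_,
            )
        )
        if hits:
            log.info("PCA outliers removed (%s, %s): %s", fm.layer, label, hits)
    keep = [s for s in fm.sample_ids if s not in set(removed)]
    return fm.subset_samples(keep), reports
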