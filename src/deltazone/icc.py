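"""Reproducibility filtering of features by intraclass correlation.

Two raters delineate the same ROIs on a reproducibility subset of subjects;
features whose two-rater agreement is weak are discarded before modelling.
Agreement is measured by ICC(2,1) — two-way random effects, absolute
agreement, single rater — computed from the two-way ANOVA mean squares:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with n subjects, k = 2 raters, MSR/MSC/MSE the subject, rater and residual
mean squares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["icc_2_1", "IccFilter", "icc_filter"]


def icc_2_1(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) per column of two (subjects x features) arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("the two rating tables must have identical shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    k = 2.0
    grand = (a + b).sum(axis=0) / (k * n)
    subj_mean = (a + b) / k
    rater_mean_a = a.mean(axis=0)
    rater_mean_b = b.mean(axis=0)

    ss_rows = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((rater_mean_a - grand) ** 2 + (rater_mean_b - grand) ** 2)
    ss_tot = ((a - grand) ** 2 + (b - grand) ** 2).sum(axis=0)
    ss_err = ss_tot - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - mse) / denom, 0.0)
    return icc


class IccFilter(SelectorMixin, BaseEstimator):
    """Feature selector keeping columns with two-rater ICC(2,1) above a
    threshold.

    Fit on the first rater's table ``X`` with the second rater's table
    passed as ``ratings_b``; transform then subsets any feature matrix with
    the same columns.

    Parameters
    ----------
    threshold : float
        Features with ICC strictly greater than this are kept.

    Attributes
    ----------
    icc_ : ndarray of shape (n_features,)
        Per-feature ICC(2,1) estimates.
    """

    def __init__(self, threshold: float = 0.8):
        self.threshold = threshold

    def fit(self, X, y=None, *, ratings_b=None):
        if ratings_b is None:
            raise ValueError("IccFilter.fit requires ratings_b, the second rater's table")
        X = validate_data(self, X, ensure_min_samples=3)
        b = np.asarray(ratings_b, dtype=float)
        self.icc_ = icc_2_1(X, b)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "icc_")
        return self.icc_ > self.threshold


def icc_filter(
    ratings_a: pd.DataFrame,
    ratings_b: pd.DataFrame,
    threshold: float = 0.8,
) -> list[str]:
    """Names of features whose two-rater ICC(2,1) exceeds ``threshold``.

    Both tables are subjects x features with identical index and columns
    (rows aligned by index before comparison).
    """
    if set(ratings_a.columns) != set(ratings_b.columns):
        raise ValueError("rating tables must share feature columns")
    b = ratings_b.reindex(index=ratings_a.index, columns=ratings_a.columns)
    if b.isna().any().any():
        raise ValueError("rating tables must cover the same subjects")
    icc = icc_2_1(ratings_a.to_numpy(float), b.to_numpy(float))
    return [c for c, v in zip(ratings_a.columns, icc) if v > threshold]
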