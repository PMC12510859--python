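"""Per-zone LASSO radiomics signatures and their logistic evaluation.

For each dose zone, an L1-penalized logistic regression over the subjects'
delta-feature matrix selects a sparse feature subset (penalty chosen by
10-fold cross-validated deviance); the radiomics signature is the pure
weighted sum RS = sum_i w_i * dRF_i of the selected features with their
LASSO coefficients, the intercept being left to the downstream logistic
model.  Signature and combined models are scored by ROC AUC with DeLong
confidence intervals and paired DeLong tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "LassoSignature",
    "RadiomicsSignature",
    "SignatureLogistic",
    "RocReport",
    "score_signature",
    "roc_auc",
    "delong_test",
]


@dataclass(frozen=True)
class RadiomicsSignature:
    """A zone's signature: selected delta-feature names and LASSO weights.

    The per-subject score is the weighted sum of the named features (plus an
    optional intercept, zero by default)."""

    zone_label: str
    feature_names: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float = 0.0
    lambda_: float | None = None
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "zone": self.zone_label,
                "features": list(self.feature_names),
                "weights": list(self.weights),
                "intercept": self.intercept,
                "lambda": self.lambda_,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RadiomicsSignature":
        d = json.loads(text)
        return cls(
            d["zone"], tuple(d["features"]), tuple(d["weights"]),
            d.get("intercept", 0.0), d.get("lambda"), d.get("seed"),
        )


def score_signature(sig: RadiomicsSignature, delta: pd.DataFrame) -> np.ndarray:
    """Per-subject signature score over a delta-feature table."""
    missing = [f for f in sig.feature_names if f not in delta.columns]
    if missing:
        raise KeyError(f"signature features missing from the table: {missing}")
    if not sig.feature_names:
        return np.full(len(delta), sig.intercept)
    X = delta[list(sig.feature_names)].to_numpy(float)
    return X @ np.asarray(sig.weights) + sig.intercept


class LassoSignature(BaseEstimator):
    """L1-penalized logistic feature selection over a delta-feature matrix.

    Columns are standardized internally; the penalty is chosen as the
    cross-validated deviance minimum over a log-spaced path, and the
    coefficients are reported back on the original feature scale.

    Parameters
    ----------
    n_folds : int
        Stratified CV folds for the penalty choice.
    n_lambdas : int
        Size of the penalty path.
    lambda_min_ratio : float
        Smallest penalty as a fraction of the data-derived maximum.
    lambda_rule : {"min"}
        Penalty choice rule (cross-validated deviance minimum).
    random_state : int
        Seed for the fold shuffling.

    Attributes
    ----------
    coef_ : ndarray
        Coefficients at the chosen penalty, on the original scale.
    lambda_path_, cv_deviance_, lambda_ : the penalty path, the mean CV
        deviance per penalty, and the chosen value.
    selected_ : boolean mask of nonzero coefficients.
    fold_assignments_ : fold index per training row.
    """

    def __init__(
        self,
        n_folds: int = 10,
        n_lambdas: int = 50,
        lambda_min_ratio: float = 1e-3,
        lambda_rule: str = "min",
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_rule = lambda_rule
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if hasattr(X, "columns"):
            pass
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("y contains a single class; LASSO logistic needs both")
        if self.lambda_rule != "min":
            raise ValueError("only the CV-deviance-minimum rule is implemented")
        n, p = X.shape
        scaler = StandardScaler().fit(X)
        scale = np.where(scaler.scale_ > 0, scaler.scale_, 1.0)
        Xs = (X - scaler.mean_) / scale
        yb = (y == classes.max()).astype(int)

        # glmnet-style path: lambda_max kills all coefficients
        pbar = yb.mean()
        lam_max = np.max(np.abs(Xs.T @ (yb - pbar))) / n
        lams = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)

        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(Xs, yb))
        self.fold_assignments_ = np.empty(n, dtype=int)
        for k, (_, test) in enumerate(folds):
            self.fold_assignments_[test] = k

        deviance = np.zeros((self.n_folds, self.n_lambdas))
        for k, (tr, te) in enumerate(folds):
            for j, lam in enumerate(lams):
                model = self._fit_at(Xs[tr], yb[tr], lam)
                probs = model.predict_proba(Xs[te])[:, 1]
                deviance[k, j] = 2.0 * log_loss(yb[te], probs, labels=[0, 1])
        self.cv_deviance_ = deviance.mean(axis=0)
        self.lambda_path_ = lams
        best = int(np.argmin(self.cv_deviance_))
        self.lambda_ = float(lams[best])

        final = self._fit_at(Xs, yb, self.lambda_)
        coef_std = final.coef_.ravel()
        self.coef_ = coef_std / scale
        self.intercept_ = float(
            final.intercept_[0] - np.sum(coef_std * scaler.mean_ / scale)
        )
        self.selected_ = self.coef_ != 0.0
        self.classes_ = classes
        self.n_features_in_ = p
        return self

    def _fit_at(self, X, y, lam: float) -> LogisticRegression:
        # sklearn objective: (1/C) * ||w||_1 + sum losses  =>  C = 1/(n*lam)
        C = 1.0 / max(len(y) * lam, 1e-12)
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000,
            random_state=self.random_state,
        ).fit(X, y)

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def to_signature(
        self, feature_names, zone_label: str
    ) -> RadiomicsSignature | None:
        """Package the nonzero coefficients as a zone signature (no
        intercept: the downstream logistic model supplies it).  Returns None
        when the penalty zeroed every coefficient."""
        check_is_fitted(self, "coef_")
        names = np.asarray(list(feature_names))
        sel = self.selected_
        if not sel.any():
            return None
        return RadiomicsSignature(
            zone_label=zone_label,
            feature_names=tuple(names[sel]),
            weights=tuple(self.coef_[sel]),
            lambda_=self.lambda_,
            seed=self.random_state,
        )


class SignatureLogistic(ClassifierMixin, BaseEstimator):
    """Logistic model over signature scores and covariates, with a small
    ridge grid (including no penalty) chosen by cross-validated log-loss.

    On perfect separation the unpenalized candidate is dropped and the model
    falls back to the best penalized fit, with a warning.

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients.
    alpha_ : chosen ridge strength (0 means plain maximum likelihood).
    """

    def __init__(
        self,
        alphas: tuple[float, ...] = (0.0, 0.01, 0.1, 1.0),
        n_folds: int = 10,
        random_state: int = 0,
    ):
        self.alphas = alphas
        self.n_folds = n_folds
        self.random_state = random_state

    @staticmethod
    def _lr(alpha: float, n: int, seed: int) -> LogisticRegression:
        C = 1e12 if alpha == 0 else 1.0 / (alpha * n)
        return LogisticRegression(C=C, solver="lbfgs", max_iter=5000,
                                  random_state=seed)

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2 or counts.min() < 2:
            raise ValueError("need a binary outcome with >= 2 subjects per class")
        n = len(y)
        yb = (y == classes.max()).astype(int)

        separated = self._is_separable(X, yb)
        alphas = list(self.alphas)
        if separated and 0.0 in alphas:
            warnings.warn(
                "perfectly separable data: falling back to a penalized fit",
                UserWarning,
            )
            alphas = [a for a in alphas if a > 0] or [0.1]

        n_folds = min(self.n_folds, counts.min())
        if len(alphas) > 1 and n_folds >= 2:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=self.random_state)
            losses = np.zeros(len(alphas))
            for tr, te in skf.split(X, yb):
                for i, a in enumerate(alphas):
                    m = self._lr(a, len(tr), self.random_state).fit(X[tr], yb[tr])
                    losses[i] += log_loss(yb[te], m.predict_proba(X[te])[:, 1],
                                          labels=[0, 1])
            self.alpha_ = float(alphas[int(np.argmin(losses))])
        else:
            self.alpha_ = float(alphas[0])

        self._model = self._lr(self.alpha_, n, self.random_state).fit(X, yb)
        self.coef_ = self._model.coef_.ravel()
        self.intercept_ = float(self._model.intercept_[0])
        self.classes_ = classes
        self.separation_ = bool(separated)
        return self

    @staticmethod
    def _is_separable(X, yb) -> bool:
        probe = LogisticRegression(C=1e12, solver="lbfgs", max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe.fit(X, yb)
        s = probe.decision_function(X)
        return s[yb == 1].min() > s[yb == 0].max()

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        X = validate_data(self, X, reset=False)
        return self._model.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = validate_data(self, X, reset=False)
        return self.classes_[self._model.predict(X)]

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = validate_data(self, X, reset=False)
        return self._model.decision_function(X)

    def conf_int(self, X, y, level: float = 0.95) -> np.ndarray:
        """Wald confidence intervals (intercept first, then slopes) from the
        observed information at the fitted coefficients."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xd = np.column_stack([np.ones(len(X)), X])
        beta = np.concatenate([[self.intercept_], self.coef_])
        eta = Xd @ beta
        w = 1.0 / (np.exp(eta) + np.exp(-eta) + 2.0)  # p(1-p)
        info = Xd.T @ (Xd * w[:, None])
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        zq = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([beta - zq * se, beta + zq * se])


# --------------------------------------------------------------------------
# ROC / DeLong

@dataclass(frozen=True)
class RocReport:
    """AUC with a DeLong 95% confidence interval and the ROC curve points."""

    auc: float
    ci_low: float
    ci_high: float
    variance: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)


def _placements(scores: np.ndarray, y: np.ndarray):
    """DeLong placement values: V10 over positives, V01 over negatives."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    return cmp_.mean(axis=1), 1.0 - cmp_.mean(axis=0)


def roc_auc(scores, y, level: float = 0.95) -> RocReport:
    """AUC (Mann-Whitney statistic) with DeLong variance and Wald CI."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    v10, v01 = _placements(scores, y)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    zq = stats.norm.ppf(0.5 + level / 2.0)
    half = zq * np.sqrt(var)
    fpr, tpr, thr = roc_curve(y, scores)
    return RocReport(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        variance=float(var),
        fpr=fpr, tpr=tpr, thresholds=thr,
    )


def delong_test(scores_a, scores_b, y) -> tuple[float, float]:
    """Paired DeLong test of AUC(a) = AUC(b) on the same subjects.

    Returns (z, two-sided p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    y = np.asarray(y).astype(int)
    va10, va01 = _placements(scores_a, y)
    vb10, vb01 = _placements(scores_b, y)
    m, n = len(va10), len(va01)
    auc_a, auc_b = va10.mean(), vb10.mean()

    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
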