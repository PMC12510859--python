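"""Cross-learner stability selection, combined models, and clinical-utility
evaluation.

Screening survivors are ranked by their importance in four learners (random
forest, gradient boosting, a single-hidden-layer network, and a recursive
partitioning tree), each fit per cross-validation fold; the variables with
the best aggregated rank are combined with the radiomics signature in nested
logistic models.  Model quality is reported as ROC AUC plus confusion-table
metrics at a Youden-derived threshold, a calibration curve with logistic
recalibration intercept/slope, and a decision curve (net benefit over
threshold probabilities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .signatures import SignatureLogistic, roc_auc

__all__ = [
    "StabilitySelector",
    "MetricsReport",
    "fit_combined_models",
    "classification_metrics",
    "calibration_curve",
    "decision_curve",
]

LEARNERS = ("random_forest", "gradient_boosting", "neural_net", "rpart")


def _make_learners(seed: int) -> dict[str, BaseEstimator]:
    # fixed small settings; all seeded
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=200, min_samples_leaf=2, random_state=seed
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=100, max_depth=2, random_state=seed
        ),
        "neural_net": MLPClassifier(
            hidden_layer_sizes=(5,), max_iter=1000, random_state=seed, alpha=1e-2
        ),
        "rpart": DecisionTreeClassifier(
            max_depth=4, min_samples_leaf=5, random_state=seed
        ),
    }


def _importance(name: str, model) -> np.ndarray:
    if name == "neural_net":
        return np.abs(model.coefs_[0]).sum(axis=1)
    return model.feature_importances_


class StabilitySelector(BaseEstimator):
    """Rank candidate variables by importance across four learners and CV
    folds; the ``top_k`` variables by aggregate rank are retained.

    Parameters
    ----------
    n_folds : int
        Cross-validation folds; each learner is fit once per fold.
    top_k : int
        Number of stable variables to return.
    aggregate : {"mean", "median"}
        Rank aggregation across the learner-by-fold grid.
    random_state : int
        Seeds folds and every learner.

    Attributes
    ----------
    ranks_ : DataFrame of per-(learner, fold) variable ranks (1 = most
        important).
    mean_rank_ : aggregated rank per variable.
    top_k_ : list of retained variable names, best first.
    """

    def __init__(
        self,
        n_folds: int = 10,
        top_k: int = 3,
        aggregate: str = "mean",
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.top_k = top_k
        self.aggregate = aggregate
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        if Xa.shape[1] < 2:
            raise ValueError("stability selection needs at least 2 candidates")
        y = np.asarray(y)
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")

        scaler = StandardScaler().fit(Xa)
        Xs = scaler.transform(Xa)
        skf = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.random_state
        )
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for fold, (tr, _) in enumerate(skf.split(Xs, y)):
                for lname, learner in _make_learners(self.random_state).items():
                    learner.fit(Xs[tr], y[tr])
                    imp = _importance(lname, learner)
                    ranks = stats.rankdata(-imp, method="average")
                    rows.append(
                        pd.Series(ranks, index=names, name=(lname, fold))
                    )
        self.ranks_ = pd.DataFrame(rows)
        self.ranks_.index = pd.MultiIndex.from_tuples(
            self.ranks_.index, names=["learner", "fold"]
        )
        agg = self.ranks_.mean() if self.aggregate == "mean" else self.ranks_.median()
        self.mean_rank_ = agg.sort_values(kind="stable")
        self.top_k_ = list(self.mean_rank_.index[: self.top_k])
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self


def fit_combined_models(
    train: pd.DataFrame,
    model_specs: dict[str, list[str]],
    outcome: str = "rp",
    n_folds: int = 10,
    random_state: int = 0,
) -> dict[str, SignatureLogistic]:
    """Fit one logistic model per entry of ``model_specs`` (model name ->
    predictor columns) on the training split only.

    Raises on a singular design (duplicated or constant predictors)."""
    models: dict[str, SignatureLogistic] = {}
    y = train[outcome].to_numpy()
    for name, cols in model_specs.items():
        X = train[cols].to_numpy(float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
            raise ValueError(f"singular design for model '{name}' (columns {cols})")
        m = SignatureLogistic(n_folds=n_folds, random_state=random_state)
        m.fit(X, y)
        models[name] = m
    return models


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-table metrics at a fixed probability threshold."""

    auc: float
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fp: int
    tn: int
    fn: int
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "AUC": self.auc, "ACC": self.accuracy, "SE": self.sensitivity,
            "SP": self.specificity, "PPV": self.ppv, "NPV": self.npv,
        }


def youden_threshold(probs, y) -> float:
    """Probability cutoff maximizing sensitivity + specificity - 1."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y).astype(int), probs)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    return min(t, 1.0)  # roc_curve's first threshold exceeds 1


def classification_metrics(
    probs,
    y,
    threshold: float | None = None,
    threshold_rule: str = "youden",
) -> MetricsReport:
    """AUC plus ACC/SE/SP/PPV/NPV at a threshold.

    If ``threshold`` is None it is derived from these data by the stated
    rule (Youden's J); for a validation split pass the training-derived
    threshold explicitly.  Undefined cells (no predicted positives or
    negatives) are reported as NaN with a warning flag, never imputed.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    if threshold is None:
        if threshold_rule != "youden":
            raise ValueError("only the Youden threshold rule is implemented")
        threshold = youden_threshold(probs, y)
    pred = probs >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    warns = []
    se = tp / (tp + fn) if tp + fn else np.nan
    sp = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    if tp + fp == 0:
        warns.append("no predicted positives: PPV undefined")
    if tn + fn == 0:
        warns.append("no predicted negatives: NPV undefined")
    return MetricsReport(
        auc=roc_auc(probs, y).auc,
        threshold=float(threshold),
        accuracy=(tp + tn) / len(y),
        sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        tp=tp, fp=fp, tn=tn, fn=fn,
        warnings=tuple(warns),
    )


def calibration_curve(
    probs,
    y,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float, float]:
    """Quantile-binned observed vs predicted risk, plus the logistic
    recalibration intercept and slope (fit of the outcome on logit(p)).

    Empty or duplicate quantile bins are merged.  Returns
    (points, intercept, slope)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    if len(y) < n_bins:
        raise ValueError("need at least one subject per bin")
    try:
        bins = pd.qcut(probs, q=n_bins, duplicates="drop")
        if bins.categories.size == 0:
            raise ValueError
    except ValueError:  # constant probabilities: one merged bin
        bins = pd.Series(["all"] * len(probs))
    df = pd.DataFrame({"prob": probs, "y": y, "bin": bins})
    points = (
        df.groupby("bin", observed=True)
        .agg(mean_predicted=("prob", "mean"), observed=("y", "mean"),
             n=("y", "size"))
        .reset_index(drop=True)
    )
    eps = 1e-12
    lp = np.log(np.clip(probs, eps, 1 - eps) / np.clip(1 - probs, eps, 1 - eps))
    if np.ptp(lp) < 1e-12 or y.min() == y.max():
        return points, np.nan, np.nan
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    return points, float(fit.params[0]), float(fit.params[1])


def decision_curve(
    probs,
    y,
    thresholds=None,
) -> pd.DataFrame:
    """Net benefit of the model, treat-all and treat-none over threshold
    probabilities:

        NB(pt) = TP/n - FP/n * pt/(1-pt)

    Thresholds at or above 1 are excluded."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y).astype(int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.00, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        pred = probs >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        odds = pt / (1.0 - pt)
        rows.append(
            {
                "threshold": pt,
                "nb_model": tp - fp * odds,
                "nb_all": prev - (1.0 - prev) * odds,
                "nb_none": 0.0,
            }
        )
    return pd.DataFrame(rows)
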