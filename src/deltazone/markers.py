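"""Hematological inflammation indices and univariate screening.

From longitudinal blood counts (neutrophils N, lymphocytes L, monocytes M,
platelets P) four inflammation indices are derived at each timepoint:

    PLR = P / L      NLR = N / L      LMR = L / M      SII = P * N / L

and, for weeks 2-5, a change value relative to the pre-treatment baseline.
Candidate predictors (clinical, dosimetric, signature and marker variables)
are then screened one at a time against the outcome; variables with
p < 0.1 survive to multivariable modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import TIMEPOINTS

__all__ = ["MARKERS", "compute_markers", "univariate_screen", "ScreeningResult"]

MARKERS = ("PLR", "NLR", "LMR", "SII")
_DELTA_WEEKS = ("2w", "3w", "4w", "5w")


def compute_markers(
    counts: pd.DataFrame,
    change: str = "difference",
) -> pd.DataFrame:
    """Per-timepoint inflammation indices plus their change from baseline.

    ``change="difference"`` (default) defines the week-w change as
    value(w) - value(baseline); ``"ratio"`` as value(w) / value(baseline).
    Indices at timepoints with a zero denominator come out as NaN (flagged
    missing, never imputed).

    Returns a table indexed like ``counts`` with columns ``<marker>_<tp>``
    and ``<marker>_d<w>``.
    """
    if change not in ("difference", "ratio"):
        raise ValueError("change must be 'difference' or 'ratio'")
    out = pd.DataFrame(index=counts.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        for tp in TIMEPOINTS:
            N = counts[f"N_{tp}"].to_numpy(float)
            L = counts[f"L_{tp}"].to_numpy(float)
            M = counts[f"M_{tp}"].to_numpy(float)
            P = counts[f"P_{tp}"].to_numpy(float)
            out[f"PLR_{tp}"] = _safe_div(P, L)
            out[f"NLR_{tp}"] = _safe_div(N, L)
            out[f"LMR_{tp}"] = _safe_div(L, M)
            out[f"SII_{tp}"] = _safe_div(P * N, L)
        for m in MARKERS:
            base = out[f"{m}_base"]
            for w in _DELTA_WEEKS:
                if change == "difference":
                    out[f"{m}_d{w}"] = out[f"{m}_{w}"] - base
                else:
                    out[f"{m}_d{w}"] = _safe_div(
                        out[f"{m}_{w}"].to_numpy(float), base.to_numpy(float)
                    )
    return out


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    res = np.divide(num, den, out=np.full(den.shape, np.nan), where=den != 0)
    return res


@dataclass(frozen=True)
class ScreeningResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    selected: bool


def univariate_screen(
    table: pd.DataFrame,
    outcome: str = "rp",
    alpha: float = 0.1,
    variables: list[str] | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen each candidate variable against a binary outcome.

    Continuous variables are routed by a per-group Shapiro-Wilk normality
    check: normal in both groups -> Welch t-test, otherwise Mann-Whitney U.
    Categorical variables use the chi-square test without continuity
    correction, falling back to Fisher's exact test when any expected cell
    count is below 5.  Variables with p < ``alpha`` are flagged selected.
    Constant variables are reported as untestable (p = NaN).
    """
    y = table[outcome].to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must be binary with both classes present")
    if variables is None:
        variables = [c for c in table.columns if c not in (outcome, "subject_id", "set")]

    rows = []
    for var in variables:
        col = table[var]
        mask = col.notna().to_numpy()
        v, g = col[mask], y[mask]
        if v.nunique() <= 1:
            rows.append(ScreeningResult(var, "untestable (constant)", np.nan, np.nan, False))
            continue
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 4:
            res = _screen_continuous(v.to_numpy(float), g, normality_alpha)
        else:
            res = _screen_categorical(v, g)
        rows.append(ScreeningResult(var, res[0], res[1], res[2], res[2] < alpha))
    report = pd.DataFrame([r.__dict__ for r in rows])
    return report


def _screen_continuous(v, g, normality_alpha):
    groups = [v[g == lvl] for lvl in np.unique(g)]
    if any(len(x) < 2 for x in groups):
        return ("untestable (group too small)", np.nan, np.nan)
    normal = all(
        len(x) >= 3 and stats.shapiro(x).pvalue > normality_alpha for x in groups
    )
    if normal:
        t = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        return ("t-test", float(t.statistic), float(t.pvalue))
    u = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    return ("mann-whitney", float(u.statistic), float(u.pvalue))


def _screen_categorical(v, g):
    tab = pd.crosstab(v, g).to_numpy()
    expected = stats.contingency.expected_freq(tab)
    if (expected < 5).any() and tab.shape == (2, 2):
        odds, p = stats.fisher_exact(tab)
        return ("fisher", float(odds), float(p))
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return ("chi-square", float(chi2), float(p))
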