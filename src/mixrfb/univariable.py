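"""Univariable descriptive layer: odds ratios, Wald intervals, ROC.

Reproduces a baseline-characteristics table: for each binary predictor the
2x2 cross-product odds ratio with the Wald confidence interval and z-test
(identical to the univariable logistic MLE on a saturated 2x2), for
continuous predictors the per-unit odds ratio from a univariable logistic
fit, and a descriptive single-variable ROC analysis. Repeated rows are
collapsed to one per patient (first observed day) before fitting, since the
baseline table describes patients, not patient-days.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.metrics import roc_curve

from .design import BINARY_CODING
from .metrics import compute_auc

__all__ = ["TwoByTwo", "UnivariableResult", "odds_ratio_2x2",
           "univariable_logistic", "roc_univariable", "table_one"]

Z95 = norm.ppf(0.975)


@dataclass
class TwoByTwo:
    """Counts: a deaths-exposed, b deaths-unexposed, c survivors-exposed,
    d survivors-unexposed."""
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class UnivariableResult:
    variable: str
    estimate: float                  # odds ratio
    ci: tuple[float, float]
    p_value: float
    n_used: int


def odds_ratio_2x2(t: TwoByTwo, variable: str = "",
                   continuity: bool = False) -> UnivariableResult:
    """Cross-product odds ratio with Wald CI and z-test on ln OR."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError(
                "zero cell in 2x2 table; pass continuity=True to apply the "
                "0.5 continuity correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(orr) - Z95 * se), math.exp(math.log(orr) + Z95 * se)
    z = math.log(orr) / se
    p = 2 * float(norm.sf(abs(z)))
    return UnivariableResult(variable, float(orr), (lo, hi), p,
                             int(t.a + t.b + t.c + t.d))


def _collapse(cohort: pd.DataFrame, variable: str, summary: str = "first") -> pd.DataFrame:
    """One row per patient: first observed day (baseline) or patient mean."""
    df = cohort.sort_values(["patient_id", "day"], kind="stable")
    df = df[df[variable].notna()]
    if df.empty:
        raise ValueError(f"variable {variable!r} has no observed values")
    if summary == "mean" and variable not in BINARY_CODING:
        agg = df.groupby("patient_id", sort=False).agg(
            value=(variable, "mean"), outcome=("outcome", "first"))
        return agg.reset_index()
    first = df.groupby("patient_id", sort=False).first().reset_index()
    return first.rename(columns={variable: "value"})[["patient_id", "value", "outcome"]]


def univariable_logistic(cohort: pd.DataFrame, variable: str) -> UnivariableResult:
    """Univariable logistic regression of death on one predictor.

    Binary predictors reduce exactly to the 2x2 cross-product odds ratio;
    continuous predictors return the per-unit odds ratio. Rows with a
    missing predictor are dropped (reflected in ``n_used``).
    """
    base = _collapse(cohort, variable)
    y = (base["outcome"] == "death").astype(int).to_numpy()
    if variable in BINARY_CODING:
        x = base["value"].map(BINARY_CODING[variable]).to_numpy()
        if np.unique(x).size < 2:
            raise ValueError(f"predictor {variable!r} is constant")
        t = TwoByTwo(
            a=int(np.sum((y == 1) & (x == 1))), b=int(np.sum((y == 1) & (x == 0))),
            c=int(np.sum((y == 0) & (x == 1))), d=int(np.sum((y == 0) & (x == 0))))
        res = odds_ratio_2x2(t, variable=variable)
        return res
    x = pd.to_numeric(base["value"], errors="raise").to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(f"predictor {variable!r} is constant")
    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"separation fitting {variable!r}: {exc}") from exc
    beta, se = fit.params[1], fit.bse[1]
    if not np.isfinite(se) or abs(beta) > 30:
        raise ValueError(f"separation fitting {variable!r}")
    return UnivariableResult(
        variable, float(np.exp(beta)),
        (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))),
        float(fit.pvalues[1]), int(len(y)))


def roc_univariable(cohort: pd.DataFrame, variable: str,
                    summary: str = "first"):
    """Descriptive ROC of a raw variable as the mortality score.

    ``summary`` selects the patient-level value: first observed day or the
    patient mean. Returns (AUC, curve DataFrame with fpr/tpr/threshold).
    """
    base = _collapse(cohort, variable, summary=summary)
    y = (base["outcome"] == "death").astype(int).to_numpy()
    x = pd.to_numeric(base["value"], errors="raise").to_numpy(dtype=float)
    auc = compute_auc(x, y)
    fpr, tpr, thr = roc_curve(y, x)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


TABLE_ONE_VARIABLES = ["age", "gender", "diabetes", "cardiovascular",
                       "respiratory", "saps", "any_comorbidity"]


def table_one(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline table: one univariable OR / CI / p per predictor."""
    rows = []
    for var in TABLE_ONE_VARIABLES:
        if var not in cohort.columns:
            continue
        res = univariable_logistic(cohort, var)
        rows.append({
            "variable": var,
            "type": "binary" if var in BINARY_CODING else "continuous",
            "odds_ratio": res.estimate,
            "ci_low": res.ci[0], "ci_high": res.ci[1],
            "p_value": res.p_value, "n_used": res.n_used,
        })
    return pd.DataFrame(rows)
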