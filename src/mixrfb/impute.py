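"""Chained-equations imputation fitted on training data only.

Continuous covariates use linear regression with predictive mean matching
(PMM, 5 donors); binary covariates use logistic regression with a Bernoulli
draw from the fitted probability. ``mice_fit_transform`` runs the cyclic
sweeps on the training cohort and freezes the final sweep's conditional
models together with the training donor pools; ``mice_apply`` completes a
test cohort in one pass using only those frozen models, so no test
information ever reaches the training side.

One completed dataset is produced per call (no multiply-imputed stacks):
the validation workflow trains one model per bootstrap replication.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .design import BINARY_CODING

__all__ = ["ImputationModel", "mice_fit_transform", "mice_apply"]

IMPUTABLE = ["age", "gender", "rdw", "saps", "diabetes", "cardiovascular",
             "respiratory", "any_comorbidity"]
BINARY = set(BINARY_CODING)
N_DONORS = 5


def _to_numeric(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for c in cols:
        if c in BINARY:
            out[c] = df[c].map(BINARY_CODING[c])
        else:
            out[c] = pd.to_numeric(df[c])
    return out


def _decode(values: np.ndarray, col: str):
    if col not in BINARY:
        return values
    inverse = {v: k for k, v in BINARY_CODING[col].items()}
    return np.array([inverse[round(v)] for v in values], dtype=object)


@dataclass
class _Conditional:
    kind: str                     # "continuous" or "binary"
    model: object
    predictors: list[str]
    donor_preds: np.ndarray | None = None   # PMM pool: fitted means ...
    donor_values: np.ndarray | None = None  # ... and their observed values


@dataclass
class ImputationModel:
    column_order: list[str] = field(default_factory=list)
    conditionals: dict[str, _Conditional] = field(default_factory=dict)
    marginal_pools: dict[str, np.ndarray] = field(default_factory=dict)
    n_sweeps: int = 5
    seed: int = 0


def _pmm_draw(pred_missing, donor_preds, donor_values, rng):
    """For each prediction, donate an observed value among the N_DONORS
    observed rows with the closest fitted means."""
    k = min(N_DONORS, len(donor_preds))
    out = np.empty(len(pred_missing))
    order = np.argsort(donor_preds, kind="stable")
    sorted_preds = donor_preds[order]
    for i, pm in enumerate(pred_missing):
        pos = np.searchsorted(sorted_preds, pm)
        lo = max(0, min(pos - k, len(sorted_preds) - k))
        cand = order[lo:lo + 2 * k]
        cand = cand[np.argsort(np.abs(donor_preds[cand] - pm), kind="stable")[:k]]
        out[i] = donor_values[cand[rng.integers(0, len(cand))]]
    return out


def _fit_column(work, col, obs_mask, predictors, rng):
    Xo = work.loc[obs_mask, predictors].to_numpy(dtype=float)
    yo = work.loc[obs_mask, col].to_numpy(dtype=float)
    if col in BINARY:
        if len(np.unique(yo)) < 2:
            model = _ConstantBinary(float(yo.mean()) if len(yo) else 0.5)
        else:
            model = LogisticRegression(C=1e4, max_iter=1000)
            model.fit(Xo, yo.astype(int))
        return _Conditional("binary", model, list(predictors))
    model = LinearRegression()
    model.fit(Xo, yo)
    donor_preds = model.predict(Xo)
    return _Conditional("continuous", model, list(predictors),
                        donor_preds=donor_preds, donor_values=yo)


class _ConstantBinary:
    """Fallback conditional when the observed column is single-valued."""

    def __init__(self, p: float):
        self.p = p

    def predict_proba(self, X):
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


def _draw_column(cond: _Conditional, work, miss_mask, rng):
    Xm = work.loc[miss_mask, cond.predictors].to_numpy(dtype=float)
    if cond.kind == "binary":
        p = cond.model.predict_proba(Xm)[:, 1]
        return (rng.random(len(p)) < p).astype(float)
    pred = cond.model.predict(Xm)
    return _pmm_draw(pred, cond.donor_preds, cond.donor_values, rng)


def mice_fit_transform(train: pd.DataFrame, n_sweeps: int = 5, seed: int = 0,
                       columns: list[str] | None = None):
    """Impute the training cohort; returns (completed cohort, frozen model)."""
    present = [c for c in IMPUTABLE if c in train.columns]
    targets = columns if columns is not None else \
        [c for c in present if train[c].isna().any()]
    for c in targets:
        if train[c].isna().all():
            raise ValueError(f"column {c!r} is fully missing; cannot impute")
    rng = np.random.default_rng([seed, 9001])
    model = ImputationModel(column_order=list(targets), n_sweeps=n_sweeps, seed=seed)
    if not targets:
        return train.copy(), model

    work = _to_numeric(train, present)
    work["day"] = pd.to_numeric(train["day"])
    obs_masks = {c: train[c].notna().to_numpy() for c in targets}
    pools = {c: work.loc[obs_masks[c], c].to_numpy(dtype=float) for c in targets}
    model.marginal_pools = pools

    # initialize missing cells from observed marginals
    for c in targets:
        miss = ~obs_masks[c]
        work.loc[miss, c] = rng.choice(pools[c], size=int(miss.sum()), replace=True)

    predictors_of = {c: [p for p in present if p != c] + ["day"] for c in targets}
    for _ in range(n_sweeps):
        for c in targets:
            cond = _fit_column(work, c, obs_masks[c], predictors_of[c], rng)
            miss = ~obs_masks[c]
            work.loc[miss, c] = _draw_column(cond, work, miss, rng)
            model.conditionals[c] = cond

    completed = train.copy()
    for c in targets:
        vals = work[c].to_numpy(dtype=float)
        filled = completed[c].to_numpy(dtype=object if c in BINARY else float)
        miss = ~obs_masks[c]
        filled[miss] = _decode(vals[miss], c)
        completed[c] = filled
    return completed, model


def mice_apply(model: ImputationModel, test: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Complete a test cohort with the frozen training conditionals.

    One sweep in the fitted column order; missing cells are first
    initialized from the *training* marginal pools so predictors are
    complete, then each column is redrawn from its frozen conditional.
    Never refits on test rows and never modifies observed cells.
    """
    present = [c for c in IMPUTABLE if c in test.columns]
    missing_cols = [c for c in present if test[c].isna().any()]
    for c in missing_cols:
        if c not in model.conditionals:
            raise ValueError(
                f"column {c!r} has missing test values but no fitted conditional")
    if not missing_cols:
        return test.copy()
    rng = np.random.default_rng([seed, 9002])
    work = _to_numeric(test, present)
    work["day"] = pd.to_numeric(test["day"])
    obs_masks = {c: test[c].notna().to_numpy() for c in missing_cols}
    for c in missing_cols:
        miss = ~obs_masks[c]
        work.loc[miss, c] = rng.choice(model.marginal_pools[c],
                                       size=int(miss.sum()), replace=True)
    for c in model.column_order:
        if c not in missing_cols:
            continue
        cond = model.conditionals[c]
        miss = ~obs_masks[c]
        work.loc[miss, c] = _draw_column(cond, work, miss, rng)

    completed = test.copy()
    for c in missing_cols:
        vals = work[c].to_numpy(dtype=float)
        filled = completed[c].to_numpy(dtype=object if c in BINARY else float)
        miss = ~obs_masks[c]
        filled[miss] = _decode(vals[miss], c)
        completed[c] = filled
    return completed
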