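"""Random-intercept logistic models estimated by Laplace approximation.

The model is ``logit P(y_ij = 1) = offset_ij + x_ij' beta + b_i`` with
``b_i ~ N(0, sigma_b^2)``. Random intercepts are separable across patients
given the fixed part, so posterior modes are found with per-patient Newton
steps, and the variance component maximizes the Laplace-approximate profile
log-likelihood on the log-variance scale. Fixed coefficients (when present)
alternate with the random-effect step: a penalized-quasi-likelihood style
scheme where the GLM step uses the current modes as an offset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .design import design_matrix, group_codes, outcome_vector

__all__ = ["GlmmFit", "GlmmConvergenceError", "estimate_random_effects",
           "fit_glmm_baseline", "predict_glmm"]

_VAR_LO, _VAR_HI = 1e-8, 400.0
_PCLIP = 1e-12


class GlmmConvergenceError(RuntimeError):
    """Inner optimizer failure; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class GlmmFit:
    fixed_coefficients: dict[str, float]
    sigma_b2: float
    intercepts: dict[str, float]
    loglik: float
    converged: bool = True
    feature_names: list[str] = field(default_factory=list)

    def intercept_vector(self, labels) -> np.ndarray:
        return np.array([self.intercepts.get(g, 0.0) for g in labels])


def _solve_modes(offset, y, codes, n_groups, sigma2, max_newton=200):
    """Posterior modes of b given sigma2; returns (b, hessian, data loglik)."""
    b = np.zeros(n_groups)
    trace = []
    for _ in range(max_newton):
        eta = offset + b[codes]
        p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
        grad = np.bincount(codes, weights=y - p, minlength=n_groups) - b / sigma2
        w = np.bincount(codes, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
        step = np.clip(grad / w, -4.0, 4.0)
        b = b + step
        m = float(np.abs(step).max(initial=0.0))
        trace.append(m)
        if m < 1e-10:
            break
    else:
        raise GlmmConvergenceError(
            "Newton iterations for random-intercept modes did not converge",
            trace=trace)
    eta = offset + b[codes]
    p = np.clip(expit(eta), _PCLIP, 1 - _PCLIP)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    w = np.bincount(codes, weights=p * (1 - p), minlength=n_groups) + 1.0 / sigma2
    return b, w, loglik


def _laplace_loglik(offset, y, codes, n_groups, sigma2):
    b, w, lld = _solve_modes(offset, y, codes, n_groups, sigma2)
    pen = float(np.sum(b ** 2)) / (2.0 * sigma2)
    logdet = 0.5 * float(np.sum(np.log(sigma2 * w)))
    return lld - pen - logdet, b


def estimate_random_effects(offset, y, patient_ids, sigma_init: float = 1.0) -> GlmmFit:
    """Fit ``logit P(y=1) = offset + b_i`` returning modes and sigma_b^2.

    ``patient_ids`` may be any hashable labels; one intercept per label.
    The profile likelihood in log-variance is unimodal in practice; a
    bounded scalar search covers variances from ~0 to 400, and the
    degenerate no-heterogeneity fit (b = 0) is compared explicitly so a
    boundary solution reports sigma_b2 = 0.
    """
    offset = np.asarray(offset, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")
    codes, labels = _factorize(patient_ids)
    G = len(labels)

    def neg(theta):
        ll, _ = _laplace_loglik(offset, y, codes, G, float(np.exp(theta)))
        return -ll

    res = minimize_scalar(neg, bounds=(np.log(_VAR_LO), np.log(_VAR_HI)),
                          method="bounded", options={"xatol": 1e-8})
    sigma2 = float(np.exp(res.x))
    ll, b = _laplace_loglik(offset, y, codes, G, sigma2)
    # degenerate comparison: likelihood with b identically zero
    p0 = np.clip(expit(offset), _PCLIP, 1 - _PCLIP)
    ll0 = float(np.sum(y * np.log(p0) + (1 - y) * np.log1p(-p0)))
    if ll0 >= ll - 1e-9 or sigma2 <= 2 * _VAR_LO:
        return GlmmFit({}, 0.0, {g: 0.0 for g in labels}, ll0)
    return GlmmFit({}, sigma2, dict(zip(labels, b)), ll)


def _factorize(patient_ids):
    import pandas as pd

    codes, labels = pd.factorize(np.asarray(patient_ids), sort=False)
    return codes, list(labels)


def fit_glmm_baseline(train, features, group_col: str = "patient_id",
                      max_iter: int = 100, tol: float = 1e-5) -> GlmmFit:
    """Random-intercept logistic regression with linear fixed effects.

    Alternates a binomial GLM step for the coefficients (current modes as
    offset) with the Laplace variance-component step, until both the
    coefficients and sigma_b^2 stabilize. Quasi-separated fits (any
    |coefficient| beyond 30 on the logit scale) fail explicitly.
    """
    X = design_matrix(train, features)
    X1 = np.column_stack([np.ones(len(X)), X])
    y = outcome_vector(train)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit")
    codes, labels = group_codes(train, group_col)
    names = ["intercept"] + list(features)

    beta = np.zeros(X1.shape[1])
    sigma2 = 0.0
    b_row = np.zeros(len(y))
    re = GlmmFit({}, 0.0, {}, 0.0)
    converged = False
    for it in range(max_iter):
        try:
            glm = sm.GLM(y, X1, family=sm.families.Binomial(),
                         offset=b_row).fit(maxiter=200)
            new_beta = np.asarray(glm.params)
            bad = not np.all(np.isfinite(new_beta)) or np.abs(new_beta).max() > 30
        except Exception:
            bad = True
        if bad:
            if it == 0:
                raise ValueError("separation detected in GLMM baseline fit")
            # degenerate-variance regime: near-saturating offsets leave the
            # coefficients unidentified; keep the last stable estimate
            break
        if it > 0:  # damped update stabilizes the alternation
            new_beta = 0.5 * (beta + new_beta)
        offset = X1 @ new_beta
        re = estimate_random_effects(offset, y, train[group_col].to_numpy(),
                                     sigma_init=max(sigma2, 1.0))
        b_row = re.intercept_vector(train[group_col])
        delta = float(np.abs(new_beta - beta).max())
        beta, sigma2 = new_beta, re.sigma_b2
        if delta < tol:
            converged = True
            break
    return GlmmFit(dict(zip(names, beta)), sigma2, re.intercepts, re.loglik,
                   converged=converged, feature_names=list(features))


def predict_glmm(fit: GlmmFit, rows, mode: str = "population") -> np.ndarray:
    """Predicted death probabilities from a fitted baseline GLMM."""
    X = design_matrix(rows, fit.feature_names)
    beta = np.array([fit.fixed_coefficients["intercept"]]
                    + [fit.fixed_coefficients[f] for f in fit.feature_names])
    eta = np.column_stack([np.ones(len(X)), X]) @ beta
    if mode == "conditional":
        eta = eta + fit.intercept_vector(rows["patient_id"])
    elif mode != "population":
        raise ValueError("mode must be 'population' or 'conditional'")
    return expit(eta)
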