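"""The MixRFb estimator and its comparators.

MixRFb couples a random-forest fixed-effects learner with a random-intercept
logistic model: the forest is fit to the binary death outcome, its
out-of-bag probabilities (clipped away from 0/1) become a per-row offset on
the logit scale, and a Laplace-approximate mixed model estimates the
patient intercepts ``b_i`` and their variance ``sigma_b^2`` on top of that
offset. By default the forest is fit once and only the mixed-model step
iterates to convergence of ``sigma_b^2``; an optional ``refit_forest`` mode
re-grows the forest each outer iteration with rows exponentially
down-weighted where the current intercept already explains the outcome.

``fit_plain_rf`` is the conventional forest that ignores clustering; it is
returned in the same model container (``sigma_b2 = 0``, no intercepts) so
validation and importance code treat all models uniformly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, logit

from .design import design_matrix, group_codes, outcome_vector
from .forest import PatientBootstrapForest, fit_row_bootstrap_forest, proba_death
from .glmm import estimate_random_effects

__all__ = ["MixRFbConfig", "MixRFbModel", "fit_mixrfb", "fit_plain_rf",
           "predict_prob", "MODEL_FEATURES"]

#: feature sets of the three published model variants
MODEL_FEATURES = {
    "A": ["rdw", "age", "gender", "day", "any_comorbidity"],
    "B": ["saps"],
    "C": ["rdw", "age", "gender", "day", "any_comorbidity"],
}


@dataclass
class MixRFbConfig:
    n_trees: int = 500
    mtry: int | None = None          # default: floor(sqrt(p))
    min_node_size: int = 5
    max_iter: int = 20
    tol: float = 1e-3                # on |delta sigma_b^2|
    prob_clip: float = 1e-6
    refit_forest: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0.0 < self.prob_clip < 0.5:
            raise ValueError("prob_clip must lie in (0, 0.5)")


@dataclass
class MixRFbModel:
    forest: object
    random_intercepts: dict[str, float]
    sigma_b2: float
    trace: list[float]
    feature_names: list[str]
    converged: bool
    config: MixRFbConfig
    kind: str = "mixrfb"             # "mixrfb" or "rf"
    oob_prob: np.ndarray | None = None

    def meta(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": list(self.feature_names),
            "sigma_b2": float(self.sigma_b2),
            "trace": [float(t) for t in self.trace],
            "converged": bool(self.converged),
            "config": asdict(self.config),
        }


def _check_train(train, features):
    y = outcome_vector(train)
    if y.min() == y.max():
        raise ValueError("outcome has a single class; cannot fit")
    X = design_matrix(train, features)
    return X, y


def fit_mixrfb(train, features, config: MixRFbConfig | None = None,
               group_col: str = "patient_id") -> MixRFbModel:
    """Fit the mixed-effects logistic random forest.

    ``train`` is a long-format cohort with complete feature columns
    (imputation happens upstream); ``group_col`` names the random-effect
    grouping, normally the patient identifier.
    """
    config = config or MixRFbConfig()
    X, y = _check_train(train, features)
    codes, labels = group_codes(train, group_col)
    if len(labels) < 2:
        raise ValueError("need at least 2 patients to fit a mixed model")
    mtry = config.mtry or max(1, int(math.isqrt(X.shape[1])))

    forest = PatientBootstrapForest(
        n_trees=config.n_trees, mtry=mtry,
        min_node_size=config.min_node_size, seed=config.seed)
    forest.fit(X, y, codes)
    eps = config.prob_clip
    offset = logit(np.clip(forest.oob_prob_, eps, 1 - eps))

    trace: list[float] = []
    prev = 0.0
    converged = False
    fit = None
    ids = train[group_col].to_numpy()
    for it in range(config.max_iter):
        fit = estimate_random_effects(offset, y, ids, sigma_init=max(prev, 1.0))
        trace.append(fit.sigma_b2)
        if it > 0 and abs(fit.sigma_b2 - prev) < config.tol:
            converged = True
            break
        prev = fit.sigma_b2
        if config.refit_forest:
            b_row = fit.intercept_vector(ids)
            w = np.exp(-(2 * y - 1) * b_row)
            w *= len(w) / w.sum()
            forest.fit(X, y, codes, sample_weight=w)
            offset = logit(np.clip(forest.oob_prob_, eps, 1 - eps))
    return MixRFbModel(forest, dict(fit.intercepts), fit.sigma_b2, trace,
                       list(features), converged, config, kind="mixrfb",
                       oob_prob=forest.oob_prob_)


def fit_plain_rf(train, features, config: MixRFbConfig | None = None) -> MixRFbModel:
    """Conventional random forest (row bagging, clustering ignored)."""
    config = config or MixRFbConfig()
    X, y = _check_train(train, features)
    mtry = config.mtry or max(1, int(math.isqrt(X.shape[1])))
    rf, oob1 = fit_row_bootstrap_forest(
        X, y, config.n_trees, mtry, config.min_node_size, config.seed)
    return MixRFbModel(rf, {}, 0.0, [], list(features), True, config,
                       kind="rf", oob_prob=oob1)


def predict_prob(model: MixRFbModel, rows, mode: str = "population") -> np.ndarray:
    """Predicted death probability per row.

    ``population`` sets the random intercept to zero (new admissions);
    ``conditional`` adds the fitted ``b_i`` for patients seen in training
    and zero for unseen patients. Probabilities are clipped away from 0/1
    before the logit so outputs are always finite and inside (0, 1).
    """
    if mode not in ("population", "conditional"):
        raise ValueError("mode must be 'population' or 'conditional'")
    X = design_matrix(rows, model.feature_names)
    eps = model.config.prob_clip
    p = np.clip(proba_death(model.forest, X), eps, 1 - eps)
    if mode == "population" or not model.random_intercepts:
        return p
    b = np.array([model.random_intercepts.get(pid, 0.0)
                  for pid in rows["patient_id"]])
    return expit(logit(p) + b)
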