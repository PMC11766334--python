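"""Synthetic longitudinal ICU cohort generator.

Emulates a repeated-measures mortality cohort: one row per patient-day,
patient-level in-hospital mortality outcome, slowly varying RDW, baseline
demographics and comorbidity flags, patient-level clustering through a
Gaussian random intercept on the logit scale, and configurable partial
missingness. Every other part of the package is exercised against cohorts
drawn from this module, so its defaults are the study conditions: a
286-patient cohort with a 79/286 death rate, five daily measurements, and
covariate marginals matching a typical mixed medical/surgical ICU.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = ["CohortSpec", "generate_cohort", "inject_missingness", "simulate_cohort"]

#: canonical long-format column order
COHORT_COLUMNS = [
    "patient_id", "day", "age", "gender", "rdw", "saps",
    "diabetes", "cardiovascular", "respiratory", "any_comorbidity", "outcome",
]

COMORBIDITY_FLAGS = ("diabetes", "cardiovascular", "respiratory")

#: covariates that may legally contain missing values
MASKABLE = ("age", "gender", "rdw", "saps") + COMORBIDITY_FLAGS + ("any_comorbidity",)

#: coefficient names accepted in ``CohortSpec.beta`` (logit scale)
BETA_KEYS = ("age", "rdw", "saps", "female") + COMORBIDITY_FLAGS + ("any_comorbidity",)

MAX_MISSING_RATE = 0.23


def _default_beta() -> dict[str, float]:
    # Informative age and RDW, SAPS a weaker summary of severity, modest
    # gender/comorbidity effects. The RDW effect is predominantly
    # threshold-shaped (see CohortSpec.rdw_hinge): anisocytosis is roughly
    # benign in the normal range and mortality risk rises sharply above
    # ~16%, which is the nonlinearity a forest can represent and a linear
    # mixed model cannot.
    return {
        "age": 0.03,
        "rdw": 0.02,
        "saps": 0.07,
        "female": 0.2,
        "any_comorbidity": 0.4,
    }


def _default_missing() -> dict[str, float]:
    # Baseline-characteristic denominators of roughly 250/286 imply ~12.6%
    # missingness on the categorical covariates; labs assumed mostly complete.
    cat = 36 / 286
    out = {flag: cat for flag in COMORBIDITY_FLAGS}
    out.update({"gender": cat, "any_comorbidity": cat, "rdw": 0.10, "saps": 0.0})
    return out


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``sigma_b`` is the standard deviation of the patient random intercept on
    the logit scale; ``beta`` maps covariate names to fixed-effect logit
    coefficients. Two non-additive components carry most of the joint
    signal, mirroring how single-variable discrimination in ICU data is
    weak while the multivariable machine-learning fit is strong:
    ``rdw_hinge`` adds an extra slope above a threshold (mortality risk
    rises sharply for RDW above ~16%), and ``age_rdw_interaction``
    (age threshold, rdw threshold, coefficient) adds a logit bump on days
    where an elderly patient also shows elevated RDW — the combination of
    age-related vulnerability and systemic inflammation exceeding the sum
    of the two effects. A forest can represent both; an additive linear
    mixed model cannot.
    """

    n_patients: int = 286
    n_days: int = 5
    death_rate: float = 79 / 286
    age_dist: tuple[float, float] = (69.0, 12.0)
    age_bounds: tuple[float, float] = (18.0, 100.0)
    female_prob: float = 94 / 250
    comorbidity_probs: dict[str, float] = field(
        default_factory=lambda: {"diabetes": 75 / 250, "cardiovascular": 128 / 250,
                                 "respiratory": 51 / 250})
    rdw_baseline: tuple[float, float] = (14.5, 2.0)
    rdw_daily_sd: float = 0.5
    saps_dist: tuple[float, float] = (40.0, 14.0)
    sigma_b: float = 1.5
    beta: dict[str, float] = field(default_factory=_default_beta)
    rdw_hinge: tuple[float, float] = (16.0, 0.4)
    age_rdw_interaction: tuple[float, float, float] = (65.0, 15.0, 4.0)
    missing_rate: dict[str, float] = field(default_factory=_default_missing)
    missing_mechanism: str = "MCAR"
    mar_outcome_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 < self.death_rate < 1.0:
            raise ValueError("death_rate must lie strictly inside (0, 1)")
        for name, p in [("female_prob", self.female_prob), *self.comorbidity_probs.items()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")
        if self.missing_mechanism not in ("MCAR", "MAR-on-outcome"):
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")
        for var, rate in self.missing_rate.items():
            if var not in MASKABLE:
                raise ValueError(f"missingness not allowed on column {var!r}")
            if not 0.0 <= rate <= MAX_MISSING_RATE:
                raise ValueError(
                    f"missing rate {rate} for {var!r} outside [0, {MAX_MISSING_RATE}]")
        for key, val in self.beta.items():
            if key not in BETA_KEYS:
                raise ValueError(f"unknown beta key {key!r}")
            if not math.isfinite(val):
                raise ValueError(f"beta[{key!r}] is not finite")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec, return_latent: bool = False) -> pd.DataFrame:
    """Draw a complete (no missingness) long-format cohort.

    The patient outcome is a single Bernoulli draw with
    ``logit p_i = alpha + mean_d(sum_j beta_j x_ijd) + b_i`` where
    ``b_i ~ N(0, sigma_b^2)`` and ``alpha`` is solved numerically so the
    expected death fraction equals ``spec.death_rate``. The outcome is
    repeated on every row of the patient, mirroring in-hospital mortality.

    With ``return_latent=True`` also returns a patient-level frame with the
    random intercepts and linear predictors (for diagnostics and tests).
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_patients, spec.n_days

    age = _truncated_normal(rng, *spec.age_dist, *spec.age_bounds, n)
    female = rng.random(n) < spec.female_prob
    flags = {f: rng.random(n) < spec.comorbidity_probs.get(f, 0.0) for f in COMORBIDITY_FLAGS}
    any_com = np.logical_or.reduce([flags[f] for f in COMORBIDITY_FLAGS])
    saps = _truncated_normal(rng, *spec.saps_dist, 0.0, np.inf, n)
    rdw_base = _truncated_normal(rng, *spec.rdw_baseline, 10.0, np.inf, n)
    rdw = rdw_base[:, None] + rng.normal(0.0, spec.rdw_daily_sd, size=(n, d))
    rdw = np.clip(rdw, 8.0, None)
    b = rng.normal(0.0, spec.sigma_b, n) if spec.sigma_b > 0 else np.zeros(n)

    beta = spec.beta
    # day-level fixed-effect contribution, averaged over the stay
    eta_day = np.zeros((n, d))
    eta_day += beta.get("rdw", 0.0) * rdw
    thr, slope = spec.rdw_hinge
    eta_day += slope * np.clip(rdw - thr, 0.0, None)
    age_thr, rdw_thr, gamma = spec.age_rdw_interaction
    eta_day += gamma * ((age[:, None] >= age_thr) & (rdw > rdw_thr))
    s = eta_day.mean(axis=1)
    s += beta.get("age", 0.0) * age
    s += beta.get("female", 0.0) * female
    s += beta.get("saps", 0.0) * saps
    for f in COMORBIDITY_FLAGS:
        s += beta.get(f, 0.0) * flags[f]
    s += beta.get("any_comorbidity", 0.0) * any_com
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite linear predictor; check beta coefficients")
    s = s + b

    def gap(alpha: float) -> float:
        return float(expit(alpha + s).mean() - spec.death_rate)

    lo, hi = -80.0 - float(np.abs(s).max()), 80.0 + float(np.abs(s).max())
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            "intercept not solvable for the requested death_rate; "
            "betas are degenerate")
    alpha = brentq(gap, lo, hi, xtol=1e-10)
    p_death = expit(alpha + s)
    death = rng.random(n) < p_death

    pid = np.array([f"P{i + 1:04d}" for i in range(n)])
    df = pd.DataFrame({
        "patient_id": np.repeat(pid, d),
        "day": np.tile(np.arange(1, d + 1), n),
        "age": np.repeat(age, d),
        "gender": np.repeat(np.where(female, "female", "male"), d),
        "rdw": rdw.ravel(),
        "saps": np.repeat(saps, d),
        "diabetes": np.repeat(np.where(flags["diabetes"], "yes", "no"), d),
        "cardiovascular": np.repeat(np.where(flags["cardiovascular"], "yes", "no"), d),
        "respiratory": np.repeat(np.where(flags["respiratory"], "yes", "no"), d),
        "any_comorbidity": np.repeat(np.where(any_com, "yes", "no"), d),
        "outcome": np.repeat(np.where(death, "death", "survival"), d),
    })
    if not return_latent:
        return df
    latent = pd.DataFrame({
        "patient_id": pid, "b": b, "fixed_predictor": s - b,
        "linear_predictor": alpha + s, "p_death": p_death, "intercept": alpha,
    })
    return df, latent


def inject_missingness(cohort: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Mask covariate cells according to ``spec.missing_rate``.

    MCAR masks each targeted cell independently with its variable's rate.
    MAR-on-outcome masks deceased patients' cells ``mar_outcome_ratio`` times
    more often than survivors', rescaled so the overall expected rate is
    preserved. ``patient_id``, ``day`` and ``outcome`` are never masked.
    """
    for var, rate in spec.missing_rate.items():
        if not 0.0 <= rate <= MAX_MISSING_RATE:
            raise ValueError(f"missing rate {rate} for {var!r} outside [0, {MAX_MISSING_RATE}]")
        if var not in MASKABLE:
            raise ValueError(f"missingness not allowed on column {var!r}")
    rng = np.random.default_rng([spec.seed, 104729])
    out = cohort.copy()
    is_death = (out["outcome"] == "death").to_numpy()
    n_rows = len(out)
    for var in MASKABLE:
        rate = spec.missing_rate.get(var, 0.0)
        if rate <= 0 or var not in out.columns:
            continue
        if spec.missing_mechanism == "MCAR":
            cell_rate = np.full(n_rows, rate)
        else:
            n_d, n_s = int(is_death.sum()), int((~is_death).sum())
            r = spec.mar_outcome_ratio
            r_s = rate * n_rows / (n_s + r * n_d) if (n_s + r * n_d) else 0.0
            cell_rate = np.where(is_death, min(1.0, r * r_s), r_s)
        mask = rng.random(n_rows) < cell_rate
        if mask.any():
            if out[var].dtype == object:
                col = out[var].astype(object)
                col[mask] = np.nan
                out[var] = col
            else:
                out.loc[mask, var] = np.nan
    return out


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort and apply the spec's missingness in one call."""
    return inject_missingness(generate_cohort(spec), spec)
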