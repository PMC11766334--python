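"""Random-intercept logistic estimation on correctly specified data."""
import json
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mixrfb import estimate_random_effects, fit_glmm_baseline, predict_glmm


def simulate_rows(G, k, sigma_b, beta=(), seed=0, offset_sd=1.0):
    """Rows conditionally independent given the patient intercept."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0, sigma_b, G)
    off = rng.normal(0, offset_sd, G * k)
    ids = np.repeat(np.arange(G), k)
    X = rng.normal(0, 1, (G * k, len(beta))) if beta else np.zeros((G * k, 0))
    eta = off + X @ np.asarray(beta) + b[ids]
    y = (rng.random(G * k) < expit(eta)).astype(int)
    return off, X, y, ids, b


def test_variance_recovery():
    off, _, y, ids, _ = simulate_rows(200, 5, sigma_b=2.0, seed=1)
    fit = estimate_random_effects(off, y, ids)
    assert 1.5 <= np.sqrt(fit.sigma_b2) <= 2.5


def test_no_heterogeneity_gives_zero_variance():
    # outcome deterministic from a strong offset, one row per patient
    rng = np.random.default_rng(2)
    off = rng.choice([-4.0, 4.0], size=300)
    y = (off > 0).astype(int)
    fit = estimate_random_effects(off, y, np.arange(300))
    assert fit.sigma_b2 < 0.05


def test_intercept_symmetry_two_patients():
    off = np.zeros(6)
    y = np.array([1, 0, 1, 0, 1, 0])
    ids = np.array([1, 1, 1, 2, 2, 2])
    fit = estimate_random_effects(off, y, ids)
    b1, b2 = fit.intercepts[1], fit.intercepts[2]
    assert abs(b1 + b2) < 1e-6


def test_intercept_mean_near_zero():
    off, _, y, ids, _ = simulate_rows(400, 5, sigma_b=1.5, seed=3)
    fit = estimate_random_effects(off, y, ids)
    b = np.array(list(fit.intercepts.values()))
    assert abs(b.mean()) < 3 * 1.5 / np.sqrt(400)


def test_nonfinite_offset_rejected():
    with pytest.raises(ValueError):
        estimate_random_effects(np.array([np.inf, 0.0]), np.array([0, 1]),
                                np.array([1, 2]))


def _rows_frame(X, y, ids, features):
    df = pd.DataFrame(X, columns=features)
    df["patient_id"] = [f"G{i}" for i in ids]
    df["outcome"] = np.where(y == 1, "death", "survival")
    df["day"] = 1
    return df


def test_baseline_coefficient_recovery():
    beta = (0.8, -0.5)
    _, X, y, ids, _ = simulate_rows(1000, 3, sigma_b=1.0, beta=beta, seed=4,
                                    offset_sd=0.0)
    df = _rows_frame(X, y, ids, ["rdw", "age"])
    fit = fit_glmm_baseline(df, ["rdw", "age"])
    for name, truth in zip(["rdw", "age"], beta):
        assert abs(fit.fixed_coefficients[name] - truth) <= 0.2 * abs(truth)


def test_baseline_null_recovery():
    _, X, y, ids, _ = simulate_rows(2000, 2, sigma_b=0.5, beta=(0.0, 0.0),
                                    seed=5, offset_sd=0.0)
    df = _rows_frame(X, y, ids, ["rdw", "age"])
    fit = fit_glmm_baseline(df, ["rdw", "age"])
    assert abs(fit.fixed_coefficients["rdw"]) < 0.1
    assert abs(fit.fixed_coefficients["age"]) < 0.1


def test_baseline_separation_rejected():
    df = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(40)],
        "day": 1,
        "rdw": np.r_[np.full(20, 12.0), np.full(20, 18.0)],
        "outcome": ["survival"] * 20 + ["death"] * 20,
    })
    with pytest.raises(ValueError):
        fit_glmm_baseline(df, ["rdw"])


def test_predict_glmm_modes():
    _, X, y, ids, _ = simulate_rows(100, 4, sigma_b=1.5, beta=(0.7,), seed=6,
                                    offset_sd=0.0)
    df = _rows_frame(X, y, ids, ["rdw"])
    fit = fit_glmm_baseline(df, ["rdw"])
    pop = predict_glmm(fit, df, mode="population")
    cond = predict_glmm(fit, df, mode="conditional")
    assert np.all((pop > 0) & (pop < 1))
    # conditional shifts in the direction of the fitted intercept
    b = fit.intercept_vector(df["patient_id"])
    assert np.all(np.sign(cond - pop)[b != 0] == np.sign(b)[b != 0])


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_agrees_with_lme4(tmp_path):
    """Independent oracle: lme4::glmer (Laplace) on the same data."""
    beta = (0.6,)
    _, X, y, ids, _ = simulate_rows(250, 4, sigma_b=1.2, beta=beta, seed=7,
                                    offset_sd=0.0)
    df = _rows_frame(X, y, ids, ["rdw"])
    fit = fit_glmm_baseline(df, ["rdw"])
    csv = tmp_path / "rows.csv"
    out = tmp_path / "fit.json"
    pd.DataFrame({"y": y, "x": X[:, 0], "id": ids}).to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x + (1 | id), data = d, family = binomial)
        cat(jsonlite::toJSON(list(beta = fixef(m)[["x"]],
                                  intercept = fixef(m)[["(Intercept)"]],
                                  sigma2 = as.numeric(VarCorr(m)$id[1])),
                             auto_unbox = TRUE), file = "{out}")
    """))
    subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                   capture_output=True)
    ref = json.loads(out.read_text())
    assert abs(fit.fixed_coefficients["rdw"] - ref["beta"]) < 0.1
    assert abs(fit.fixed_coefficients["intercept"] - ref["intercept"]) < 0.1
    assert abs(fit.sigma_b2 - ref["sigma2"]) < max(0.3, 0.3 * ref["sigma2"])
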