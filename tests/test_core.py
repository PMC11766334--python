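"""MixRFb estimator and plain-RF comparator."""
import numpy as np
import pandas as pd
import pytest

from mixrfb import (CohortSpec, MixRFbConfig, compute_auc, fit_mixrfb,
                    fit_plain_rf, generate_cohort, predict_prob)
from mixrfb.design import outcome_vector

from conftest import make_threshold_frame

FEATS = ["rdw", "age", "gender", "day", "any_comorbidity"]


def test_plain_rf_separable_in_sample_auc():
    df = make_threshold_frame(n_rows=200, seed=1)
    model = fit_plain_rf(df, ["rdw"], MixRFbConfig(n_trees=50, seed=0))
    p = predict_prob(model, df)
    assert compute_auc(p, outcome_vector(df)) == 1.0


def test_plain_rf_shuffled_labels_null_auc():
    df = make_threshold_frame(n_rows=200, seed=2)
    aucs = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        shuffled = df.copy()
        shuffled["outcome"] = rng.permutation(df["outcome"].to_numpy())
        if shuffled["outcome"].nunique() < 2:
            continue
        m = fit_plain_rf(shuffled, ["rdw"], MixRFbConfig(n_trees=100, seed=seed))
        aucs.append(compute_auc(m.oob_prob, outcome_vector(shuffled)))
    assert 0.4 <= np.median(aucs) <= 0.6


def test_determinism(default_cohort, fast_config):
    m1 = fit_mixrfb(default_cohort, FEATS, fast_config)
    m2 = fit_mixrfb(default_cohort, FEATS, fast_config)
    np.testing.assert_array_equal(predict_prob(m1, default_cohort),
                                  predict_prob(m2, default_cohort))
    assert m1.sigma_b2 == m2.sigma_b2


def test_mixrfb_matches_plain_rf_without_clustering():
    spec = CohortSpec(n_patients=300, sigma_b=0.0, missing_rate={}, seed=21)
    df = generate_cohort(spec)
    cfg = MixRFbConfig(n_trees=150, seed=2)
    mix = fit_mixrfb(df, FEATS, cfg)
    rf = fit_plain_rf(df, FEATS, cfg)
    p_mix = predict_prob(mix, df, mode="population")
    p_rf = predict_prob(rf, df, mode="population")
    assert np.corrcoef(p_mix, p_rf)[0, 1] > 0.9
    # the random-effects machinery does no harm on held-out patients
    # (row-level OOB of the plain forest is optimistically biased on
    # clustered rows, so fresh patients are the fair comparison)
    holdout = generate_cohort(CohortSpec(n_patients=300, sigma_b=0.0,
                                         missing_rate={}, seed=51))
    y = outcome_vector(holdout)
    a_mix = compute_auc(predict_prob(mix, holdout), y)
    a_rf = compute_auc(predict_prob(rf, holdout), y)
    assert abs(a_mix - a_rf) < 0.05


def test_conditional_oob_beats_plain_rf_under_clustering():
    """With strong clustering the fitted intercepts carry real information
    about training patients, so conditional OOB discrimination dominates."""
    medians = []
    for seed in range(5):
        spec = CohortSpec(n_patients=200, sigma_b=1.5, missing_rate={}, seed=30 + seed)
        df = generate_cohort(spec)
        cfg = MixRFbConfig(n_trees=100, seed=seed)
        mix = fit_mixrfb(df, FEATS, cfg)
        rf = fit_plain_rf(df, FEATS, cfg)
        y = outcome_vector(df)
        from scipy.special import expit, logit
        eps = cfg.prob_clip
        b = np.array([mix.random_intercepts.get(p, 0.0) for p in df["patient_id"]])
        cond_oob = expit(logit(np.clip(mix.oob_prob, eps, 1 - eps)) + b)
        medians.append(compute_auc(cond_oob, y) - compute_auc(rf.oob_prob, y))
    assert np.median(medians) >= 0


def test_trace_and_variance_invariants(default_cohort, fast_config):
    model = fit_mixrfb(default_cohort, FEATS, fast_config)
    assert model.sigma_b2 >= 0
    assert np.all(np.isfinite(model.trace))
    assert len(model.random_intercepts) == default_cohort["patient_id"].nunique()


def test_population_prediction_invariant_to_relabeling(fast_config):
    spec = CohortSpec(n_patients=120, missing_rate={}, seed=22)
    df = generate_cohort(spec)
    m1 = fit_mixrfb(df, FEATS, fast_config)
    relabeled = df.copy()
    relabeled["patient_id"] = "Z" + relabeled["patient_id"]
    m2 = fit_mixrfb(relabeled, FEATS, fast_config)
    np.testing.assert_allclose(predict_prob(m1, df), predict_prob(m2, relabeled))


def test_predict_modes_and_clipping(threshold_frame):
    model = fit_plain_rf(threshold_frame, ["rdw"], MixRFbConfig(n_trees=40, seed=1))
    pop = predict_prob(model, threshold_frame, mode="population")
    cond = predict_prob(model, threshold_frame, mode="conditional")
    np.testing.assert_array_equal(pop, cond)  # no intercepts: identical
    assert np.all((pop > 0) & (pop < 1)) and np.all(np.isfinite(pop))
    # inject intercepts: positive b raises the conditional probability
    model.random_intercepts = {pid: 1.0 for pid in threshold_frame["patient_id"]}
    cond2 = predict_prob(model, threshold_frame, mode="conditional")
    assert np.all(cond2 > pop)


def test_fit_errors():
    df = make_threshold_frame(n_rows=50, seed=3)
    single = df.assign(outcome="death")
    with pytest.raises(ValueError):
        fit_mixrfb(single, ["rdw"])
    bad = df.copy()
    bad.loc[0, "rdw"] = np.nan
    with pytest.raises(ValueError):
        fit_mixrfb(bad, ["rdw"])
    with pytest.raises(KeyError):
        predict_prob(fit_plain_rf(df, ["rdw"]), df.drop(columns=["rdw"]))


def test_refit_forest_variant_runs(default_cohort):
    cfg = MixRFbConfig(n_trees=40, seed=5, refit_forest=True, max_iter=3)
    model = fit_mixrfb(default_cohort, FEATS, cfg)
    assert len(model.trace) >= 1 and np.all(np.isfinite(model.trace))
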