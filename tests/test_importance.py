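"""Importance suite: permutation, binomial root test, PDP, minimal depth."""
import numpy as np
import pandas as pd
import pytest

from mixrfb import (MixRFbConfig, binomial_root_test, fit_plain_rf,
                    mean_minimal_depth, multiway_importance,
                    partial_dependence, permutation_importance)
from mixrfb.importance import _accuracy_drop
from mixrfb.design import outcome_vector

from conftest import make_threshold_frame


@pytest.fixture(scope="module")
def toy_model():
    """Forest on outcome = indicator(rdw > 15) with a noise feature and a
    constant feature that can never split."""
    df = make_threshold_frame(n_rows=400, seed=5)
    df["dud"] = 1.0
    model = fit_plain_rf(df, ["rdw", "age", "dud"],
                         MixRFbConfig(n_trees=120, mtry=3, seed=7))
    return model, df


@pytest.mark.parametrize("k,n,p0,expected", [
    (0, 10, 0.3, 1.0),
    (10, 10, 0.5, 0.5 ** 10),
    (3, 5, 0.2, 0.05792),
])
def test_binomial_tail_closed_forms(k, n, p0, expected):
    assert binomial_root_test(k, n, p0) == pytest.approx(expected, rel=1e-9)


def test_binomial_tail_matches_monte_carlo():
    rng = np.random.default_rng(0)
    for k, n, p0 in [(3, 12, 0.2), (7, 30, 0.25), (2, 50, 0.02)]:
        draws = rng.binomial(n, p0, size=40_000)
        mc = np.mean(draws >= k)
        se = np.sqrt(mc * (1 - mc) / draws.size)
        assert abs(binomial_root_test(k, n, p0) - mc) < 3 * max(se, 1e-4)


def test_binomial_tail_invalid_inputs():
    with pytest.raises(ValueError):
        binomial_root_test(2, 5, 0.0)
    with pytest.raises(ValueError):
        binomial_root_test(6, 5, 0.2)


def test_permutation_importance_finds_dominant_feature(toy_model):
    model, df = toy_model
    mda = permutation_importance(model, df, n_repeats=10, seed=1)
    assert mda["rdw"] > 0.2
    assert mda.idxmax() == "rdw"
    assert abs(mda["age"]) < 0.02      # pure-noise feature
    with pytest.raises(KeyError):
        permutation_importance(model, df, features=["unknown"])


def test_identity_permutation_gives_zero_drop(toy_model):
    model, df = toy_model
    y = outcome_vector(df)
    assert _accuracy_drop(model, df, y, "rdw", np.arange(len(df))) == 0.0


def test_permutation_importance_order_invariant(toy_model):
    model, df = toy_model
    a = permutation_importance(model, df, n_repeats=5, seed=2,
                               features=["rdw", "age", "dud"])
    b = permutation_importance(model, df, n_repeats=5, seed=2,
                               features=["dud", "age", "rdw"])
    pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


def test_multiway_importance_dominance_and_bookkeeping(toy_model):
    model, df = toy_model
    report = multiway_importance(model, df, n_repeats=5, seed=3)
    tab = report.table.set_index("variable")
    assert tab["gini_decrease"].idxmax() == "rdw"
    assert tab["root_count"].idxmax() == "rdw"
    assert tab["root_count"].sum() == len(model.forest.estimators_)
    # the constant feature never splits anywhere
    assert tab.loc["dud", "gini_decrease"] == 0
    assert tab.loc["dud", "root_count"] == 0
    assert tab.loc["dud", "node_count"] == 0
    assert tab.loc["dud", "p_value_root"] == 1.0
    assert ((tab["p_value_root"] >= 0) & (tab["p_value_root"] <= 1)).all()


def test_pdp_monotone_on_threshold_truth(toy_model):
    model, df = toy_model
    curve = partial_dependence(model, df, "rdw")
    assert np.all(np.diff(curve.grid) > 0)
    assert np.all((curve.mean_prediction >= 0) & (curve.mean_prediction <= 1))
    assert curve.mean_prediction[-1] - curve.mean_prediction[0] > 0.3
    # weak violations of monotonicity only
    assert np.min(np.diff(curve.mean_prediction)) > -0.02


def test_pdp_flat_on_noise_and_constant_rejected(toy_model):
    model, df = toy_model
    noise_curve = partial_dependence(model, df, "age")
    assert noise_curve.mean_prediction.max() - noise_curve.mean_prediction.min() < 0.05
    with pytest.raises(ValueError):
        partial_dependence(model, df, "dud")


def test_mean_minimal_depth_ordering(toy_model):
    model, df = toy_model
    d_rdw = mean_minimal_depth(model, "rdw")
    d_age = mean_minimal_depth(model, "age")
    assert d_rdw == 0.0            # rdw splits the root of every tree
    assert d_age > d_rdw
    # absent variable: penalized convention, mean tree depth + 1
    depths = []
    for est in model.forest.estimators_:
        from mixrfb.importance import _tree_arrays, _node_depths
        cl, cr, *_ = _tree_arrays(est)
        depths.append(_node_depths(cl, cr).max())
    assert mean_minimal_depth(model, "dud") == pytest.approx(np.mean(depths) + 1)
    with pytest.raises(KeyError):
        mean_minimal_depth(model, "unknown")


def test_conditional_minimal_depth(toy_model):
    model, df = toy_model
    pair = mean_minimal_depth(model, ("rdw", "age"))
    assert pair >= 1.0  # child split is a strict descendant
    report = multiway_importance(model, df, n_repeats=2, seed=4)
    assert ("rdw", "age") in report.pairwise_depth
    assert report.pairwise_depth[("rdw", "age")] == pytest.approx(pair)
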