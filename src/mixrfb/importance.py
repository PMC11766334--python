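"""Forest interpretability suite.

Covers four complementary views of the fitted forest component:

* permutation importance — mean decrease in classification accuracy
  (threshold 0.5, population predictions) after shuffling one column;
* multi-way importance — summed Gini impurity decrease per variable,
  root-split counts, and a one-sided binomial test of whether a variable
  reaches the root (or any node) more often than uniform selection among
  candidates would produce;
* partial dependence — average predicted death probability as one variable
  sweeps a grid between its 2.5th and 97.5th percentiles;
* minimal depth — mean depth (root = 0) of the shallowest split on a
  variable per tree, and the conditional variant for variable pairs
  (shallowest child-variable split inside the maximal subtree rooted at a
  parent-variable split). Trees not containing the variable contribute the
  forest's mean tree depth + 1 (the usual penalized convention).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .core import MixRFbModel, predict_prob
from .design import outcome_vector

__all__ = ["ImportanceReport", "PDPCurve", "permutation_importance",
           "binomial_root_test", "multiway_importance", "partial_dependence",
           "mean_minimal_depth"]


@dataclass
class ImportanceReport:
    table: pd.DataFrame            # one row per variable
    pairwise_depth: dict           # (parent, child) -> mean conditional depth
    n_trees: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class PDPCurve:
    variable: str
    grid: np.ndarray
    mean_prediction: np.ndarray
    grid_resolution: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.variable: self.grid,
                             "mean_prediction": self.mean_prediction})


# ---------------------------------------------------------------- permutation

def _accuracy(model, data, y) -> float:
    p = predict_prob(model, data, mode="population")
    return float(np.mean((p >= 0.5).astype(int) == y))


def _accuracy_drop(model, data, y, variable, perm) -> float:
    shuffled = data.copy()
    shuffled[variable] = data[variable].to_numpy()[perm]
    return _accuracy(model, data, y) - _accuracy(model, shuffled, y)


def permutation_importance(model: MixRFbModel, data: pd.DataFrame,
                           n_repeats: int = 10, seed: int = 0,
                           features: list[str] | None = None) -> pd.Series:
    """Mean decrease in accuracy per variable over ``n_repeats`` shuffles."""
    feats = list(features or model.feature_names)
    unknown = [f for f in feats if f not in model.feature_names]
    if unknown:
        raise KeyError(f"variables {unknown} not in the fitted model")
    y = outcome_vector(data)
    rng = np.random.default_rng([seed, 5381])
    n = len(data)
    out = {}
    for f in sorted(feats, key=model.feature_names.index):
        drops = [_accuracy_drop(model, data, y, f, rng.permutation(n))
                 for _ in range(n_repeats)]
        out[f] = float(np.mean(drops))
    return pd.Series(out, name="mean_decrease_accuracy")


# ---------------------------------------------------------------- binomial test

def binomial_root_test(k: int, n: int, p0: float) -> float:
    """One-sided upper tail P(Bin(n, p0) >= k) by exact summation."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


# ---------------------------------------------------------------- tree walking

def _tree_arrays(est):
    t = est.tree_
    return t.children_left, t.children_right, t.feature, t.weighted_n_node_samples, t.impurity


def _node_depths(cl, cr) -> np.ndarray:
    depth = np.zeros(len(cl), dtype=int)
    stack = [(0, 0)]
    while stack:
        node, d = stack.pop()
        depth[node] = d
        if cl[node] != -1:
            stack.append((cl[node], d + 1))
            stack.append((cr[node], d + 1))
    return depth


def _forest_stats(model: MixRFbModel):
    p = len(model.feature_names)
    gini = np.zeros(p)
    root = np.zeros(p, dtype=int)
    nodes = np.zeros(p, dtype=int)
    total_internal = 0
    depths = []
    min_depth = []  # per tree: array of min split depth per feature (inf if absent)
    for est in model.forest.estimators_:
        cl, cr, feat, wn, imp = _tree_arrays(est)
        internal = cl != -1
        total_internal += int(internal.sum())
        dec = np.zeros(len(cl))
        dec[internal] = (wn[internal] * imp[internal]
                         - wn[cl[internal]] * imp[cl[internal]]
                         - wn[cr[internal]] * imp[cr[internal]])
        depth = _node_depths(cl, cr)
        depths.append(int(depth.max()))
        md = np.full(p, np.inf)
        for node in np.flatnonzero(internal):
            j = feat[node]
            gini[j] += dec[node]
            nodes[j] += 1
            md[j] = min(md[j], depth[node])
        if internal.any():
            root[feat[0]] += 1
        min_depth.append(md)
    return gini, root, nodes, total_internal, np.array(depths), np.array(min_depth)


def multiway_importance(model: MixRFbModel, data: pd.DataFrame | None = None,
                        p0_mode: str = "uniform", n_repeats: int = 10,
                        seed: int = 0) -> ImportanceReport:
    """Assemble the per-variable importance table.

    ``p0_mode='uniform'`` uses p0 = 1/p (a split variable drawn uniformly
    among all p covariates); ``'candidate'`` uses p0 = mtry/p, the chance
    the variable enters the candidate draw at all. The binomial tail is
    reported under both n conventions: number of trees (root splits,
    default plot) and total internal nodes.
    """
    if not getattr(model.forest, "estimators_", None):
        raise ValueError("model forest is not fitted")
    p = len(model.feature_names)
    gini, root, nodes, total_internal, depths, min_depth = _forest_stats(model)
    n_trees = len(model.forest.estimators_)
    mtry = model.config.mtry or max(1, int(np.sqrt(p)))
    p0 = (1.0 / p) if p0_mode == "uniform" else min(1.0, mtry / p)
    penalty = float(depths.mean()) + 1.0
    mmd = np.where(np.isfinite(min_depth), min_depth, penalty).mean(axis=0)
    present_everywhere = np.isfinite(min_depth).all(axis=0)

    table = pd.DataFrame({
        "variable": model.feature_names,
        "gini_decrease": gini,
        "root_count": root,
        "n_trees": n_trees,
        "node_count": nodes,
        "n_internal_nodes": total_internal,
        "p_value_root": [binomial_root_test(int(k), n_trees, p0) for k in root],
        "p_value_nodes": [binomial_root_test(int(k), total_internal, p0)
                          for k in nodes],
        "mean_minimal_depth": mmd,
        "in_every_tree": present_everywhere,
    })
    if data is not None:
        mda = permutation_importance(model, data, n_repeats=n_repeats, seed=seed)
        table["mean_decrease_accuracy"] = table["variable"].map(mda)
    pairs = {}
    for parent in model.feature_names:
        for child in model.feature_names:
            if parent != child:
                pairs[(parent, child)] = mean_minimal_depth(model, (parent, child))
    return ImportanceReport(table, pairs, n_trees)


# ---------------------------------------------------------------- PDP

def partial_dependence(model: MixRFbModel, data: pd.DataFrame, variable: str,
                       grid_resolution: int = 50) -> PDPCurve:
    """Average population-mode prediction as ``variable`` sweeps its
    2.5-97.5 percentile range, holding the other columns at observed values."""
    if variable not in model.feature_names:
        raise KeyError(f"variable {variable!r} not in the fitted model")
    col = pd.to_numeric(data[variable], errors="raise").to_numpy(dtype=float)
    lo, hi = np.percentile(col[np.isfinite(col)], [2.5, 97.5])
    if not hi > lo:
        raise ValueError(f"variable {variable!r} is (nearly) constant")
    grid = np.linspace(lo, hi, grid_resolution)
    means = np.empty(grid_resolution)
    work = data.copy()
    for i, v in enumerate(grid):
        work[variable] = v
        means[i] = float(np.mean(predict_prob(model, work, mode="population")))
    return PDPCurve(variable, grid, means, grid_resolution)


# ---------------------------------------------------------------- minimal depth

def _conditional_depth_tree(est, j_parent: int, j_child: int) -> float | None:
    """Min depth of a child-variable split strictly inside the maximal
    subtree(s) rooted at a parent-variable split; depth relative to the
    subtree root. None when the tree has no such configuration."""
    cl, cr, feat, _, _ = _tree_arrays(est)
    best: float | None = None
    # stack: (node, depth, root_depth_of_enclosing_maximal_parent_subtree or None)
    stack = [(0, 0, None)]
    while stack:
        node, d, sub_root = stack.pop()
        if cl[node] == -1:
            continue
        inside = sub_root is not None
        if inside and feat[node] == j_child and d > sub_root:
            rel = d - sub_root
            if best is None or rel < best:
                best = rel
        if not inside and feat[node] == j_parent:
            sub_root = d  # maximal parent-rooted subtree starts here
        stack.append((cl[node], d + 1, sub_root))
        stack.append((cr[node], d + 1, sub_root))
    return best


def mean_minimal_depth(model: MixRFbModel, variable) -> float:
    """Mean minimal depth of a variable, or conditional depth for a
    (parent, child) pair; root depth is 0, absent trees contribute the
    forest mean tree depth + 1."""
    names = model.feature_names
    _, _, _, _, depths, min_depth = _forest_stats(model)
    penalty = float(depths.mean()) + 1.0
    if isinstance(variable, (tuple, list)):
        parent, child = variable
        for v in (parent, child):
            if v not in names:
                raise KeyError(f"variable {v!r} not in the fitted model")
        jp, jc = names.index(parent), names.index(child)
        vals = []
        for est in model.forest.estimators_:
            rel = _conditional_depth_tree(est, jp, jc)
            vals.append(penalty if rel is None else float(rel))
        return float(np.mean(vals))
    if variable not in names:
        raise KeyError(f"variable {variable!r} not in the fitted model")
    j = names.index(variable)
    col = min_depth[:, j]
    return float(np.where(np.isfinite(col), col, penalty).mean())
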