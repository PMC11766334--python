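"""Random-forest learners used as the fixed-effects component.

Two variants share the scikit-learn tree machinery:

* :class:`PatientBootstrapForest` — bagging at the patient level: every tree
  is grown on a bootstrap sample of patients, so all rows of a patient are
  jointly in- or out-of-bag. Out-of-bag probabilities for a row therefore
  never see any row of the same patient, which keeps them honest under
  clustering and prevents patient memorization from collapsing the
  random-intercept variance downstream.
* plain scikit-learn ``RandomForestClassifier`` (row-level bagging), the
  conventional forest that ignores the repeated-measures structure.
"""
from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = ["PatientBootstrapForest", "fit_row_bootstrap_forest", "proba_death"]


def proba_death(clf, X: np.ndarray) -> np.ndarray:
    """Class-1 (death) probability, robust to single-class trees."""
    p = clf.predict_proba(X)
    classes = list(clf.classes_)
    if 1 in classes:
        return p[:, classes.index(1)]
    return np.zeros(len(X))


class PatientBootstrapForest:
    """Classification forest with patient-level bootstrap aggregation."""

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_node_size: int = 5, seed: int = 0):
        self.n_trees = int(n_trees)
        self.mtry = mtry
        self.min_node_size = int(min_node_size)
        self.seed = int(seed)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.oob_prob_: np.ndarray | None = None
        self.classes_ = np.array([0, 1])

    def fit(self, X, y, group_codes, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        codes = np.asarray(group_codes)
        G = int(codes.max()) + 1
        rows_by_group = [np.flatnonzero(codes == g) for g in range(G)]
        mtry = self.mtry or max(1, int(np.sqrt(X.shape[1])))

        ss = np.random.SeedSequence([self.seed, 20553])
        children = ss.spawn(self.n_trees)
        oob_sum = np.zeros(len(y))
        oob_cnt = np.zeros(len(y))
        self.estimators_ = []
        for child in children:
            rng = np.random.default_rng(child)
            for _ in range(20):  # redraw if the sample is single-class
                draw = rng.integers(0, G, size=G)
                rows = np.concatenate([rows_by_group[g] for g in draw])
                if y[rows].min() != y[rows].max():
                    break
            tree = DecisionTreeClassifier(
                max_features=mtry, min_samples_leaf=self.min_node_size,
                random_state=int(rng.integers(0, 2 ** 31 - 1)))
            sw = sample_weight[rows] if sample_weight is not None else None
            tree.fit(X[rows], y[rows], sample_weight=sw)
            self.estimators_.append(tree)
            oob_groups = np.setdiff1d(np.arange(G), draw, assume_unique=False)
            if len(oob_groups):
                oob_rows = np.concatenate([rows_by_group[g] for g in oob_groups])
                oob_sum[oob_rows] += proba_death(tree, X[oob_rows])
                oob_cnt[oob_rows] += 1
        full = self.predict_proba(X)[:, 1]
        with np.errstate(invalid="ignore"):
            oob = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), full)
        self.oob_prob_ = oob
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p1 = np.zeros(len(X))
        for tree in self.estimators_:
            p1 += proba_death(tree, X)
        p1 /= len(self.estimators_)
        return np.column_stack([1 - p1, p1])


def fit_row_bootstrap_forest(X, y, n_trees, mtry, min_node_size, seed):
    """Conventional row-bagged forest with OOB probabilities."""
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, min_samples_leaf=min_node_size,
        oob_score=True, bootstrap=True, random_state=int(seed) % (2 ** 31 - 1),
        n_jobs=1)
    rf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
    oob = rf.oob_decision_function_
    idx = list(rf.classes_).index(1)
    oob1 = oob[:, idx]
    missing = ~np.isfinite(oob1)
    if missing.any():  # rows never out of bag: fall back to in-bag probability
        oob1 = oob1.copy()
        oob1[missing] = proba_death(rf, np.asarray(X, dtype=float)[missing])
    return rf, oob1
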