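"""Bootstrap training/validation workflow with in-loop imputation.

Each replication draws ceil(split * n) patients with replacement (the
bootstrap sample, "60% of the data"); patients never drawn form the
out-of-bag test set. Imputation is fitted on the training side only and
applied frozen to the test side; minority-class patients are then
oversampled to balance the classes; the requested model is fitted and every
test patient-day is scored in population mode (test patients are unseen).
Row-level AUC and F1 are the headline metrics; a patient-level AUC on the
mean daily score is reported alongside. Aggregates are medians with
percentile confidence intervals over replications.

Resampling is always by patient, never by row, to respect the
repeated-measures structure. ``split_mode="mc"`` replaces the
with-replacement draw by a plain 60/40 random split.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .core import MODEL_FEATURES, MixRFbConfig, fit_mixrfb, fit_plain_rf, predict_prob
from .design import outcome_vector
from .glmm import fit_glmm_baseline, predict_glmm
from .impute import mice_apply, mice_fit_transform
from .metrics import compute_auc, compute_f1, percentile_ci

__all__ = ["BootstrapReport", "bootstrap_validate", "oversample_minority"]


@dataclass
class BootstrapReport:
    records: pd.DataFrame
    aggregates: dict
    B: int
    split_fraction: float
    split_mode: str
    model: str
    n_skipped: int

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "model": self.model, "B": self.B,
            "split_fraction": self.split_fraction, "split_mode": self.split_mode,
            "n_skipped": self.n_skipped, "aggregates": self.aggregates,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _patient_outcomes(cohort: pd.DataFrame) -> pd.Series:
    return cohort.groupby("patient_id", sort=False)["outcome"].first()


def oversample_minority(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Balance outcome classes by duplicating whole minority patients.

    Duplicates are drawn with replacement and given fresh patient_id
    aliases; a ``source_id`` column records the originating patient so the
    random-effect grouping can follow the source. Already-balanced cohorts
    are returned unchanged.
    """
    out_by_pid = _patient_outcomes(train)
    if out_by_pid.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    counts = out_by_pid.value_counts()
    if counts.iloc[0] == counts.iloc[1]:
        return train
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    pool = out_by_pid.index[out_by_pid == minority].to_numpy()
    rng = np.random.default_rng([seed, 71993])
    picks = rng.choice(pool, size=deficit, replace=True)

    base = train.copy()
    if "source_id" not in base.columns:
        base["source_id"] = base["patient_id"]
    blocks = [base]
    by_pid = dict(tuple(base.groupby("patient_id", sort=False)))
    for k, pid in enumerate(picks):
        block = by_pid[pid].copy()
        block["patient_id"] = f"{pid}~os{k}"
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def _draw_split(patients: np.ndarray, split: float, mode: str, rng):
    n = len(patients)
    k = math.ceil(split * n)
    if mode == "bootstrap":
        draw = rng.choice(patients, size=k, replace=True)
        test = np.array(sorted(set(patients) - set(draw)))
        return draw, test
    if mode == "mc":
        perm = rng.permutation(patients)
        return perm[:k], perm[k:]
    raise ValueError("split_mode must be 'bootstrap' or 'mc'")


def _build_train(cohort: pd.DataFrame, draw: np.ndarray) -> pd.DataFrame:
    """Assemble training rows honoring bootstrap multiplicity; duplicated
    patients get aliased ids sharing the source random-effect group."""
    by_pid = dict(tuple(cohort.groupby("patient_id", sort=False)))
    seen: dict[str, int] = {}
    blocks = []
    for pid in draw:
        j = seen.get(pid, 0)
        seen[pid] = j + 1
        block = by_pid[pid].copy()
        block["source_id"] = pid
        if j > 0:
            block["patient_id"] = f"{pid}~b{j}"
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def _fit_and_score(model_name, train, test, config, features):
    feats = features or MODEL_FEATURES.get(model_name, MODEL_FEATURES["A"])
    if model_name in ("A", "B"):
        fitted = fit_mixrfb(train, feats, config, group_col="source_id")
        scores = predict_prob(fitted, test, mode="population")
    elif model_name == "C":
        fitted = fit_plain_rf(train, feats, config)
        scores = predict_prob(fitted, test, mode="population")
    elif model_name == "glmm":
        fitted = fit_glmm_baseline(train, feats, group_col="source_id")
        scores = predict_glmm(fitted, test, mode="population")
    else:
        raise ValueError(f"unknown model {model_name!r}")
    return fitted, np.asarray(scores)


def run_replication(cohort: pd.DataFrame, rep_seed: int, model: str = "A",
                    split: float = 0.6, split_mode: str = "bootstrap",
                    config: MixRFbConfig | None = None,
                    features: list[str] | None = None,
                    oversample: bool = True, n_sweeps: int = 5) -> dict | None:
    """One bootstrap replication; returns metrics plus the intermediate
    artifacts (imputed training data, fitted model, patient id sets) so
    leakage and disjointness can be asserted directly. Returns None when the
    OOB test set has a single outcome class."""
    config = config or MixRFbConfig()
    rng = np.random.default_rng([rep_seed, 11])
    patients = np.asarray(pd.unique(cohort["patient_id"]))
    draw, test_pids = _draw_split(patients, split, split_mode, rng)
    test = cohort[cohort["patient_id"].isin(set(test_pids))].reset_index(drop=True)
    train = _build_train(cohort, draw)
    y_train = outcome_vector(train)
    if len(test) == 0 or y_train.min() == y_train.max():
        return None
    y_test = outcome_vector(test)
    if y_test.min() == y_test.max():
        return None

    train_imp, imodel = mice_fit_transform(train, n_sweeps=n_sweeps,
                                           seed=int(rep_seed) + 1)
    test_imp = mice_apply(imodel, test, seed=int(rep_seed) + 2)
    if oversample:
        train_fit = oversample_minority(train_imp, seed=int(rep_seed) + 3)
    else:
        train_fit = train_imp
    if "source_id" not in train_fit.columns:
        train_fit = train_fit.copy()
        train_fit["source_id"] = train_fit["patient_id"]
    cfg = dc_replace(config, seed=int(rep_seed) % (2 ** 31 - 1))
    fitted, scores = _fit_and_score(model, train_fit, test_imp, cfg, features)

    patient_scores = pd.Series(scores).groupby(test_imp["patient_id"].values).mean()
    patient_y = _patient_outcomes(test_imp).reindex(patient_scores.index)
    record = {
        "auc": compute_auc(scores, y_test),
        "f1": compute_f1(scores, y_test),
        "auc_patient": compute_auc(patient_scores.to_numpy(),
                                   (patient_y == "death").astype(int).to_numpy()),
        "n_train_patients": int(pd.unique(train["patient_id"]).size),
        "n_test_patients": int(pd.unique(test["patient_id"]).size),
    }
    return {
        "record": record, "model": fitted, "train_imputed": train_imp,
        "test_imputed": test_imp, "train_pids": set(train["source_id"]),
        "test_pids": set(test_pids), "scores": scores,
    }


def bootstrap_validate(cohort: pd.DataFrame, model: str = "A", B: int = 1000,
                       split: float = 0.6, seed: int = 0,
                       split_mode: str = "bootstrap",
                       config: MixRFbConfig | None = None,
                       features: list[str] | None = None,
                       oversample: bool = True, n_sweeps: int = 5) -> BootstrapReport:
    """Run B bootstrap replications and aggregate AUC/F1."""
    if B < 1:
        raise ValueError("B must be >= 1")
    master = np.random.SeedSequence([int(seed), 424243])
    rep_seeds = master.generate_state(B, dtype=np.uint32)
    rows = []
    skipped = 0
    for r in range(B):
        result = run_replication(cohort, int(rep_seeds[r]), model=model,
                                 split=split, split_mode=split_mode,
                                 config=config, features=features,
                                 oversample=oversample, n_sweeps=n_sweeps)
        if result is None:
            skipped += 1
            continue
        rows.append({"replication": r, "seed": int(rep_seeds[r]),
                     **result["record"]})
    records = pd.DataFrame(rows)
    aggregates = {}
    if len(records) >= 2:
        for metric in ("auc", "f1", "auc_patient"):
            vals = records[metric].to_numpy()
            lo, hi = percentile_ci(vals)
            aggregates[f"median_{metric}"] = float(np.median(vals))
            aggregates[f"{metric}_ci_low"] = lo
            aggregates[f"{metric}_ci_high"] = hi
    elif len(records) == 1:
        for metric in ("auc", "f1", "auc_patient"):
            aggregates[f"median_{metric}"] = float(records[metric].iloc[0])
    return BootstrapReport(records, aggregates, B, split, split_mode, model, skipped)
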