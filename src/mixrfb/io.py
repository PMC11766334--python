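"""Cohort CSV schema, validation and model bundle persistence.

The only input dialect is the long-format CSV: one row per patient-day with
columns patient_id, day, age, gender, rdw, saps, diabetes, cardiovascular,
respiratory, any_comorbidity, outcome. Empty fields encode missing values.
Validation errors name the offending row (1-based data row) and column.
"""
from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .core import MixRFbConfig, MixRFbModel

__all__ = ["read_cohort", "write_cohort", "save_model", "load_model",
           "CohortSchemaError"]

REQUIRED = ("patient_id", "day", "outcome")
CATEGORICAL = {
    "gender": {"male", "female"},
    "diabetes": {"yes", "no"},
    "cardiovascular": {"yes", "no"},
    "respiratory": {"yes", "no"},
    "any_comorbidity": {"yes", "no"},
    "outcome": {"death", "survival"},
}


class CohortSchemaError(ValueError):
    pass


def _fail(row, column, message):
    where = f"row {row}" if row is not None else "file"
    raise CohortSchemaError(f"{where}, column {column!r}: {message}")


def _first_bad(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0]) + 1


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in REQUIRED:
        if col not in df.columns:
            _fail(None, col, "required column missing")
    if df["patient_id"].isna().any():
        _fail(_first_bad(df["patient_id"].isna()), "patient_id", "missing identifier")

    day = pd.to_numeric(df["day"], errors="coerce")
    bad = day.isna() | (day != day.round()) | (day < 1)
    if bad.any():
        _fail(_first_bad(bad), "day", "day must be an integer >= 1")
    df["day"] = day.astype(int)

    dup = df.duplicated(subset=["patient_id", "day"])
    if dup.any():
        _fail(_first_bad(dup), "day", "duplicate (patient_id, day)")

    for col, legal in CATEGORICAL.items():
        if col not in df.columns:
            continue
        vals = df[col]
        bad = vals.notna() & ~vals.isin(legal)
        if bad.any():
            _fail(_first_bad(bad), col, f"value must be one of {sorted(legal)}")
        if col == "outcome" and vals.isna().any():
            _fail(_first_bad(vals.isna()), col, "outcome may not be missing")

    for col in ("age", "rdw", "saps"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce") \
                if df[col].dtype == object else df[col].astype(float)
    if "rdw" in df.columns:
        bad = df["rdw"].notna() & (df["rdw"] <= 0)
        if bad.any():
            _fail(_first_bad(bad), "rdw", "rdw must be positive")
    if "age" in df.columns:
        bad = df["age"].notna() & (df["age"] < 18)
        if bad.any():
            _fail(_first_bad(bad), "age",
                  "patients under 18 years are excluded from the cohort")

    per_patient = df.groupby("patient_id", sort=False)["outcome"].nunique()
    if (per_patient > 1).any():
        pid = per_patient.index[per_patient > 1][0]
        _fail(None, "outcome", f"patient {pid!r} has inconsistent outcomes")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cols += [c for c in cohort.columns if c not in cols]
    cohort[cols].to_csv(path, index=False, na_rep="")


def save_model(model: MixRFbModel, directory) -> None:
    """Persist a fitted model as a directory bundle.

    Layout: meta.json (kind, features, variance component, trace, config),
    intercepts.csv (patient_id, b), forest.joblib (the tree ensemble).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "meta.json", "w") as fh:
        json.dump(model.meta(), fh, indent=2)
    pd.DataFrame({"patient_id": list(model.random_intercepts),
                  "b": list(model.random_intercepts.values())}
                 ).to_csv(directory / "intercepts.csv", index=False)
    joblib.dump(model.forest, directory / "forest.joblib")


def load_model(directory) -> MixRFbModel:
    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    intercepts = pd.read_csv(directory / "intercepts.csv", dtype={"patient_id": str})
    forest = joblib.load(directory / "forest.joblib")
    return MixRFbModel(
        forest=forest,
        random_intercepts=dict(zip(intercepts["patient_id"], intercepts["b"])),
        sigma_b2=float(meta["sigma_b2"]),
        trace=list(meta["trace"]),
        feature_names=list(meta["feature_names"]),
        converged=bool(meta["converged"]),
        config=MixRFbConfig(**meta["config"]),
        kind=meta["kind"],
    )
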