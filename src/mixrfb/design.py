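"""Feature encoding shared by the model-fitting modules.

The long-format cohort stores categorical columns as strings
(``gender`` in {male, female}, comorbidity flags in {yes, no}); models work
on a numeric design matrix where female=1 and yes=1. The death outcome is
the positive class (1) everywhere.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

BINARY_CODING = {
    "gender": {"male": 0.0, "female": 1.0},
    "diabetes": {"no": 0.0, "yes": 1.0},
    "cardiovascular": {"no": 0.0, "yes": 1.0},
    "respiratory": {"no": 0.0, "yes": 1.0},
    "any_comorbidity": {"no": 0.0, "yes": 1.0},
}


def encode_column(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise KeyError(f"feature column {name!r} not present in data")
    col = df[name]
    if name in BINARY_CODING:
        mapped = col.map(BINARY_CODING[name])
        bad = mapped.isna() & col.notna()
        if bad.any():
            raise ValueError(
                f"column {name!r} contains values outside "
                f"{sorted(BINARY_CODING[name])}")
        return mapped.to_numpy(dtype=float)
    return pd.to_numeric(col, errors="raise").to_numpy(dtype=float)


def design_matrix(df: pd.DataFrame, features: list[str],
                  allow_missing: bool = False) -> np.ndarray:
    """Stack encoded feature columns; rejects non-finite cells by default."""
    X = np.column_stack([encode_column(df, f) for f in features])
    if not allow_missing and not np.all(np.isfinite(X)):
        bad = [f for j, f in enumerate(features) if not np.all(np.isfinite(X[:, j]))]
        raise ValueError(f"non-finite values in feature column(s) {bad}; "
                         "impute upstream before fitting")
    return X


def outcome_vector(df: pd.DataFrame) -> np.ndarray:
    col = df["outcome"]
    legal = {"death", "survival"}
    if not set(col.dropna().unique()) <= legal:
        raise ValueError(f"outcome values must be in {legal}")
    return (col == "death").to_numpy(dtype=int)


def group_codes(df: pd.DataFrame, group_col: str = "patient_id"):
    """Integer group codes in order of first appearance plus the labels.

    Order-of-appearance factorization (not sorting) keeps model fits
    invariant to relabeling of patient identifiers.
    """
    codes, labels = pd.factorize(df[group_col], sort=False)
    if (codes < 0).any():
        raise ValueError(f"missing values in grouping column {group_col!r}")
    return codes, list(labels)
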