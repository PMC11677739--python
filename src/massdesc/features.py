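"""Feature selection: correlation with BI-RADS grade and named feature sets.

The named sets follow the shape / margin / density selection experiments:
``S1`` all shape candidates, ``S2`` the four best-correlated shape features,
``S3`` the final shape pair {n_lobes, IS}; ``M1`` all four margin metrics,
``M2`` roundness only, ``M3`` {MR, n_lobes}; ``D1`` both density labels,
``D2`` the density-map label only; ``FINAL`` = S3 ∪ M3 ∪ D2 =
{n_lobes, IS, MR, dms}. ``BINARY`` uses the FINAL features with grades
BR-2/3 mapped to benign and BR-4/5 to malignant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURE_SETS: dict[str, list[str]] = {
    "S1": ["n_lobes", "is", "p_mean", "p_var", "p_std", "p_kurt", "p_skew"],
    "S2": ["n_lobes", "is", "p_mean", "p_std"],
    "S3": ["n_lobes", "is"],
    "M1": ["mr", "rr", "mor", "circ"],
    "M2": ["mr"],
    "M3": ["mr", "n_lobes"],
    "D1": ["dms_gray", "dms_dm"],
    "D2": ["dms_dm"],
    "FINAL": ["n_lobes", "is", "mr", "dms_dm"],
    "BINARY": ["n_lobes", "is", "mr", "dms_dm"],
}

#: Grades mapped to the binary benign(0)/malignant(1) reading.
BENIGN_GRADES = (2, 3)
MALIGNANT_GRADES = (4, 5)


@dataclass(frozen=True)
class CorrelationEntry:
    feature: str
    correlation: float
    zero_variance: bool


def correlation_profile(
    table: pd.DataFrame,
    features: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation of each feature with the integer BI-RADS grade (sign preserved).

    ``method`` may be "pearson" (default) or "spearman" (grade is ordinal).
    Zero-variance features get correlation 0 and a flag.
    """
    if "grade" not in table.columns:
        raise ValueError("table must contain a 'grade' column")
    grades = table["grade"].astype(float)
    if table.shape[0] < 3 or grades.nunique() < 2:
        raise ValueError("need >= 3 samples and >= 2 distinct grades")
    if features is None:
        features = [c for c in table.columns if c not in ("id", "grade") and
                    np.issubdtype(table[c].dtype, np.number)]
    rows = []
    for name in features:
        x = table[name].astype(float)
        if x.std(ddof=0) == 0:
            rows.append(CorrelationEntry(name, 0.0, True))
        else:
            rows.append(CorrelationEntry(name, float(x.corr(grades, method=method)), False))
    return pd.DataFrame([r.__dict__ for r in rows])


def binary_labels(grades) -> np.ndarray:
    """BR-2/3 -> 0 (benign), BR-4/5 -> 1 (malignant)."""
    grades = np.asarray(grades, int)
    if not np.isin(grades, BENIGN_GRADES + MALIGNANT_GRADES).all():
        raise ValueError("grades must be in 2..5")
    return np.isin(grades, MALIGNANT_GRADES).astype(int)


def build_feature_set(table: pd.DataFrame, name: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Column subset for a named feature set, with labels.

    Returns ``(X, y, feature_names)``; ``y`` is the integer grade, except for
    the BINARY set where it is the benign/malignant label.
    """
    key = name.upper()
    if key not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {name!r}; known: {sorted(FEATURE_SETS)}")
    cols = FEATURE_SETS[key]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing feature columns {missing}")
    X = table[cols].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError(f"missing values in active feature set {key}")
    grades = table["grade"].to_numpy(int)
    y = binary_labels(grades) if key == "BINARY" else grades
    return X, y, list(cols)
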