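"""Spearman-rank screening of features against the chilling-injury grade.

Each feature is scored by its Spearman rank correlation with the numeric grade
level (1-4).  With no ties the coefficient reduces to

    Rs = 1 - 6 * sum(d_i^2) / (n^3 - n),

where d_i is the rank difference of observation i; grade labels are massively
tied, so the tie-corrected estimator (product-moment correlation of average
ranks) is used throughout.  |Rs| is binned into strength groups

    [0, 0.3) weak | [0.3, 0.5) moderate | [0.5, 0.8) strong | [0.8, 1] very strong

and the very-strong group becomes the classifier input set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STRENGTH_BINS",
    "SpearmanResult",
    "spearman_rho",
    "classify_strength",
    "select_features",
]

#: |rho| left bin edges for moderate / strong / very_strong
STRENGTH_BINS = (0.3, 0.5, 0.8)
_STRENGTH_NAMES = ("weak", "moderate", "strong", "very_strong")


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman correlation of one feature with the grade level."""

    feature_name: str
    rho: float
    strength: str


def spearman_rho(x, y) -> float:
    """Tie-corrected Spearman rank correlation of two equal-length vectors.

    A constant ``x`` has no rank ordering; the correlation is defined as 0
    (with a warning).  ``y`` must not be constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0:
        raise ValueError("y is constant")
    if np.ptp(x) == 0:
        warnings.warn("constant feature: Spearman rho set to 0", stacklevel=2)
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def classify_strength(rho: float) -> str:
    """Strength group of |rho|: weak / moderate / strong / very_strong."""
    a = abs(rho)
    if a > 1:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    return _STRENGTH_NAMES[int(np.searchsorted(STRENGTH_BINS, a, side="right"))]


def _grade_levels(grades) -> np.ndarray:
    order = {"A": 1, "B": 2, "C": 3, "D": 4}
    try:
        return np.array([order[g] if isinstance(g, str) else int(g) for g in grades],
                        dtype=float)
    except KeyError as exc:
        raise ValueError(f"unknown grade label {exc.args[0]!r}") from None


def select_features(feature_table: pd.DataFrame, grades) -> tuple[list[str], pd.DataFrame]:
    """Screen every feature column against the grade and keep the very-strong group.

    Parameters
    ----------
    feature_table
        n x p DataFrame of feature values (one column per named feature).
    grades
        n grade labels (A-D) or numeric levels.

    Returns
    -------
    (selected, report)
        ``selected``: names with strength ``very_strong``, in column order.
        ``report``: one row per feature with rho, |rho|, strength and the
        selection flag.
    """
    levels = _grade_levels(grades)
    if len(levels) != len(feature_table):
        raise ValueError("grades and feature table disagree in length")
    if len(levels) < 8 or len(np.unique(levels)) < 2:
        raise ValueError("need >= 8 rows spanning >= 2 distinct grades")
    rows = []
    for name in feature_table.columns:
        rho = spearman_rho(feature_table[name].to_numpy(), levels)
        strength = classify_strength(rho)
        rows.append((name, rho, abs(rho), strength, strength == "very_strong"))
    report = pd.DataFrame(rows, columns=["feature", "rho", "abs_rho",
                                         "strength", "selected"])
    selected = report.loc[report["selected"], "feature"].tolist()
    if not selected:
        warnings.warn("no feature reaches the very-strong group; selection is empty",
                      stacklevel=2)
    return selected, report
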