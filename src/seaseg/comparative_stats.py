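"""Sex-comparison statistics: size dimorphism, bill PCA, segregation tests.

Covers the sexual size dimorphism index (SSI), a covariance PCA of the four
bill measurements whose first axis serves as a bill-size proxy, the Pearson
chi-square test of sex-by-nonbreeding-area contingency tables, and the
Welch t-test used to decide whether neighbouring areas with indistinguishable
feather isotope values should be merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

BILL_VARIABLES = ["culmen_mm", "head_bill_mm", "bill_depth_base_mm", "bill_depth_nostril_mm"]


def ssi(male_mean: float, female_mean: float) -> float:
    """Sexual size dimorphism index, percent.

    (m - f) / (0.5 * (m + f)) * 100: symmetric about zero (monomorphy),
    positive when males are the larger sex.
    """
    if male_mean <= 0 or female_mean <= 0:
        raise ValueError("SSI needs positive means")
    return (male_mean - female_mean) / ((male_mean + female_mean) * 0.5) * 100.0


def bill_pca(records: pd.DataFrame, variables: Sequence[str] = BILL_VARIABLES):
    """Covariance PCA of the bill measurements.

    Centering only (no scaling): the four variables share units (mm), so the
    covariance PCA keeps PC1 interpretable as overall bill size in mm.  PC1 is
    oriented so that larger bills score positive.  Rows with missing values
    are dropped with a warning.

    Returns ``(pc1_scores, variance_explained)`` with scores indexed like the
    retained rows.
    """
    x = records.loc[:, list(variables)]
    complete = x.notna().all(axis=1)
    if (~complete).any():
        warnings.warn(f"dropping {(~complete).sum()} incomplete biometric row(s)",
                      stacklevel=2)
    x = x.loc[complete]
    if len(x) < 5:
        raise ValueError(f"PCA needs >= 5 complete records, got {len(x)}")
    centred = x.to_numpy(dtype=float) - x.to_numpy(dtype=float).mean(axis=0)
    cov = np.cov(centred, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    if eigvec[:, 0].sum() < 0:  # larger bills positive
        eigvec[:, 0] = -eigvec[:, 0]
    scores = centred @ eigvec[:, 0]
    var_frac = eigval / eigval.sum()
    return pd.Series(scores, index=x.index, name="pc1"), var_frac


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    low_expected: bool


def pearson_chi_square(table) -> ChiSquareResult:
    """Uncorrected Pearson chi-square of an r x c contingency table.

    Expected counts from the margins; df = (r-1)(c-1).  Flags (does not fail)
    tables with any expected count below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn("expected count < 5 in contingency table", stacklevel=2)
    return ChiSquareResult(float(chi2), int(df), float(p), low)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df_welch: float
    p: float
    merge: bool


def welch_t(group_a, group_b, alpha: float = 0.05) -> WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite df.

    ``merge`` is true when the two groups are indistinguishable at ``alpha``
    (p > alpha) — the criterion used to pool geographically adjacent
    nonbreeding areas with uniform isotope values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, True)
        raise ValueError("degenerate zero-variance groups with different means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return WelchResult(float(t), float(df), float(p), bool(p > alpha))


def welch_t_merge(
    d13c_a, d13c_b, d15n_a, d15n_b, alpha: float = 0.05
) -> Tuple[WelchResult, WelchResult, bool]:
    """Area-merging decision on both isotope elements.

    Two candidate areas merge only when *both* d13C and d15N are
    indistinguishable between them (Welch p > alpha for each element).
    """
    rc = welch_t(d13c_a, d13c_b, alpha)
    rn = welch_t(d15n_a, d15n_b, alpha)
    return rc, rn, rc.merge and rn.merge


def sex_area_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Sex-by-area contingency table from per-bird area assignments
    (columns ``sex`` and ``area``)."""
    return pd.crosstab(assignments["sex"], assignments["area"])
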