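"""Closed-form statistics: correlations, t tests, ICC, dependent-correlation
comparison, and Benjamini-Hochberg FDR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ICCResult:
    """Single-measure consistency intraclass correlation, ICC(3,1).

    Derived from the two-way ANOVA decomposition of a complete subject x
    session matrix with random subject effects and fixed session effects:
    ICC = (BMS - EMS) / (BMS + (k-1) EMS). Consistency form: a constant
    session offset does not lower the ICC.
    """

    icc: float
    bms: float  # between-subject mean square
    jms: float  # between-session mean square
    ems: float  # residual mean square
    n_subjects: int
    n_sessions: int


@dataclass
class CorrComparisonResult:
    """Two-sided z test comparing two dependent, nonoverlapping correlations."""

    r1: float
    r2: float
    z_stat: float
    p: float
    n: int


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def student_t_independent(a, b) -> tuple[float, int, float]:
    """Pooled-variance independent-samples t test; df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    return float(res.statistic), int(df), float(res.pvalue)


def icc_consistency(data: np.ndarray) -> ICCResult:
    """ICC(3,1) from a complete subject x session matrix.

    Two-way ANOVA: subjects (rows) random, sessions (columns) fixed, one
    observation per cell, so the residual mean square is the subject x session
    interaction. Parcel values are expected to be voxel averages; the matrix
    must be complete.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 sessions")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must be complete (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    icc = 1.0 if denom == 0 else (bms - ems) / denom
    return ICCResult(
        icc=float(icc), bms=float(bms), jms=float(jms), ems=float(ems),
        n_subjects=n, n_sessions=k,
    )


def _check_psd(r12, r34, r13, r14, r23, r24) -> None:
    C = np.array(
        [
            [1.0, r12, r13, r14],
            [r12, 1.0, r23, r24],
            [r13, r23, 1.0, r34],
            [r14, r24, r34, 1.0],
        ]
    )
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("implied 4x4 correlation matrix is not positive semidefinite")


def compare_dependent_correlations(
    r12: float, r34: float, r13: float, r14: float, r23: float, r24: float, n: int
) -> CorrComparisonResult:
    """Compare two dependent correlations sharing no variable (r12 vs r34).

    Dunn-Clark-type z on the Fisher transforms, with the covariance term
    evaluated at the back-transformed mean of the two correlations
    (Silver/Hittner modification); two-sided normal p. This is the setting of
    comparing parcellation methods: the same subjects underlie both
    correlations but the four variables are distinct.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    _check_psd(r12, r34, r13, r14, r23, r24)
    z12, z34 = np.arctanh(r12), np.arctanh(r34)
    rm = np.tanh((z12 + z34) / 2.0)
    cov_term = (
        0.5 * rm * rm * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - rm * (r13 * r14 + r23 * r24 + r13 * r23 + r14 * r24)
    )
    c = cov_term / (1.0 - rm * rm) ** 2
    z = (z12 - z34) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrComparisonResult(r1=float(r12), r2=float(r34), z_stat=float(z), p=float(p), n=n)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between subdivision Ki columns."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    r = np.corrcoef(np.asarray(table, dtype=float), rowvar=False)
    return pd.DataFrame(r, index=table.columns, columns=table.columns)
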