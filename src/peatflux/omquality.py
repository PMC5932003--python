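"""Organic-matter-quality proxies and correlation-mode PCA.

The eight OM variables carried through the analysis are total C and N (%),
C/N, d13C and d15N (permil), the degree of peat humification (DPH, alkaline
extract absorbance) and the two FTIR decomposition indices
carbohydrate/lignin (1040/1650 cm-1) and carbohydrate/aliphatic
(1040/2920 cm-1).  PCA is run in correlation mode: every column is z-scored
(n-1 sample SD) and the correlation matrix eigen-decomposed, so loadings
are variable-component correlations and eigenvalues sum to the number of
variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OM_VARIABLES",
    "PcaResult",
    "correct_dph",
    "ftir_indices",
    "pca_correlation",
    "detrend_on_component",
    "pearson",
    "build_om_matrix",
]

OM_VARIABLES = (
    "C",
    "N",
    "C/N",
    "d13C",
    "d15N",
    "DPH",
    "carbohydrate/lignin",
    "carbohydrate/aliphatic",
)


def correct_dph(absorbance: np.ndarray, age: np.ndarray) -> np.ndarray:
    """Remove the long-term decomposition trend from humification.

    Ordinary least squares of absorbance on age (first-order polynomial);
    the corrected series is residual + overall mean, so it stays on the
    absorbance scale while the secular catotelm-decomposition trend is gone.
    """
    absorbance = np.asarray(absorbance, dtype=float)
    age = np.asarray(age, dtype=float)
    if absorbance.size < 3:
        raise ValueError("need at least 3 slices")
    if np.ptp(age) == 0:
        raise ValueError("age vector is constant; cannot detrend on age")
    slope, intercept = np.polyfit(age, absorbance, 1)
    resid = absorbance - (slope * age + intercept)
    return resid + absorbance.mean()


def ftir_indices(
    band_1040: np.ndarray, band_1650: np.ndarray, band_2920: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """FTIR decomposition indices (carbohydrate/lignin, carbohydrate/aliphatic)."""
    b1040 = np.asarray(band_1040, dtype=float)
    b1650 = np.asarray(band_1650, dtype=float)
    b2920 = np.asarray(band_2920, dtype=float)
    if np.any(b1650 <= 0) or np.any(b2920 <= 0):
        raise ValueError("denominator band intensities must be > 0")
    return b1040 / b1650, b1040 / b2920


@dataclass(frozen=True)
class PcaResult:
    """Correlation-mode PCA output.

    ``loadings`` (variables x components) are correlation-scaled
    (eigenvector times sqrt(eigenvalue)); ``scores`` (rows x components)
    are standardised to unit variance; ``explained_variance`` is the
    fraction of total variance per component.
    """

    loadings: pd.DataFrame
    scores: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray

    @property
    def variables(self) -> list[str]:
        return list(self.loadings.index)


def pca_correlation(matrix: pd.DataFrame) -> PcaResult:
    """PCA of the correlation matrix of ``matrix`` (rows = slices).

    Each component is oriented so that its largest-|loading| variable loads
    positively (the sign of a principal axis is arbitrary).  Raises on
    constant columns, naming them.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if np.any(~np.isfinite(X)):
        raise ValueError("matrix contains missing/non-finite cells")
    sd = X.std(axis=0, ddof=1)
    constant = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # orientation: largest-|loading| variable positive per component
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    loadings = eigvec * np.sqrt(eigval)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(eigval > 0, (Z @ eigvec) / np.sqrt(eigval), 0.0)
    names = [f"Cp{j + 1}" for j in range(len(eigval))]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=names),
        scores=scores,
        eigenvalues=eigval,
        explained_variance=eigval / eigval.sum(),
    )


def detrend_on_component(series: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """OLS residuals of a series on one component's scores."""
    series = np.asarray(series, dtype=float)
    scores = np.asarray(scores, dtype=float)
    A = np.column_stack([scores, np.ones_like(scores)])
    coef, *_ = np.linalg.lstsq(A, series, rcond=None)
    return series - A @ coef


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with n >= 3")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("inputs must be finite")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def build_om_matrix(
    age: np.ndarray,
    c_pct: np.ndarray,
    n_pct: np.ndarray,
    d13c: np.ndarray,
    d15n: np.ndarray,
    dph: np.ndarray,
    ftir_1040: np.ndarray,
    ftir_1650: np.ndarray,
    ftir_2920: np.ndarray,
    correct_dph_on_age: bool = True,
) -> pd.DataFrame:
    """Assemble the 8-variable OM matrix indexed by midpoint age.

    DPH is detrended on age by default (the humification working value is
    corrected for decomposition over time before multivariate analysis).
    """
    carb_lig, carb_ali = ftir_indices(ftir_1040, ftir_1650, ftir_2920)
    dph = np.asarray(dph, dtype=float)
    if correct_dph_on_age:
        dph = correct_dph(dph, age)
    n_pct = np.asarray(n_pct, dtype=float)
    if np.any(n_pct <= 0):
        raise ValueError("N% must be > 0 to form C/N")
    data = {
        "C": np.asarray(c_pct, dtype=float),
        "N": n_pct,
        "C/N": np.asarray(c_pct, dtype=float) / n_pct,
        "d13C": np.asarray(d13c, dtype=float),
        "d15N": np.asarray(d15n, dtype=float),
        "DPH": dph,
        "carbohydrate/lignin": carb_lig,
        "carbohydrate/aliphatic": carb_ali,
    }
    return pd.DataFrame(data, index=pd.Index(np.asarray(age, dtype=float), name="age"))
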