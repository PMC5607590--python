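"""Confounder adjustment by OLS residuals, and column standardization.

When factors such as age, sex or BMI influence the outcome but are not of
primary interest, the tree is grown on *adjusted residuals*: fit

    Y = b0 + b1 C1 + ... + bk Ck + e

by ordinary least squares over the confounders C1..Ck, and use

    Y* = Y − b0̂ − b1̂ C1 − ... − bk̂ Ck

as the outcome.  On the fitting sample Y* has mean zero and is exactly
orthogonal to every confounder.  Adjustment and tree fitting use the same
sample; binary confounders enter as 0/1 numeric columns, and the
confounders are excluded from the tree's candidate covariates.

``standardize`` implements the column-wise z-scoring used for display
(mean 0, variance 1 with denominator n−1), retaining per-column means and
SDs so results can be mapped back to the original units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AdjustmentModel",
    "fit_adjustment",
    "adjusted_residuals",
    "adjust_outcome",
    "standardize",
    "destandardize",
]


@dataclass
class AdjustmentModel:
    """OLS fit over confounders; coefficients are (intercept, slopes...)."""

    confounders: list[str]
    coefficients: np.ndarray
    residual_sd: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.confounders) + 1:
            raise ValueError("coefficient count must equal confounder count + 1")

    def fitted(self, data: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.confounders if c not in data.columns]
        if missing:
            raise ValueError(f"missing confounder column(s): {missing}")
        X = data[self.confounders].to_numpy(dtype=float)
        return self.coefficients[0] + X @ self.coefficients[1:]


def fit_adjustment(
    data: pd.DataFrame, outcome: str, confounders: list[str]
) -> AdjustmentModel:
    """Ordinary least squares of the outcome on an intercept and confounders."""
    if not confounders:
        raise ValueError("at least one confounder is required")
    n = len(data)
    if n <= len(confounders) + 1:
        raise ValueError("need n > number of confounders + 1")
    X = sm.add_constant(data[confounders].to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = _collinear_columns(X, ["(intercept)"] + list(confounders))
        raise ValueError(f"rank-deficient design; collinear columns: {names}")
    res = sm.OLS(np.asarray(data[outcome], dtype=float), X).fit()
    resid_sd = float(np.std(res.resid, ddof=X.shape[1]))
    return AdjustmentModel(list(confounders), np.asarray(res.params), resid_sd)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    from scipy.linalg import qr

    _, R, piv = qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


def adjusted_residuals(
    data: pd.DataFrame, model: AdjustmentModel, outcome: str
) -> np.ndarray:
    """Outcome minus the adjustment model's fitted values (Y*)."""
    if outcome not in data.columns:
        raise ValueError(f"outcome column {outcome!r} not in data")
    return data[outcome].to_numpy(dtype=float) - model.fitted(data)


def adjust_outcome(
    data: pd.DataFrame, outcome: str, confounders: list[str]
) -> tuple[pd.DataFrame, AdjustmentModel]:
    """Fit the adjustment, replace the outcome by Y*, drop the confounders.

    The returned frame is ready for tree fitting: the confounders are no
    longer offered as candidate split variables.
    """
    model = fit_adjustment(data, outcome, confounders)
    out = data.drop(columns=confounders).copy()
    out[outcome] = adjusted_residuals(data, model, outcome)
    return out, model


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-scoring: mean 0, variance 1 (denominator n−1).

    Returns the scored frame plus the per-column means and SDs needed to
    back-transform (a standardized value v corresponds to
    ``mean + v * sd`` in original units).
    """
    means = X.mean()
    sds = X.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be standardized: {constant}")
    return (X - means) / sds, means, sds


def destandardize(Z: pd.DataFrame, means: pd.Series, sds: pd.Series) -> pd.DataFrame:
    """Inverse of :func:`standardize`."""
    return Z * sds + means
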