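"""Regression model specification, standardization, OLS fitting and VIF.

The regression battery reports *standardized* coefficients: continuous
variables are z-scored within the analytic (complete-case) sample while
binary sex stays coded 0 = female / 1 = male.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: predictors of the baseline (cross-sectional) model, in reported order
CROSS_SECTIONAL_TERMS = ("qsm", "volume", "age", "sex", "disease_duration")
#: the longitudinal model adds the baseline outcome and the follow-up interval
LONGITUDINAL_TERMS = CROSS_SECTIONAL_TERMS + ("baseline_outcome", "followup_interval")

#: terms that are never z-scored
BINARY_TERMS = frozenset({"sex"})


@dataclass(frozen=True)
class ModelSpec:
    """One model of the battery: a (family, region, outcome) cell."""

    family: str  # "cross_sectional" | "longitudinal"
    region: str
    outcome: str
    n_permutations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("cross_sectional", "longitudinal"):
            raise ValueError(f"unknown model family {self.family!r}")

    @property
    def terms(self) -> tuple[str, ...]:
        return (
            CROSS_SECTIONAL_TERMS
            if self.family == "cross_sectional"
            else LONGITUDINAL_TERMS
        )


@dataclass
class ModelResult:
    """A fitted battery model with permutation and FDR inference."""

    spec: ModelSpec
    beta: dict[str, float]  # standardized coefficients per term
    tvalues: dict[str, float]
    p_perm: dict[str, float]
    q_fdr: dict[str, float]  # grouped-FDR corrected p (effect terms)
    significant: dict[str, bool]
    r_squared: float
    n_used: int
    flags: dict = field(default_factory=dict)


def standardize(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Z-score ``columns`` of a copy of ``table`` (mean 0, sd 1, ddof 1).

    Raises on zero-variance columns; binary 0/1 sex should not be passed.
    """
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        if not has_variance(x):
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - np.nanmean(x)) / np.nanstd(x, ddof=1)
    return out


def has_variance(x: np.ndarray) -> bool:
    """False for (numerically) constant columns."""
    sd = np.nanstd(np.asarray(x, dtype=float), ddof=1)
    scale = max(1.0, float(abs(np.nanmean(x))))
    return bool(np.isfinite(sd) and sd > 1e-12 * scale)


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for k in range(x.shape[1]):
        others = np.delete(x, k, axis=1)
        resid = x[:, k] - others @ np.linalg.lstsq(others, x[:, k], rcond=None)[0]
        if np.sum(resid**2) <= 1e-10 * max(np.sum(x[:, k] ** 2), 1.0):
            bad.append(names[k])
    return bad


def fit_ols(design: pd.DataFrame, outcome: np.ndarray | pd.Series):
    """Least-squares fit with intercept on complete cases.

    Returns a statsmodels results object; ``nobs`` reports the complete-case
    count.  Rank-deficient designs raise, naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    x = design.to_numpy(dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    x, y = x[keep], y[keep]
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("not enough complete cases for the design")
    xc = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        bad = _collinear_columns(xc, ["const", *design.columns])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    model = sm.OLS(y, xc)
    return model.fit()


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: ``1 / (1 - R^2_k)``.

    Perfectly collinear predictors are reported as ``inf`` (no exception),
    so the caller can flag them.
    """
    x = design.to_numpy(dtype=float)
    x = x[np.all(np.isfinite(x), axis=1)]
    out = {}
    for k, name in enumerate(design.columns):
        others = sm.add_constant(np.delete(x, k, axis=1), has_constant="add")
        fit = sm.OLS(x[:, k], others).fit()
        r2 = min(fit.rsquared, 1.0)
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
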