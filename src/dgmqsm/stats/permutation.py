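"""Freedman-Lane permutation p-values for linear-model coefficients.

For each tested coefficient, residuals of the reduced model (all other
terms) are permuted and added back to the reduced-model fit, the full model
is refit on each permuted response, and the observed |t| is ranked among the
permuted |t| values.  This preserves the nuisance structure (the reduced-
model fit) while destroying any association specific to the tested term,
giving valid inference under non-normal residuals.  The estimator is
``p = (1 + #{|t*| >= |t_obs|}) / (1 + B)``, never exactly zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def freedman_lane_pvalues(
    design: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    n_permutations: int = 10000,
    seed: int = 0,
    terms: list[str] | None = None,
) -> tuple[pd.Series, pd.Series, dict]:
    """Permutation p per term of an OLS fit with intercept.

    Parameters
    ----------
    design : DataFrame
        Predictor columns (no intercept; it is added internally).
    outcome : array-like
    n_permutations : int
        Below 100 the returned flags carry a warning (resolution too coarse
        for any conventional alpha).
    seed : int
        Drives the permutation stream; identical seeds give identical p.
    terms : list of str, optional
        Subset of columns to test (default: all).

    Returns
    -------
    (p, t_obs, flags)
    """
    flags: dict = {}
    if n_permutations < 100:
        flags["warning"] = "fewer than 100 permutations: p-values are coarse"

    names = list(design.columns)
    terms = names if terms is None else list(terms)
    y = np.asarray(outcome, dtype=float)
    x = design.to_numpy(dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    x, y = x[keep], y[keep]
    n = len(y)
    xc = np.column_stack([np.ones(n), x])
    p_cols = xc.shape[1]
    df_resid = n - p_cols

    pinv = np.linalg.pinv(xc)
    xtx_inv_diag = np.sum(pinv**2, axis=1)  # diag of (X'X)^-1 via pinv rows
    beta = pinv @ y
    resid = y - xc @ beta
    sigma2 = resid @ resid / df_resid
    t_obs = beta / np.sqrt(sigma2 * xtx_inv_diag)

    rng = np.random.default_rng(seed)
    p_out: dict[str, float] = {}
    for term in terms:
        k = 1 + names.index(term)  # offset for intercept
        x_red = np.delete(xc, k, axis=1)
        beta_red = np.linalg.lstsq(x_red, y, rcond=None)[0]
        yhat_red = x_red @ beta_red
        e_red = y - yhat_red

        idx = rng.permuted(
            np.broadcast_to(np.arange(n), (n_permutations, n)), axis=1
        )
        y_star = yhat_red[:, None] + e_red[idx].T  # (n, B)
        b_star = pinv @ y_star
        r_star = y_star - xc @ b_star
        sigma2_star = np.einsum("ij,ij->j", r_star, r_star) / df_resid
        t_star = b_star[k] / np.sqrt(sigma2_star * xtx_inv_diag[k])
        exceed = int(np.sum(np.abs(t_star) >= np.abs(t_obs[k])))
        p_out[term] = (1.0 + exceed) / (1.0 + n_permutations)

    t_series = pd.Series({nm: t_obs[1 + names.index(nm)] for nm in names})
    return pd.Series(p_out), t_series, flags
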