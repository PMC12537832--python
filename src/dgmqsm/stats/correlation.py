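"""Pairwise Spearman correlation matrix with FDR correction.

Rank correlation (average ranks for ties) over pairwise-complete
observations, two-sided p from the t-approximation, and Benjamini-Hochberg
FDR across the upper triangle — the all-variables screening step that
precedes the regression battery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman matrix with raw and FDR-corrected p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_fdr: pd.DataFrame
    n: pd.DataFrame  # pairwise-complete sample sizes

    @property
    def variables(self) -> list[str]:
        return list(self.r.columns)


def spearman_matrix(table: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations among ``variables``.

    Constant variables yield undefined correlations, reported as NaN.  Cells
    with fewer than 3 complete pairs raise.
    """
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = int(table[variables[i]].notna().sum())
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[variables[i], variables[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for "
                    f"({variables[i]}, {variables[j]})"
                )
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.spearmanr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue

    # BH-FDR across the upper triangle (defined cells only)
    iu = np.triu_indices(k, 1)
    raw = p[iu]
    q = np.full_like(raw, np.nan)
    finite = np.isfinite(raw)
    if finite.any():
        q[finite] = multipletests(raw[finite], method="fdr_bh")[1]
    p_fdr = np.full((k, k), np.nan)
    p_fdr[iu] = q
    p_fdr.T[iu] = q
    np.fill_diagonal(p_fdr, 0.0)

    def frame(a):
        return pd.DataFrame(a, index=variables, columns=variables)

    return CorrelationMatrix(r=frame(r), p=frame(p), p_fdr=frame(p_fdr), n=frame(n))
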