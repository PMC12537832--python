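"""Benjamini-Hochberg FDR applied independently within outcome groups.

The battery corrects p-values within each group of models sharing the same
outcome variable (one group per outcome, spanning the four regional models),
separately for the cross-sectional and longitudinal families.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def fdr_grouped(
    pvals: np.ndarray, group_labels: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Grouped BH step-up correction.

    Parameters
    ----------
    pvals : array of p-values in [0, 1] (NaN allowed: propagated untouched)
    group_labels : array of hashables, same length; correction is applied
        independently within each label
    q : target false discovery rate

    Returns
    -------
    (corrected p, significance flags)
    """
    p = np.asarray(pvals, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    groups = np.asarray(group_labels)
    if groups.shape != p.shape:
        raise ValueError("group_labels must match pvals in length")
    q_out = np.full_like(p, np.nan)
    sig = np.zeros_like(p, dtype=bool)
    for g in np.unique(groups):
        m = (groups == g) & finite
        if not np.any(m):
            continue
        reject, corrected, _, _ = multipletests(p[m], alpha=q, method="fdr_bh")
        q_out[m] = corrected
        sig[m] = reject
    return q_out, sig
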