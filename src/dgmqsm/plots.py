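"""Figure helpers: Spearman correlation heatmap and standardized-beta
heatmaps of the regression batteries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from dgmqsm.stats.correlation import CorrelationMatrix


def plot_correlation_matrix(corr: CorrelationMatrix, alpha: float = 0.05):
    """Heatmap of Spearman r with non-significant (FDR) cells left blank."""
    r = corr.r.to_numpy().copy()
    q = corr.p_fdr.to_numpy()
    shown = np.where((q <= alpha) | np.eye(len(r), dtype=bool), r, np.nan)
    fig, ax = plt.subplots(figsize=(0.5 * len(r) + 2, 0.5 * len(r) + 2))
    im = ax.imshow(shown, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(r)), corr.variables, rotation=90)
    ax.set_yticks(range(len(r)), corr.variables)
    fig.colorbar(im, ax=ax, label="Spearman $r_s$ (FDR-significant)")
    fig.tight_layout()
    return fig


def plot_beta_heatmap(results_frame: pd.DataFrame, term: str = "qsm"):
    """Region x outcome heatmap of standardized betas for one effect term;
    non-significant cells are annotated without color."""
    sub = results_frame[results_frame.term == term]
    regions = list(dict.fromkeys(sub.region))
    outcomes = list(dict.fromkeys(sub.outcome))
    beta = np.full((len(regions), len(outcomes)), np.nan)
    sig = np.zeros_like(beta, dtype=bool)
    for _, row in sub.iterrows():
        i, j = regions.index(row.region), outcomes.index(row.outcome)
        beta[i, j], sig[i, j] = row.beta, row.significant
    fig, ax = plt.subplots(figsize=(1.1 * len(outcomes) + 2, 1.0 * len(regions) + 1.5))
    shown = np.where(sig, beta, np.nan)
    vmax = max(0.2, np.nanmax(np.abs(beta)))
    im = ax.imshow(shown, vmin=-vmax, vmax=vmax, cmap="RdBu_r")
    for i in range(len(regions)):
        for j in range(len(outcomes)):
            ax.text(
                j, i, f"{beta[i, j]:.2f}", ha="center", va="center",
                fontweight="bold" if sig[i, j] else "normal",
                color="black" if sig[i, j] else "gray",
            )
    ax.set_xticks(range(len(outcomes)), outcomes, rotation=45)
    ax.set_yticks(range(len(regions)), regions)
    ax.set_title(f"standardized beta ({term})")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    return fig
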