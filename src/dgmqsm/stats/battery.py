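"""The regression battery: per-region standardized-beta models with
Freedman-Lane permutation p-values and outcome-grouped FDR.

Cross-sectional family (one model per region x outcome, 4 x 7 = 28):

    outcome_bl ~ qsm_region + volume_region + age + sex + disease_duration

Longitudinal family (4 regions x 5 clinical outcomes = 20):

    outcome_fu ~ qsm_region + volume_region + age + sex + disease_duration
                 + outcome_bl + followup_interval

Each model z-scores its continuous variables on its own complete cases
(sex stays 0/1), so coefficients are standardized betas.  FDR is applied
within each group of models sharing the same outcome, to the regional QSM
and volume effect terms (the cells of the reported heatmaps); nuisance
covariates are not corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dgmqsm.stats.fdr import fdr_grouped
from dgmqsm.stats.models import (
    BINARY_TERMS,
    ModelResult,
    ModelSpec,
    fit_ols,
    has_variance,
    standardize,
    vif,
)
from dgmqsm.stats.permutation import freedman_lane_pvalues
from dgmqsm.synthetic.cohort import (
    ALL_OUTCOMES,
    CLINICAL_OUTCOMES,
    OUTCOME_BASELINE_COLUMN,
    OUTCOME_FOLLOWUP_COLUMN,
    REGIONS,
)

#: terms entering the grouped FDR correction (the heatmap cells)
EFFECT_TERMS = ("qsm", "volume")


def _term_columns(spec: ModelSpec) -> dict[str, str]:
    cols = {
        "qsm": f"qsm_{spec.region}",
        "volume": f"vol_{spec.region}",
        "age": "age",
        "sex": "sex",
        "disease_duration": "disease_duration",
    }
    if spec.family == "longitudinal":
        cols["baseline_outcome"] = OUTCOME_BASELINE_COLUMN[spec.outcome]
        cols["followup_interval"] = "followup_interval"
    return cols


def _outcome_column(spec: ModelSpec) -> str:
    if spec.family == "cross_sectional":
        return OUTCOME_BASELINE_COLUMN[spec.outcome]
    return OUTCOME_FOLLOWUP_COLUMN[spec.outcome]


def fit_battery_model(spec: ModelSpec, table: pd.DataFrame) -> ModelResult:
    """Fit one battery cell; grouped FDR is attached by the battery runners."""
    cols = _term_columns(spec)
    out_col = _outcome_column(spec)
    missing = [c for c in [*cols.values(), out_col] if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")

    data = table[[*cols.values(), out_col]].dropna()
    flags: dict = {}

    # zero-variance continuous terms cannot be z-scored; they are excluded
    # from the design and reported with beta 0 and no test
    dropped: list[str] = []
    for term, col in cols.items():
        if term in BINARY_TERMS:
            continue
        if not has_variance(data[col].to_numpy(dtype=float)):
            dropped.append(term)
    if dropped:
        flags["zero_variance"] = dropped

    active = [t for t in spec.terms if t not in dropped]
    zcols = [cols[t] for t in active if t not in BINARY_TERMS] + [out_col]
    zdata = standardize(data, zcols)
    design = zdata[[cols[t] for t in active]].copy()
    design.columns = active

    fit = fit_ols(design, zdata[out_col])
    beta = dict(zip(["const", *active], fit.params))

    vifs = vif(design)
    flags["vif"] = vifs.to_dict()
    if np.any(~np.isfinite(vifs.to_numpy())) or np.any(vifs.to_numpy() >= 10):
        flags["vif_warning"] = True

    child_seed = int(
        np.random.SeedSequence(
            [
                spec.seed,
                0 if spec.family == "cross_sectional" else 1,
                REGIONS.index(spec.region),
                ALL_OUTCOMES.index(spec.outcome),
            ]
        ).generate_state(1)[0]
    )
    p_perm, t_obs, perm_flags = freedman_lane_pvalues(
        design, zdata[out_col], n_permutations=spec.n_permutations, seed=child_seed
    )
    flags.update(perm_flags)

    def full(d: dict[str, float], fill) -> dict[str, float]:
        return {t: d.get(t, fill) for t in spec.terms}

    return ModelResult(
        spec=spec,
        beta=full(beta, 0.0),
        tvalues=full(t_obs.to_dict(), np.nan),
        p_perm=full(p_perm.to_dict(), np.nan),
        q_fdr={t: np.nan for t in spec.terms},
        significant={t: False for t in spec.terms},
        r_squared=float(fit.rsquared),
        n_used=int(fit.nobs),
        flags=flags,
    )


def _attach_grouped_fdr(results: list[ModelResult], q: float) -> None:
    pvals, groups, where = [], [], []
    for i, res in enumerate(results):
        for term in EFFECT_TERMS:
            pvals.append(res.p_perm[term])
            groups.append(res.spec.outcome)
            where.append((i, term))
    q_corr, sig = fdr_grouped(np.asarray(pvals), np.asarray(groups), q=q)
    for (i, term), qv, sg in zip(where, q_corr, sig):
        results[i].q_fdr[term] = float(qv)
        results[i].significant[term] = bool(sg)


def run_cross_sectional_battery(
    table: pd.DataFrame,
    outcomes: tuple[str, ...] = ALL_OUTCOMES,
    n_permutations: int = 10000,
    seed: int = 0,
    q: float = 0.05,
) -> list[ModelResult]:
    """All baseline models: one per (region, outcome), FDR-grouped by outcome."""
    results = [
        fit_battery_model(
            ModelSpec("cross_sectional", region, outcome, n_permutations, seed), table
        )
        for outcome in outcomes
        for region in REGIONS
    ]
    _attach_grouped_fdr(results, q)
    return results


def run_longitudinal_battery(
    table: pd.DataFrame,
    outcomes: tuple[str, ...] = CLINICAL_OUTCOMES,
    n_permutations: int = 10000,
    seed: int = 0,
    q: float = 0.05,
) -> list[ModelResult]:
    """All follow-up models (clinical outcomes only); subjects without
    follow-up drop out per model via complete-case handling."""
    results = [
        fit_battery_model(
            ModelSpec("longitudinal", region, outcome, n_permutations, seed), table
        )
        for outcome in outcomes
        for region in REGIONS
    ]
    _attach_grouped_fdr(results, q)
    return results


def results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    """Long-format table: one row per (family, region, outcome, term)."""
    rows = []
    for res in results:
        for term in res.spec.terms:
            rows.append(
                {
                    "family": res.spec.family,
                    "region": res.spec.region,
                    "outcome": res.spec.outcome,
                    "term": term,
                    "beta": res.beta[term],
                    "t": res.tvalues[term],
                    "p_perm": res.p_perm[term],
                    "q_fdr": res.q_fdr[term],
                    "significant": res.significant[term],
                    "r_squared": res.r_squared,
                    "n": res.n_used,
                }
            )
    return pd.DataFrame(rows)
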