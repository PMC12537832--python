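"""Synthetic multiple-sclerosis cohort tables.

Generates per-subject rows with demographic covariates, regional deep-grey
susceptibility (QSM) values and head-size-normalized volumes, MRI surrogates
(normalized brain volume, lesion volume), and five clinical outcomes at
baseline and follow-up.  The generative model is a Gaussian latent system:

* continuous covariates (age, disease duration, 4 regional QSM values,
  4 regional volumes) are a multivariate normal with configurable means,
  SDs, and correlation matrix; sex is an independent Bernoulli (female = 0,
  male = 1);
* each outcome's standardized latent is a linear combination of standardized
  predictors — ``effect_map`` entries are true standardized regression
  coefficients — plus a Gaussian residual scaled so the latent has unit
  variance (``noise_sd`` = 1);
* follow-up outcomes combine an autocorrelation term on the baseline latent
  with injected baseline-predictor effects and fresh noise, again scaled to
  unit variance;
* outcome latents are mapped affinely onto clinically plausible scales
  (affine maps do not change standardized coefficients).

Defaults emulate a 771-subject early-MS cohort: age 40.0 (11.0) years,
35.7% male, disease duration 7.4 (6.3) years, regional QSM and normalized
volume means/SDs at published cohort values, a 51.4% follow-up subset with
intervals uniform on [1, 4.7] years, and effect-map defaults that populate
the regression battery with standardized effects of the reported sign and
size (e.g. caudate QSM -> EDSS beta = 0.19).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("thalamus", "caudate", "putamen", "pallidum")
CLINICAL_OUTCOMES = ("edss", "t25fw", "nhpt", "sdmt", "fsmc")
MRI_OUTCOMES = ("nbv", "log_tlv")
ALL_OUTCOMES = CLINICAL_OUTCOMES + MRI_OUTCOMES

#: table column holding each outcome at baseline
OUTCOME_BASELINE_COLUMN = {o: f"{o}_bl" for o in CLINICAL_OUTCOMES}
OUTCOME_BASELINE_COLUMN["nbv"] = "nbv_ml"
OUTCOME_BASELINE_COLUMN["log_tlv"] = "log_tlv"
OUTCOME_FOLLOWUP_COLUMN = {o: f"{o}_fu" for o in CLINICAL_OUTCOMES}

# Affine scale (location, scale) taking the unit-variance latent to clinical
# units.  Only presentation: standardized coefficients are scale-invariant.
_OUTCOME_SCALE = {
    "edss": (1.7, 1.2),
    "t25fw": (4.4, 1.0),
    "nhpt": (18.6, 3.0),
    "sdmt": (60.0, 11.0),
    "fsmc": (42.0, 20.0),
    "nbv": (1418.2, 56.8),
    "log_tlv": (0.8, 1.3),
}

_COVARIATES = ("age", "disease_duration")
# latent ordering: age, duration, qsm x 4, vol x 4 (REGIONS order), then sex
_LATENT_NAMES = (
    _COVARIATES
    + tuple(f"qsm_{r}" for r in REGIONS)
    + tuple(f"vol_{r}" for r in REGIONS)
    + ("sex",)
)

_QSM_MOMENTS = {
    "thalamus": (-0.008, 0.010),
    "caudate": (0.042, 0.018),
    "putamen": (0.050, 0.028),
    "pallidum": (0.099, 0.028),
}
_VOL_MOMENTS = {
    "thalamus": (13.0, 1.3),
    "caudate": (6.6, 0.8),
    "putamen": (8.6, 0.9),
    "pallidum": (2.9, 0.5),
}

LOG_TLV_OFFSET_ML = 0.01


def default_effect_map() -> dict[tuple[str, str], tuple[float, float]]:
    """(region, outcome) -> (standardized beta of QSM, of volume), baseline.

    Signs and magnitudes follow the reported cross-sectional associations:
    basal-ganglia QSM raises lesion load, EDSS and NHPT and lowers SDMT;
    thalamic QSM is weakly negative on lesion load; regional volumes carry
    the stronger (0.1-0.5) protective effects.
    """
    qsm = {
        ("caudate", "log_tlv"): 0.17,
        ("putamen", "log_tlv"): 0.14,
        ("pallidum", "log_tlv"): 0.14,
        ("caudate", "edss"): 0.19,
        ("putamen", "edss"): 0.15,
        ("pallidum", "edss"): 0.13,
        ("caudate", "nhpt"): 0.14,
        ("putamen", "nhpt"): 0.16,
        ("pallidum", "nhpt"): 0.13,
        ("caudate", "sdmt"): -0.14,
        ("putamen", "sdmt"): -0.15,
        ("pallidum", "sdmt"): -0.13,
        ("thalamus", "log_tlv"): -0.07,
    }
    vol = {
        ("thalamus", "edss"): -0.20,
        ("thalamus", "sdmt"): 0.20,
        ("thalamus", "nbv"): 0.40,
        ("thalamus", "log_tlv"): -0.25,
        ("caudate", "edss"): -0.12,
        ("caudate", "nbv"): 0.25,
        ("caudate", "log_tlv"): -0.15,
        ("putamen", "nbv"): 0.20,
        ("pallidum", "nbv"): 0.15,
    }
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for key in set(qsm) | set(vol):
        out[key] = (qsm.get(key, 0.0), vol.get(key, 0.0))
    return out


def default_longitudinal_effect_map() -> dict[tuple[str, str], tuple[float, float]]:
    """Baseline-predictor effects on follow-up outcomes (QSM beta, volume
    beta); default: volume-only prediction, QSM null."""
    return {
        ("thalamus", "edss"): (0.0, -0.11),
        ("caudate", "edss"): (0.0, -0.10),
        ("caudate", "nhpt"): (0.0, -0.14),
    }


def default_covariate_effects() -> dict[str, dict[str, float]]:
    """Standardized effects of age / sex / disease duration on outcomes —
    the nuisance structure the permutation scheme has to absorb."""
    return {
        "edss": {"disease_duration": 0.15, "age": 0.10},
        "t25fw": {"age": 0.10},
        "nhpt": {"age": 0.12},
        "sdmt": {"age": -0.20},
        "fsmc": {"disease_duration": 0.10},
        "nbv": {"age": -0.35},
        "log_tlv": {"disease_duration": 0.20},
    }


def default_covariate_correlation() -> np.ndarray:
    """Correlation matrix over (age, duration, qsm x 4, vol x 4).

    Encodes: age-duration dependence, basal-ganglia QSM rising with age and
    duration, atrophy (volume loss) with age/duration, inter-regional QSM and
    volume coherence, and a mild within-region QSM-volume anticorrelation.
    Configuration, not a fidelity claim.
    """
    n = 10
    r = np.eye(n)

    def setr(i, j, v):
        r[i, j] = r[j, i] = v

    iq = {reg: 2 + k for k, reg in enumerate(REGIONS)}
    iv = {reg: 6 + k for k, reg in enumerate(REGIONS)}
    setr(0, 1, 0.40)  # age - duration
    for reg in REGIONS[1:]:  # basal ganglia QSM vs age/duration
        setr(0, iq[reg], 0.40)
        setr(1, iq[reg], 0.18)
    setr(0, iq["thalamus"], -0.10)
    for reg in REGIONS:  # atrophy with age/duration
        setr(0, iv[reg], -0.30)
        setr(1, iv[reg], -0.18)
    for a in REGIONS[1:]:  # QSM coherence among basal ganglia
        for b in REGIONS[1:]:
            if a < b:
                setr(iq[a], iq[b], 0.50)
    for b in REGIONS[1:]:
        setr(iq["thalamus"], iq[b], 0.15)
    for a in REGIONS:  # volume coherence
        for b in REGIONS:
            if a < b:
                setr(iv[a], iv[b], 0.40)
    for reg in REGIONS:  # within-region QSM-volume anticorrelation
        setr(iq[reg], iv[reg], -0.25)
    return r


@dataclass
class CohortSpec:
    """Configuration of the synthetic cohort generator."""

    n_subjects: int = 771
    effect_map: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=default_effect_map
    )
    longitudinal_effect_map: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=default_longitudinal_effect_map
    )
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=default_covariate_effects
    )
    age_mean: float = 40.0
    age_sd: float = 11.0
    duration_mean: float = 7.4
    duration_sd: float = 6.3
    p_male: float = 0.357
    tiv_mean: float = 1540.0
    tiv_sd: float = 140.0
    covariate_correlation: np.ndarray = field(
        default_factory=default_covariate_correlation
    )
    followup_fraction: float = 396.0 / 771.0
    followup_interval: tuple[float, float] = (1.0, 4.7)
    autocorrelation: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if not 0.0 <= self.autocorrelation <= 1.0:
            raise ValueError("autocorrelation must lie in [0, 1]")
        for (reg, out), (bq, bv) in self.effect_map.items():
            if reg not in REGIONS or out not in ALL_OUTCOMES:
                raise ValueError(f"unknown effect key {(reg, out)}")
            if abs(bq) >= 1 or abs(bv) >= 1:
                raise ValueError(f"|standardized beta| must be < 1, got {(bq, bv)}")
        c = np.asarray(self.covariate_correlation, dtype=float)
        if c.shape != (10, 10) or not np.allclose(c, c.T):
            raise ValueError("covariate_correlation must be a symmetric 10x10 matrix")
        if np.min(np.linalg.eigvalsh(c)) <= 0:
            raise ValueError("covariate_correlation must be positive definite")
        lo, hi = self.followup_interval
        if lo < 1.0 or hi < lo:
            raise ValueError("followup_interval must satisfy 1 <= lo <= hi")

    def null(self) -> "CohortSpec":
        """Copy with all QSM/volume effects removed (pure-null cohort)."""
        return replace(self, effect_map={}, longitudinal_effect_map={})


def _latent_index(name: str) -> int:
    return _LATENT_NAMES.index(name)


def _effect_vector(
    outcome: str,
    effect_map: dict[tuple[str, str], tuple[float, float]],
    covariate_effects: dict[str, dict[str, float]],
) -> np.ndarray:
    a = np.zeros(len(_LATENT_NAMES))
    for (reg, out), (bq, bv) in effect_map.items():
        if out == outcome:
            a[_latent_index(f"qsm_{reg}")] += bq
            a[_latent_index(f"vol_{reg}")] += bv
    for cov, b in covariate_effects.get(outcome, {}).items():
        a[_latent_index(cov if cov != "sex" else "sex")] += b
    return a


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table; bit-identical for a fixed ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    corr = np.asarray(spec.covariate_correlation, dtype=float)
    chol = np.linalg.cholesky(corr)
    z_cont = rng.standard_normal((n, 10)) @ chol.T
    sex = (rng.random(n) < spec.p_male).astype(int)
    z_sex = (sex - spec.p_male) / np.sqrt(spec.p_male * (1 - spec.p_male))
    z = np.column_stack([z_cont, z_sex])  # (n, 11) standardized predictors
    r_full = np.eye(11)
    r_full[:10, :10] = corr

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "age": spec.age_mean + spec.age_sd * z[:, 0],
            "sex": sex,
            "disease_duration": np.clip(
                spec.duration_mean + spec.duration_sd * z[:, 1], 0.0, None
            ),
        }
    )
    for k, reg in enumerate(REGIONS):
        mu, sd = _QSM_MOMENTS[reg]
        df[f"qsm_{reg}"] = mu + sd * z[:, 2 + k]
        mu, sd = _VOL_MOMENTS[reg]
        df[f"vol_{reg}"] = mu + sd * z[:, 6 + k]
    df["tiv_ml"] = spec.tiv_mean + spec.tiv_sd * rng.standard_normal(n)

    # baseline outcome latents: unit variance by construction
    eps_bl: dict[str, np.ndarray] = {}
    lat_bl: dict[str, np.ndarray] = {}
    avec: dict[str, np.ndarray] = {}
    for out in ALL_OUTCOMES:
        a = _effect_vector(out, spec.effect_map, spec.covariate_effects)
        v_sys = float(a @ r_full @ a)
        v_res = 1.0 - v_sys
        if v_res <= 0:
            raise ValueError(
                f"effect combination for outcome {out!r} leaves residual "
                f"variance {v_res:.3f} <= 0"
            )
        eps = spec.noise_sd * np.sqrt(v_res) * rng.standard_normal(n)
        lat_bl[out] = z @ a + eps
        eps_bl[out] = eps
        avec[out] = a

    # follow-up latents for the clinical outcomes
    rho = spec.autocorrelation
    lat_fu: dict[str, np.ndarray] = {}
    for out in CLINICAL_OUTCOMES:
        b = _effect_vector(out, spec.longitudinal_effect_map, {})
        c = rho * avec[out] + b
        v_res_bl = 1.0 - float(avec[out] @ r_full @ avec[out])
        v_sys = float(c @ r_full @ c) + rho**2 * spec.noise_sd**2 * v_res_bl
        v_res = 1.0 - v_sys
        if v_res < -1e-9:
            raise ValueError(
                f"longitudinal effects for {out!r} leave residual variance "
                f"{v_res:.3f} < 0"
            )
        v_res = max(v_res, 0.0)  # rho = 1 with no extra effects is legal
        lat_fu[out] = (
            z @ c
            + rho * eps_bl[out]
            + spec.noise_sd * np.sqrt(v_res) * rng.standard_normal(n)
        )

    for out in ALL_OUTCOMES:
        loc, scale = _OUTCOME_SCALE[out]
        df[OUTCOME_BASELINE_COLUMN[out]] = loc + scale * lat_bl[out]
    # lesion volume in mL from its log-latent; log_tlv = ln(tlv + offset)
    df["tlv_ml"] = np.maximum(np.exp(df["log_tlv"]) - LOG_TLV_OFFSET_ML, 0.0)

    has_fu = rng.random(n) < spec.followup_fraction
    lo, hi = spec.followup_interval
    interval = np.where(has_fu, rng.uniform(lo, hi, size=n), np.nan)
    df["followup_interval"] = interval
    for out in CLINICAL_OUTCOMES:
        loc, scale = _OUTCOME_SCALE[out]
        col = loc + scale * lat_fu[out]
        df[OUTCOME_FOLLOWUP_COLUMN[out]] = np.where(has_fu, col, np.nan)

    return df
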