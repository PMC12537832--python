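"""Stage orchestration for the CLI: phantom -> signal -> reconstruction ->
metrics -> cohort -> statistical batteries, each writing its artifacts and
a run manifest."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from dgmqsm.config import PipelineConfig
from dgmqsm.io import (
    write_cohort,
    write_complex_volume,
    write_manifest,
    write_volume,
)
from dgmqsm.metrics import extract_region_metrics
from dgmqsm.recon import mtfi_reconstruct
from dgmqsm.stats import (
    results_to_frame,
    run_cross_sectional_battery,
    run_longitudinal_battery,
    spearman_matrix,
)
from dgmqsm.synthetic import (
    generate_cohort,
    make_dgm_phantom,
    synthesize_background_field,
    synthesize_multiecho,
)
from dgmqsm.synthetic.cohort import (
    OUTCOME_BASELINE_COLUMN,
    REGIONS,
)


def run_phantom(config: PipelineConfig, outdir: Path) -> dict:
    phantom = make_dgm_phantom(
        grid=config.grid, seed=config.stage_seed("phantom"), n_lesions=config.n_lesions
    )
    write_volume(phantom.chi, outdir / "chi_truth.nii.gz", config.grid)
    write_volume(phantom.labels, outdir / "labels.nii.gz", config.grid)
    write_volume(phantom.brain_mask, outdir / "brain_mask.nii.gz", config.grid)
    write_volume(phantom.csf_mask, outdir / "csf_mask.nii.gz", config.grid)
    write_volume(phantom.lesion_mask, outdir / "lesion_mask.nii.gz", config.grid)
    return {"phantom": phantom}


def run_signal(config: PipelineConfig, outdir: Path, phantom) -> dict:
    background = (
        synthesize_background_field(config.grid, phantom.brain_mask)
        if config.with_background
        else None
    )
    signal = synthesize_multiecho(
        phantom,
        acq=config.acquisition,
        background=background,
        seed=config.stage_seed("signal"),
    )
    write_complex_volume(signal, outdir / "signal")
    return {"signal": signal}


def run_recon(config: PipelineConfig, outdir: Path, signal, phantom) -> dict:
    qsm = mtfi_reconstruct(signal, phantom.brain_mask, phantom.csf_mask, config.recon)
    write_volume(qsm.chi, outdir / "chi_recon.nii.gz", config.grid)
    return {"qsm": qsm}


def run_metrics(config: PipelineConfig, outdir: Path, qsm, phantom) -> dict:
    metrics = extract_region_metrics(
        qsm,
        phantom.labels,
        phantom.label_names,
        phantom.brain_mask,
        phantom.lesion_mask,
        config.grid.voxel_volume_mm3,
    )
    metrics.table.to_csv(outdir / "region_metrics.csv", index=False)
    return {"metrics": metrics}


def run_cohort(config: PipelineConfig, outdir: Path) -> dict:
    cohort = generate_cohort(config.cohort_spec())
    write_cohort(cohort, outdir / "cohort.csv")
    return {"cohort": cohort}


def run_stats(config: PipelineConfig, outdir: Path, cohort: pd.DataFrame) -> dict:
    seed = config.stage_seed("stats")
    cs = run_cross_sectional_battery(
        cohort, n_permutations=config.n_permutations, seed=seed, q=config.fdr_q
    )
    lg = run_longitudinal_battery(
        cohort, n_permutations=config.n_permutations, seed=seed, q=config.fdr_q
    )
    cs_frame, lg_frame = results_to_frame(cs), results_to_frame(lg)
    cs_frame.to_csv(outdir / "cross_sectional_results.csv", index=False)
    lg_frame.to_csv(outdir / "longitudinal_results.csv", index=False)

    variables = (
        ["age", "disease_duration"]
        + [f"qsm_{r}" for r in REGIONS]
        + [f"vol_{r}" for r in REGIONS]
        + [OUTCOME_BASELINE_COLUMN[o] for o in OUTCOME_BASELINE_COLUMN]
    )
    corr = spearman_matrix(cohort, variables)
    corr.r.to_csv(outdir / "spearman_r.csv")
    corr.p_fdr.to_csv(outdir / "spearman_p_fdr.csv")
    return {"cross_sectional": cs, "longitudinal": lg, "correlation": corr}


def full_run(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Chain every stage; returns the in-memory artifacts."""
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    state.update(run_phantom(config, outdir))
    state.update(run_signal(config, outdir, state["phantom"]))
    state.update(run_recon(config, outdir, state["signal"], state["phantom"]))
    state.update(run_metrics(config, outdir, state["qsm"], state["phantom"]))
    state.update(run_cohort(config, outdir))
    state.update(run_stats(config, outdir, state["cohort"]))
    write_manifest(outdir / "manifest.json", config.to_dict(), config.seed, "full-run")
    return state
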