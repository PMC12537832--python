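"""ROI metrics: regional mean susceptibility, head-size-normalized volumes,
lesion-volume filtering and the log lesion-volume transform.

These operations turn maps and masks into the per-subject analysis
variables of the cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from dgmqsm.recon.mtfi import SusceptibilityMap
from dgmqsm.synthetic.cohort import LOG_TLV_OFFSET_ML

#: inclusive minimum surviving lesion-component volume (~3 mm diameter)
MIN_LESION_VOLUME_MM3 = 15.0


def roi_mean(
    chi: np.ndarray | SusceptibilityMap, labels: np.ndarray, label_id: int
) -> float:
    """Arithmetic mean susceptibility (ppm) over one label."""
    vol = chi.chi if isinstance(chi, SusceptibilityMap) else np.asarray(chi)
    mask = labels == label_id
    if not np.any(mask):
        raise ValueError(f"label {label_id} is absent from the label volume")
    return float(vol[mask].mean())


def normalize_volume(raw_ml: float, tiv_ml: float, mean_tiv_ml: float) -> float:
    """Head-size correction: divide by individual TIV, multiply by the
    cohort-mean TIV to stay on an intuitive mL scale."""
    if tiv_ml <= 0:
        raise ValueError(f"TIV must be positive, got {tiv_ml}")
    return raw_ml / tiv_ml * mean_tiv_ml


def lesion_filter_tlv(
    lesion_mask: np.ndarray,
    voxel_volume_mm3: float,
    min_volume_mm3: float = MIN_LESION_VOLUME_MM3,
) -> tuple[np.ndarray, float]:
    """Remove sub-threshold lesion components; return (mask, TLV in mL).

    Connected components use 26-connectivity; components with volume
    >= ``min_volume_mm3`` survive (inclusive threshold).  An empty mask
    yields TLV 0.
    """
    lesion_mask = np.asarray(lesion_mask).astype(bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    labeled, n = ndimage.label(lesion_mask, structure=structure)
    if n == 0:
        return np.zeros_like(lesion_mask), 0.0
    counts = np.bincount(labeled.ravel())[1:]
    keep = np.flatnonzero(counts * voxel_volume_mm3 >= min_volume_mm3) + 1
    filtered = np.isin(labeled, keep)
    tlv_ml = float(filtered.sum()) * voxel_volume_mm3 / 1000.0
    return filtered, tlv_ml


def log_tlv(tlv_ml: float, offset_ml: float = LOG_TLV_OFFSET_ML) -> float:
    """Natural log of (TLV + offset); the offset keeps zero-lesion subjects
    finite and is exposed as configuration."""
    if tlv_ml < 0:
        raise ValueError(f"TLV must be >= 0, got {tlv_ml}")
    return float(np.log(tlv_ml + offset_ml))


@dataclass
class RegionMetrics:
    """Per-subject summary extracted from one reconstructed map."""

    table: pd.DataFrame  # one row per region: qsm_ppm, n_voxels, raw/norm volume
    tiv_ml: float
    nbv_ml: float
    tlv_ml: float
    log_tlv: float


def extract_region_metrics(
    chi: np.ndarray | SusceptibilityMap,
    labels: np.ndarray,
    label_names: dict[int, str],
    brain_mask: np.ndarray,
    lesion_mask: np.ndarray,
    voxel_volume_mm3: float,
    tiv_ml: float | None = None,
    mean_tiv_ml: float | None = None,
) -> RegionMetrics:
    """Assemble the analysis variables for one subject.

    For the synthetic pipeline the intracranial volume is the whole-grid
    tissue volume unless given; NBV is the brain-mask volume.  Volumes in mL.
    """
    rows = []
    tiv = tiv_ml if tiv_ml is not None else float(brain_mask.sum()) * voxel_volume_mm3 / 1000.0
    mean_tiv = mean_tiv_ml if mean_tiv_ml is not None else tiv
    for lid, name in sorted(label_names.items()):
        n_vox = int((labels == lid).sum())
        raw_ml = n_vox * voxel_volume_mm3 / 1000.0
        rows.append(
            {
                "region": name,
                "qsm_ppm": roi_mean(chi, labels, lid),
                "n_voxels": n_vox,
                "raw_volume_ml": raw_ml,
                "normalized_volume_ml": normalize_volume(raw_ml, tiv, mean_tiv),
            }
        )
    _, tlv_ml = lesion_filter_tlv(lesion_mask, voxel_volume_mm3)
    nbv_ml = float(brain_mask.sum()) * voxel_volume_mm3 / 1000.0
    return RegionMetrics(
        table=pd.DataFrame(rows),
        tiv_ml=tiv,
        nbv_ml=nbv_ml,
        tlv_ml=tlv_ml,
        log_tlv=log_tlv(tlv_ml),
    )
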