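"""File I/O: NIfTI volumes, complex echo stacks, cohort/result tables,
configuration and run manifests.

Conventions: NIfTI-1 with an RAS+ diagonal affine built from the voxel
size; complex multi-echo data is stored as a magnitude/phase pair of 4-D
volumes (echo along the 4th axis) plus a JSON sidecar with the acquisition
parameters; tables are UTF-8 CSV.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from dgmqsm import __version__
from dgmqsm.grids import GridSpec
from dgmqsm.synthetic.signal import AcquisitionParams, MultiEchoComplexVolume


def _affine(grid: GridSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size
    return aff


def write_volume(volume: np.ndarray, path: str | Path, grid: GridSpec) -> Path:
    """Write a 3-D (or 4-D) volume as NIfTI-1 with the grid's RAS+ affine."""
    path = Path(path)
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(grid))
    img.header.set_zooms((*grid.voxel_size, *([1.0] * (data.ndim - 3))))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a NIfTI volume; returns the array and the grid it implies."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.asarray(img.dataobj)
    grid = GridSpec(shape=tuple(data.shape[:3]), voxel_size=tuple(float(z) for z in zooms))
    return data, grid


def check_same_geometry(path_a: str | Path, path_b: str | Path) -> None:
    """Raise if two volumes disagree in shape or affine (never resample)."""
    a, b = nib.load(str(path_a)), nib.load(str(path_b))
    if a.shape[:3] != b.shape[:3] or not np.allclose(a.affine, b.affine):
        raise ValueError(
            f"geometry mismatch between {path_a} and {path_b}: "
            f"shapes {a.shape[:3]} vs {b.shape[:3]}, affines differ: "
            f"{not np.allclose(a.affine, b.affine)}"
        )


def write_complex_volume(signal: MultiEchoComplexVolume, prefix: str | Path) -> dict:
    """Write a complex echo stack as ``<prefix>_mag.nii.gz`` +
    ``<prefix>_phase.nii.gz`` + ``<prefix>_acq.json``."""
    prefix = Path(prefix)
    mag = np.moveaxis(signal.magnitude, 0, -1)
    phase = np.moveaxis(signal.phase, 0, -1)
    paths = {
        "magnitude": write_volume(mag, prefix.with_name(prefix.name + "_mag.nii.gz"), signal.grid),
        "phase": write_volume(phase, prefix.with_name(prefix.name + "_phase.nii.gz"), signal.grid),
    }
    sidecar = prefix.with_name(prefix.name + "_acq.json")
    sidecar.write_text(
        json.dumps(
            {
                "echo_times_ms": list(signal.acq.echo_times),
                "tr_ms": signal.acq.tr,
                "flip_angle_deg": signal.acq.flip_angle,
                "b0_tesla": signal.acq.b0,
                "noise_sigma": signal.acq.noise_sigma,
                "b0_direction": list(signal.grid.b0_direction),
            },
            indent=2,
        )
    )
    paths["acq"] = sidecar
    return paths


def read_complex_volume(prefix: str | Path) -> MultiEchoComplexVolume:
    """Reassemble a complex echo stack written by :func:`write_complex_volume`."""
    prefix = Path(prefix)
    mag_path = prefix.with_name(prefix.name + "_mag.nii.gz")
    phase_path = prefix.with_name(prefix.name + "_phase.nii.gz")
    check_same_geometry(mag_path, phase_path)
    mag, grid = read_volume(mag_path)
    phase, _ = read_volume(phase_path)
    meta = json.loads(prefix.with_name(prefix.name + "_acq.json").read_text())
    acq = AcquisitionParams(
        echo_times=tuple(meta["echo_times_ms"]),
        tr=meta["tr_ms"],
        flip_angle=meta["flip_angle_deg"],
        b0=meta["b0_tesla"],
        noise_sigma=meta["noise_sigma"],
    )
    grid = GridSpec(
        shape=grid.shape,
        voxel_size=grid.voxel_size,
        b0_direction=tuple(meta.get("b0_direction", (0.0, 0.0, 1.0))),
    )
    data = np.moveaxis(mag * np.exp(1j * phase), -1, 0)
    return MultiEchoComplexVolume(grid=grid, acq=acq, data=data)


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    table = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"cohort CSV {path} is missing columns: {missing}")
    return table


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable config dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int, stage: str) -> Path:
    """Run manifest: everything needed to reconstruct the run (plus a
    timestamp, which is informational and excluded from the hash)."""
    path = Path(path)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "versions": {
            "dgmqsm": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "nibabel": nib.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
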