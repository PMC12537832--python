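"""Pipeline configuration: one serializable object driving every stage.

Every stochastic stage derives its seed from the global seed through a
named ``SeedSequence`` spawn, so a config + seed fully determines the run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from dgmqsm.grids import GridSpec
from dgmqsm.recon.params import ReconParams
from dgmqsm.synthetic.cohort import CohortSpec
from dgmqsm.synthetic.signal import AcquisitionParams

_STAGES = ("phantom", "signal", "recon", "cohort", "stats")


@dataclass
class PipelineConfig:
    """Parameter blocks for the full phantom-to-battery pipeline."""

    grid: GridSpec = field(default_factory=GridSpec)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    recon: ReconParams = field(default_factory=ReconParams)
    n_subjects: int = 771
    n_lesions: int = 10
    with_background: bool = False
    n_permutations: int = 10000
    fdr_q: float = 0.05
    seed: int = 0
    output_dir: str = "dgmqsm_out"
    verbosity: int = 1

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        idx = _STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0] % (2**31))

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_subjects=self.n_subjects, seed=self.stage_seed("cohort"))

    def to_dict(self) -> dict:
        """Serializable scientific configuration; runtime-only fields
        (output directory, verbosity) are excluded so that manifests of
        identical runs hash identically."""
        d = asdict(self)
        d.pop("output_dir", None)
        d.pop("verbosity", None)
        d["grid"] = {
            "shape": list(self.grid.shape),
            "voxel_size": list(self.grid.voxel_size),
            "b0_direction": list(self.grid.b0_direction),
        }
        d["acquisition"] = {**asdict(self.acquisition), "echo_times": list(self.acquisition.echo_times)}
        d["recon"] = asdict(self.recon)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid" in d:
            g = d["grid"]
            d["grid"] = GridSpec(
                shape=tuple(g["shape"]),
                voxel_size=tuple(g["voxel_size"]),
                b0_direction=tuple(g.get("b0_direction", (0.0, 0.0, 1.0))),
            )
        if "acquisition" in d:
            a = dict(d["acquisition"])
            a["echo_times"] = tuple(a["echo_times"])
            d["acquisition"] = AcquisitionParams(**a)
        if "recon" in d:
            d["recon"] = ReconParams(**d["recon"])
        return cls(**d)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)
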