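"""Reconstruction parameters shared by the TFI initializer and mTFI."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReconParams:
    """Tunables of the TV-regularized inversion.

    Attributes
    ----------
    lambda_tv : float
        Weight of the edge-masked total-variation penalty, in units of the
        normalized data fidelity (chi in ppm, unit-normalized magnitude
        weights).  The default was fixed once by an L-curve sweep on the
        default noiseless phantom.
    edge_percentile : float
        Percentile of within-mask gradient magnitudes above which voxels are
        treated as anatomical edges and exempted from the TV penalty
        (70 -> ~30% of voxels are edges).
    max_outer_iters, cg_iters : int
        Outer Gauss-Newton / IRLS iterations and inner conjugate-gradient
        iterations per outer step.
    tol : float
        Relative objective-change stopping threshold.
    preconditioner_scale : float
        Two-level right preconditioner: 1 inside the brain mask, this value
        outside, letting strong background sources be represented cheaply.
    tv_epsilon : float
        Smoothing of the l1 gradient norm, in ppm.
    """

    lambda_tv: float = 1e-4
    edge_percentile: float = 70.0
    max_outer_iters: int = 12
    cg_iters: int = 40
    tol: float = 1e-4
    preconditioner_scale: float = 30.0
    tv_epsilon: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_tv <= 0:
            raise ValueError("lambda_tv must be > 0")
        if not 0 < self.edge_percentile < 100:
            raise ValueError("edge_percentile must lie strictly in (0, 100)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_outer_iters < 1 or self.cg_iters < 1:
            raise ValueError("iteration counts must be >= 1")
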