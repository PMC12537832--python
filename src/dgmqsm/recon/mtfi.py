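"""Multi-echo complex total field inversion (mTFI).

Reconstructs the susceptibility map directly from the multi-echo complex
data over the whole field of view, with no separate background-field
removal.  The committed objective is a magnitude-weighted complex-exponential
phase misfit summed over echoes plus an edge-masked TV penalty:

    E(chi, phi0) = sum_j || w_j ( e^{i(phi0 + c_j D*chi)} - e^{i angle(S_j)} ) ||^2
                   + lambda_tv || M_G grad(chi) ||_1

with per-echo weights ``w_j = m e^{-R2* TE_j} |S_j| / max|S|`` (model
magnitude times normalized data magnitude) and ``c_j = 2 pi gamma_bar B0
1e-6 TE_j`` converting ppm to radians at echo j.  Voxels with any zero echo
magnitude carry zero weight.

Minimization alternates blocks from the TFI initializer:

* ``m`` and ``R2*`` are per-voxel refits of the magnitude decay — their own
  least-squares subproblem, independent of ``chi`` (in the phase objective
  they appear only as weights, so refitting them *from* it would be
  degenerate); the refit is idempotent across iterations;
* ``phi0`` has a closed-form per-voxel minimizer (a weighted circular mean),
  which never increases the objective;
* ``chi`` takes a Gauss-Newton step with CG inner solves (IRLS-majorized
  TV), safeguarded by a backtracking line search on the true epsilon-smoothed
  objective.

The logged objective is therefore non-increasing at every outer iteration.
The k = 0 dipole coefficient is zero, so the absolute offset of ``chi`` is
unobservable; the output is referenced to the CSF mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dgmqsm.grids import dipole_kernel
from dgmqsm.recon.fitting import echo_time_weighted_magnitude, fit_signal_model
from dgmqsm.recon.params import ReconParams
from dgmqsm.recon.solvers import (
    conv_kernel,
    gradient,
    divergence,
    irls_weights,
    solve_normal_equations,
    tv_value,
)
from dgmqsm.recon.tfi import total_field_inversion_init
from dgmqsm.recon.weights import gradient_edge_weights
from dgmqsm.synthetic.signal import MultiEchoComplexVolume
from dgmqsm.units import hz_per_ppm


@dataclass
class SusceptibilityMap:
    """Reconstructed susceptibility volume (ppm) with provenance."""

    chi: np.ndarray
    reference_region: str | None
    reference_value: float
    objective_log: list[float] = field(default_factory=list)
    converged: bool = True
    flags: dict = field(default_factory=dict)
    params: ReconParams | None = None


def csf_reference(
    chi: np.ndarray | SusceptibilityMap, csf_mask: np.ndarray
) -> SusceptibilityMap:
    """Subtract the mean susceptibility over the CSF mask.

    Fixes the arbitrary offset of the dipole inversion; the returned map has
    zero mean over ``csf_mask``.
    """
    if not np.any(csf_mask):
        raise ValueError("CSF reference mask is empty")
    if isinstance(chi, SusceptibilityMap):
        ref = float(chi.chi[csf_mask].mean())
        return SusceptibilityMap(
            chi=chi.chi - ref,
            reference_region="csf",
            reference_value=ref,
            objective_log=chi.objective_log,
            converged=chi.converged,
            flags=dict(chi.flags),
            params=chi.params,
        )
    chi = np.asarray(chi, dtype=float)
    ref = float(chi[csf_mask].mean())
    return SusceptibilityMap(chi=chi - ref, reference_region="csf", reference_value=ref)


def _wrap(phase: np.ndarray) -> np.ndarray:
    return np.mod(phase + np.pi, 2.0 * np.pi) - np.pi


def mtfi_reconstruct(
    signal: MultiEchoComplexVolume,
    brain_mask: np.ndarray,
    csf_mask: np.ndarray | None,
    params: ReconParams | None = None,
) -> SusceptibilityMap:
    """Reconstruct a CSF-referenced susceptibility map from complex data.

    Parameters
    ----------
    signal : MultiEchoComplexVolume
        At least three echoes.
    brain_mask : ndarray of bool
        Tissue region; drives the preconditioner and edge-weight percentile.
    csf_mask : ndarray of bool or None
        Reference region.  ``None`` or empty returns an unreferenced map
        with an explicit ``unreferenced`` flag.
    params : ReconParams, optional

    Raises
    ------
    RuntimeError
        If the objective ever increases across an outer iteration
        (divergence), with the diagnostic log attached.
    """
    params = params or ReconParams()
    if signal.acq.n_echoes < 3:
        raise ValueError("mTFI needs >= 3 echoes")
    brain_mask = brain_mask.astype(bool)
    kernel = dipole_kernel(signal.grid)

    # Block 1: magnitude-model parameters (their own LS subproblem).
    fit = fit_signal_model(signal, mask=None)
    etw = echo_time_weighted_magnitude(signal)
    edge_w = gradient_edge_weights(etw, brain_mask, params.edge_percentile)

    # Initializer: total field inversion of the fitted field.
    chi, tfi_log = total_field_inversion_init(
        fit, kernel, params, brain_mask, edge_weights=edge_w, b0=signal.acq.b0
    )
    phi0 = fit.phi0.copy()

    te_s = signal.acq.echo_times_s
    c_j = 2.0 * np.pi * hz_per_ppm(signal.acq.b0) * te_s  # rad per ppm, (J,)
    mag = signal.magnitude
    w_j = (
        fit.magnitude[None]
        * np.exp(-np.outer(te_s, fit.r2star.ravel()).reshape(len(te_s), *fit.r2star.shape))
        * mag
        / float(mag.max())
    )
    w_j *= fit.fit_mask[None]  # zero weight for degenerate voxels
    w2_j = w_j**2
    data_phase = np.angle(signal.data)
    w2c2 = np.tensordot(c_j**2, w2_j, axes=(0, 0))  # sum_j c_j^2 w_j^2

    precond = np.where(brain_mask, 1.0, params.preconditioner_scale)

    def data_misfit(b_ppm: np.ndarray, phi0_: np.ndarray) -> float:
        # |e^{i a} - e^{i b}|^2 = 2 (1 - cos(a - b))
        total = 0.0
        for j in range(len(te_s)):
            d = data_phase[j] - phi0_ - c_j[j] * b_ppm
            total += float(np.sum(w2_j[j] * 2.0 * (1.0 - np.cos(d))))
        return total

    def objective(chi_: np.ndarray, b_ppm: np.ndarray, phi0_: np.ndarray) -> float:
        return data_misfit(b_ppm, phi0_) + params.lambda_tv * tv_value(
            chi_, edge_w, params.tv_epsilon
        )

    b = conv_kernel(chi, kernel)
    log: list[float] = [objective(chi, b, phi0)]
    converged = False

    for _ in range(params.max_outer_iters):
        # Block 2: Gauss-Newton step on chi (solved in y, chi = P y).
        sin_rhs = np.zeros_like(chi)
        for j in range(len(te_s)):
            sin_rhs += c_j[j] * w2_j[j] * np.sin(_wrap(data_phase[j] - phi0 - c_j[j] * b))
        u = irls_weights(chi, edge_w, params.tv_epsilon)
        rhs = precond * conv_kernel(sin_rhs, kernel)
        rhs += params.lambda_tv * precond * divergence(u * gradient(chi))
        dy = solve_normal_equations(
            w2c2, kernel, u, params.lambda_tv, precond, rhs, params.cg_iters
        )
        dchi = precond * dy
        db = conv_kernel(dchi, kernel)

        t, current = 1.0, log[-1]
        accepted = False
        for _ls in range(12):
            cand = objective(chi + t * dchi, b + t * db, phi0)
            if cand < current:
                chi, b = chi + t * dchi, b + t * db
                accepted = True
                break
            t *= 0.5

        # Block 3: closed-form phi0 (weighted circular mean), never increases E.
        acc = np.zeros(chi.shape, dtype=complex)
        for j in range(len(te_s)):
            acc += w2_j[j] * np.exp(1j * (data_phase[j] - c_j[j] * b))
        phi0 = np.where(np.abs(acc) > 0, np.angle(acc), phi0)

        log.append(objective(chi, b, phi0))
        rel = abs(log[-2] - log[-1]) / max(abs(log[-2]), 1e-30)
        if log[-1] > log[-2] + 1e-9 * abs(log[-2]):
            raise RuntimeError(f"mTFI objective increased; diagnostic log: {log}")
        if rel < params.tol:
            converged = True
            break

    result = SusceptibilityMap(
        chi=chi,
        reference_region=None,
        reference_value=0.0,
        objective_log=log,
        converged=converged,
        flags={"tfi": tfi_log},
        params=params,
    )
    if not converged:
        result.flags["warning"] = "stopped at max_outer_iters before tolerance"
    if csf_mask is None or not np.any(csf_mask):
        result.flags["unreferenced"] = True
        return result
    return csf_reference(result, csf_mask)
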