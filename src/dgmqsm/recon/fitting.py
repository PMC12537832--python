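"""Per-voxel signal-model fitting from the multi-echo complex stack.

Provides the initial estimates for the non-convex inversion: spin density
``m`` and effective relaxation ``R2*`` from a log-linear fit to the echo
magnitudes, and field ``f`` (Hz) plus phase offset ``phi0`` from a
magnitude-squared-weighted linear fit to the temporally unwrapped phase.
Temporal unwrapping is greedy nearest-2pi per voxel starting from the first
echo; no spatial unwrapping is performed (the complex-domain fidelity of the
final inversion makes it non-critical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dgmqsm.synthetic.signal import MultiEchoComplexVolume


@dataclass
class FieldModelFit:
    """Voxelwise estimates of the signal model and the fit mask actually
    used (voxels with any zero echo magnitude are flagged and excluded)."""

    magnitude: np.ndarray  # m, a.u.
    r2star: np.ndarray  # 1/s
    phi0: np.ndarray  # rad
    field_hz: np.ndarray  # Hz
    residual: np.ndarray  # RMS complex misfit per voxel, a.u.
    fit_mask: np.ndarray
    excluded_mask: np.ndarray


def echo_time_weighted_magnitude(signal: MultiEchoComplexVolume) -> np.ndarray:
    """Echo-time weighted magnitude ``W = sum_j TE_j |S_j| / sum_j TE_j``.

    Later echoes, whose phase carries most of the susceptibility contrast,
    dominate the weighting; the normalization by ``sum TE_j`` keeps ``W`` on
    the scale of the echo magnitudes.
    """
    te = np.asarray(signal.acq.echo_times, dtype=float)
    mag = signal.magnitude
    return np.tensordot(te, mag, axes=(0, 0)) / te.sum()


def temporal_unwrap(phase: np.ndarray) -> np.ndarray:
    """Greedy nearest-2pi unwrapping along the echo axis (axis 0)."""
    return np.unwrap(phase, axis=0)


def fit_signal_model(
    signal: MultiEchoComplexVolume, mask: np.ndarray | None = None
) -> FieldModelFit:
    """Fit (m, R2*, phi0, f) per voxel inside ``mask``.

    Requires at least three echoes so that the four parameters are
    identifiable from magnitudes (2 d.o.f.) and phases (2 d.o.f.).
    """
    if signal.acq.n_echoes < 3:
        raise ValueError("signal-model fit needs >= 3 echoes")
    shape = signal.grid.shape
    mask = np.ones(shape, dtype=bool) if mask is None else mask.astype(bool)

    mag = signal.magnitude
    excluded = mask & np.any(mag == 0, axis=0)
    fit_mask = mask & ~excluded

    te_s = signal.acq.echo_times_s  # (J,)
    v_mag = mag[:, fit_mask]  # (J, V)
    v_phase = temporal_unwrap(np.angle(signal.data[:, fit_mask]))

    # magnitude: log-linear fit  ln|S_j| = ln m - R2* TE_j
    coeff = np.polynomial.polynomial.polyfit(te_s, np.log(v_mag), 1)
    m_v = np.exp(coeff[0])
    r2_v = np.clip(-coeff[1], 0.0, None)

    # phase: weighted linear fit  phi_j = phi0 + 2 pi f TE_j, weights |S_j|^2
    w = v_mag**2
    sw = w.sum(axis=0)
    t_bar = (w * te_s[:, None]).sum(axis=0) / sw
    p_bar = (w * v_phase).sum(axis=0) / sw
    dt = te_s[:, None] - t_bar
    slope = (w * dt * (v_phase - p_bar)).sum(axis=0) / (w * dt**2).sum(axis=0)
    phi0_v = p_bar - slope * t_bar
    f_v = slope / (2.0 * np.pi)

    model = m_v * np.exp(-np.outer(te_s, r2_v)) * np.exp(
        1j * (phi0_v + slope * te_s[:, None])
    )
    resid_v = np.sqrt(np.mean(np.abs(model - signal.data[:, fit_mask]) ** 2, axis=0))

    def scatter(vals, fill=0.0):
        out = np.full(shape, fill)
        out[fit_mask] = vals
        return out

    return FieldModelFit(
        magnitude=scatter(m_v),
        r2star=scatter(r2_v),
        phi0=scatter(np.mod(phi0_v + np.pi, 2 * np.pi) - np.pi),
        field_hz=scatter(f_v),
        residual=scatter(resid_v),
        fit_mask=fit_mask,
        excluded_mask=excluded,
    )
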