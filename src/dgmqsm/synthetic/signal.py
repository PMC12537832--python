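"""Multi-echo gradient-echo complex signal synthesis.

Per voxel, echo ``j`` of the monopolar multi-echo GRE signal is modelled as

    S_j = m * exp(-R2* TE_j) * exp(i [phi0 + 2 pi gamma_bar B0 f_ppm 1e-6 TE_j])

with ``f`` the dipole field of the phantom susceptibility (plus any
background field) in ppm, ``m`` the effective spin density at TE = 0 and
``phi0`` a transmit/receive phase offset.  Complex Gaussian noise is added
independently per voxel and echo (SENSE-reconstructed data approximated as
white); coil sensitivities and k-space undersampling are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dgmqsm.grids import GridSpec, dipole_kernel, forward_field
from dgmqsm.synthetic.phantom import SusceptibilityPhantom
from dgmqsm.units import DEFAULT_B0_T, hz_per_ppm

#: Default echo train: first TE 6 ms, echo spacing 6.4 ms, six echoes.
DEFAULT_ECHO_TIMES_MS = (6.0, 12.4, 18.8, 25.2, 31.6, 38.0)


@dataclass(frozen=True)
class AcquisitionParams:
    """Multi-echo GRE protocol parameters (times in ms, B0 in Tesla).

    ``noise_sigma`` is the complex Gaussian noise standard deviation per real
    channel, expressed as a fraction of the maximum noiseless magnitude; the
    single-echo SNR at the noiseless maximum is ``1 / noise_sigma``.
    """

    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES_MS
    tr: float = 41.75
    flip_angle: float = 20.0
    b0: float = DEFAULT_B0_T
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or np.any(np.diff(te) <= 0):
            raise ValueError(f"echo_times must be >= 2 strictly increasing values, got {self.echo_times}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.b0 <= 0 or self.tr <= 0:
            raise ValueError("b0 and tr must be positive")

    @property
    def echo_times_s(self) -> np.ndarray:
        return np.asarray(self.echo_times, dtype=float) * 1e-3

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)


@dataclass
class MultiEchoComplexVolume:
    """Complex echo stack ``data`` of shape ``(n_echoes, *grid.shape)``."""

    grid: GridSpec
    acq: AcquisitionParams
    data: np.ndarray

    def __post_init__(self) -> None:
        expected = (self.acq.n_echoes, *self.grid.shape)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != {expected}")
        if not np.iscomplexobj(self.data):
            raise ValueError("data must be complex")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)


def synthesize_background_field(
    grid: GridSpec, brain_mask: np.ndarray, air_chi_ppm: float = 1.5
) -> np.ndarray:
    """Background field (ppm) from air/skull-like susceptibility sources
    outside the brain: a sinus-like sphere below the brain and a slab above.

    Gives the total-field initializer a genuine low-spatial-frequency
    background to absorb; the sources never intersect ``brain_mask``.  The
    default source strength keeps the in-brain field below the temporal
    phase-aliasing limit ``1 / (2 dTE)`` of the default echo train (the
    per-voxel greedy unwrapping has no spatial stage to recover from
    aliasing, mirroring the regime real protocols are designed for).
    """
    x, y, z = grid.coordinates_mm()
    half_z = grid.fov_mm[2] / 2.0
    sources = np.zeros(grid.shape)
    sphere = x**2 + (y + 4.0) ** 2 + (z + (half_z - 3.0)) ** 2 <= 4.0**2
    slab = z > half_z - 2.0
    outside = ~brain_mask
    sources[(sphere | slab) & outside] = air_chi_ppm
    return forward_field(sources, dipole_kernel(grid))


def synthesize_multiecho(
    phantom: SusceptibilityPhantom,
    acq: AcquisitionParams | None = None,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> MultiEchoComplexVolume:
    """Simulate the multi-echo complex GRE stack for a phantom.

    Parameters
    ----------
    phantom : SusceptibilityPhantom
        Supplies chi (ppm), R2* (1/s) and magnitude maps.
    acq : AcquisitionParams, optional
        Protocol; defaults to the 6-echo 3 T protocol.
    background : ndarray, optional
        Additional field in ppm (e.g. from
        :func:`synthesize_background_field`), added to the dipole field.
    seed : int
        Noise seed; the output is bit-identical for a fixed seed.
    """
    acq = acq or AcquisitionParams()
    grid = phantom.grid
    f_ppm = forward_field(phantom.chi, dipole_kernel(grid))
    if background is not None:
        if background.shape != f_ppm.shape:
            raise ValueError("background field shape does not match the grid")
        f_ppm = f_ppm + background
    f_hz = f_ppm * hz_per_ppm(acq.b0)

    te_s = acq.echo_times_s[:, None, None, None]
    m = phantom.magnitude_map[None]
    decay = np.exp(-phantom.r2star_map[None] * te_s)
    phase = 2.0 * np.pi * f_hz[None] * te_s
    # A small fixed transmit/receive phase offset; reconstruction must be
    # invariant to it.
    phi0 = 0.3
    data = m * decay * np.exp(1j * (phi0 + phase))

    if acq.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = acq.noise_sigma * float(np.abs(data).max())
        noise = rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        data = data + scale * noise

    return MultiEchoComplexVolume(grid=grid, acq=acq, data=data)
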