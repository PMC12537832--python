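"""Voxel grid geometry, the k-space dipole kernel and the forward field model.

Conventions (used everywhere in the package):

* axis order is RAS-like ``(x, y, z)`` with 0-based voxel indices;
* the main field B0 points along ``+z`` of the voxel grid by default;
* susceptibility ``chi`` is in ppm and the dipole-induced field shift is
  returned in the same ppm units (Lorentz-sphere corrected).

The unit dipole response in k-space is ``D(k) = 1/3 - (k . b0_hat)^2 / |k|^2``
with the ``k = 0`` coefficient set to zero, i.e. the forward field of any
source distribution has zero spatial mean and the absolute susceptibility
offset is unobservable (hence CSF referencing downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a 3-D acquisition grid.

    Parameters
    ----------
    shape : tuple of int
        Matrix size in voxels, each entry >= 8.
    voxel_size : tuple of float
        Voxel edge lengths in mm, all > 0.
    b0_direction : tuple of float
        Unit vector of the main field in grid coordinates; defaults to +z.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (0.75, 0.75, 0.75)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError(f"grid shape must be a triple with entries >= 8, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        b = np.asarray(self.b0_direction, dtype=float)
        if abs(float(np.linalg.norm(b)) - 1.0) > 1e-9:
            raise ValueError(f"b0_direction must be a unit vector, got {self.b0_direction}")

    @property
    def voxel_volume_mm3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def coordinates_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates (mm) relative to the grid center, sparse."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.shape, self.voxel_size)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)


def dipole_kernel(grid: GridSpec) -> np.ndarray:
    """Unit dipole response on the discrete frequency grid.

    Returns the real k-space kernel ``D(k) = 1/3 - (k.b0_hat)^2/|k|^2`` laid
    out in numpy FFT order, with ``D(0) = 0`` by convention.
    """
    freqs = [
        np.fft.fftfreq(n, d=v) for n, v in zip(grid.shape, grid.voxel_size)
    ]
    kx, ky, kz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    b = np.asarray(grid.b0_direction, dtype=float)
    k_par = kx * b[0] + ky * b[1] + kz * b[2]
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - (k_par**2) / k2
    d[k2 == 0] = 0.0
    return d


def forward_field(chi: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dipole-induced field shift (ppm) of a susceptibility volume (ppm).

    ``field = IFT(D * FT(chi))``; linear in ``chi`` and zero-mean by the
    ``D(0) = 0`` convention.
    """
    chi = np.asarray(chi, dtype=float)
    if chi.shape != kernel.shape:
        raise ValueError(
            f"chi shape {chi.shape} does not match kernel shape {kernel.shape}"
        )
    return np.fft.ifftn(kernel * np.fft.fftn(chi)).real
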