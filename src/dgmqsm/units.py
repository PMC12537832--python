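"""Physical constants and unit conversions used across the pipeline.

All susceptibility values are in ppm, fields are stored in Hz, echo times in
ms, and voxel geometry in mm.  The ppm/Hz conversion is centralized here so
that the forward simulator and the reconstruction cannot drift apart.
"""

GAMMA_BAR_HZ_PER_T = 42.577e6
"""Reduced gyromagnetic ratio of the proton, gamma-bar = gamma / 2pi (Hz/T)."""

DEFAULT_B0_T = 3.0
"""Main field strength (Tesla)."""


def hz_per_ppm(b0: float = DEFAULT_B0_T) -> float:
    """Field offset in Hz produced by a 1 ppm susceptibility-induced shift."""
    return GAMMA_BAR_HZ_PER_T * b0 * 1e-6


def ppm_to_hz(f_ppm, b0: float = DEFAULT_B0_T):
    return f_ppm * hz_per_ppm(b0)


def hz_to_ppm(f_hz, b0: float = DEFAULT_B0_T):
    return f_hz / hz_per_ppm(b0)
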