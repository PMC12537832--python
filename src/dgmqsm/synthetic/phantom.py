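"""Ellipsoidal deep-grey-matter susceptibility phantoms.

The phantom is a miniature "brain": an ellipsoidal brain compartment with a
ventricle-like CSF ellipsoid (chi = 0, the downstream reference region), four
ellipsoidal deep-grey-matter (DGM) structures — thalamus, caudate, putamen,
pallidum — at literature mean susceptibilities, and optional small spherical
white-matter lesions.  Ellipsoids are used instead of anatomical shapes
because their volume is analytic, which makes voxelization testable.

Susceptibility is in ppm relative to brain tissue; CSF and unspecified brain
tissue sit at 0 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dgmqsm.grids import GridSpec


@dataclass(frozen=True)
class StructureSpec:
    """One ellipsoidal structure.

    ``center`` and ``semi_axes`` are in mm relative to the grid center;
    ``chi`` in ppm, ``r2star`` in 1/s, ``magnitude`` in arbitrary units.
    """

    label: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    chi: float
    r2star: float = 25.0
    magnitude: float = 0.9

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"{self.label}: semi-axes must be positive, got {self.semi_axes}")
        if not np.isfinite(self.chi):
            raise ValueError(f"{self.label}: chi must be finite")
        if self.r2star < 0:
            raise ValueError(f"{self.label}: r2star must be >= 0")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


# Mean DGM susceptibilities (ppm) reported for early multiple sclerosis
# cohorts; thalamus slightly diamagnetic, basal ganglia paramagnetic.
DGM_CHI_PPM = {
    "thalamus": -0.008,
    "caudate": 0.042,
    "putamen": 0.050,
    "pallidum": 0.099,
}

# Rough iron-scaled effective relaxation rates (1/s) per structure.
_DGM_R2STAR = {"thalamus": 24.0, "caudate": 30.0, "putamen": 32.0, "pallidum": 48.0}

_BRAIN_SEMI_AXES = (19.0, 19.0, 15.0)
_CSF_CENTER, _CSF_SEMI_AXES = (0.0, 7.0, 3.0), (4.0, 6.0, 3.0)
_DGM_GEOMETRY = {
    "thalamus": ((0.0, -5.0, 0.0), (5.5, 4.5, 4.0)),
    "caudate": ((-9.0, 6.0, 2.0), (3.5, 5.0, 3.0)),
    "putamen": ((9.0, 3.0, 0.0), (3.5, 5.5, 3.5)),
    "pallidum": ((-9.5, -6.0, -2.0), (2.5, 3.5, 2.5)),
}

_TISSUE_R2STAR, _TISSUE_MAG = 18.0, 1.0
_CSF_R2STAR, _CSF_MAG = 2.0, 0.7
_AIR_R2STAR, _AIR_MAG = 120.0, 0.02
_LESION_CHI, _LESION_DR2STAR, _LESION_MAG = 0.02, 6.0, 1.1


def default_dgm_structures() -> list[StructureSpec]:
    """The four DGM ellipsoids at their default susceptibilities."""
    return [
        StructureSpec(
            label=name,
            center=_DGM_GEOMETRY[name][0],
            semi_axes=_DGM_GEOMETRY[name][1],
            chi=DGM_CHI_PPM[name],
            r2star=_DGM_R2STAR[name],
        )
        for name in ("thalamus", "caudate", "putamen", "pallidum")
    ]


@dataclass
class SusceptibilityPhantom:
    """Ground-truth susceptibility volume with labels, masks and NMR maps."""

    grid: GridSpec
    chi: np.ndarray  # ppm
    labels: np.ndarray  # int; 0 = unlabeled
    label_names: dict[int, str]
    brain_mask: np.ndarray
    csf_mask: np.ndarray
    lesion_mask: np.ndarray
    r2star_map: np.ndarray  # 1/s
    magnitude_map: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        shapes = {
            a.shape
            for a in (
                self.chi,
                self.labels,
                self.brain_mask,
                self.csf_mask,
                self.lesion_mask,
                self.r2star_map,
                self.magnitude_map,
            )
        }
        if shapes != {tuple(self.grid.shape)}:
            raise ValueError("phantom volumes must all share the grid shape")
        if np.any((self.labels > 0) & ~self.brain_mask):
            raise ValueError("labeled voxels must lie inside the brain mask")
        if np.any(self.csf_mask & (self.labels > 0)):
            raise ValueError("CSF mask must be disjoint from DGM labels")

    def label_mask(self, name: str) -> np.ndarray:
        for lid, lname in self.label_names.items():
            if lname == name:
                return self.labels == lid
        raise KeyError(f"no label named {name!r}")


def _ellipsoid_mask(grid: GridSpec, center, semi_axes) -> np.ndarray:
    x, y, z = grid.coordinates_mm()
    cx, cy, cz = center
    a, b, c = semi_axes
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def _check_inside_grid(grid: GridSpec, s: StructureSpec) -> None:
    half_fov = [f / 2.0 for f in grid.fov_mm]
    for c, a, h, ax in zip(s.center, s.semi_axes, half_fov, "xyz"):
        if abs(c) + a > h:
            raise ValueError(
                f"structure {s.label!r} extends outside the grid along {ax} "
                f"(|{c}| + {a} > {h} mm)"
            )


def make_dgm_phantom(
    grid: GridSpec | None = None,
    structures: list[StructureSpec] | None = None,
    seed: int = 0,
    n_lesions: int = 10,
) -> SusceptibilityPhantom:
    """Build the default four-structure DGM phantom.

    Parameters
    ----------
    grid : GridSpec, optional
        Defaults to a 64^3 grid at 0.75 mm isotropic.
    structures : list of StructureSpec, optional
        DGM ellipsoids; must be pairwise disjoint after voxelization and fit
        inside the grid.  Defaults to :func:`default_dgm_structures`.
    seed : int
        Drives lesion placement only; the deterministic geometry is fixed.
    n_lesions : int
        Number of spherical white-matter lesions to scatter (may be 0).
    """
    grid = grid or GridSpec()
    if structures is None:
        structures = default_dgm_structures()
    names = [s.label for s in structures]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate structure labels in {names}")

    brain = _ellipsoid_mask(grid, (0.0, 0.0, 0.0), _BRAIN_SEMI_AXES)
    csf = _ellipsoid_mask(grid, _CSF_CENTER, _CSF_SEMI_AXES) & brain

    labels = np.zeros(grid.shape, dtype=np.int32)
    label_names: dict[int, str] = {}
    for lid, s in enumerate(structures, start=1):
        _check_inside_grid(grid, s)
        m = _ellipsoid_mask(grid, s.center, s.semi_axes)
        if not np.all(brain[m]):
            raise ValueError(f"structure {s.label!r} extends outside the brain compartment")
        clash = m & (labels > 0)
        if np.any(clash):
            other = label_names[int(labels[clash][0])]
            raise ValueError(f"structures {s.label!r} and {other!r} overlap")
        if np.any(m & csf):
            raise ValueError(f"structure {s.label!r} overlaps the CSF compartment")
        labels[m] = lid
        label_names[lid] = s.label

    chi = np.zeros(grid.shape)
    r2star = np.full(grid.shape, _AIR_R2STAR)
    magnitude = np.full(grid.shape, _AIR_MAG)
    r2star[brain], magnitude[brain] = _TISSUE_R2STAR, _TISSUE_MAG
    r2star[csf], magnitude[csf] = _CSF_R2STAR, _CSF_MAG
    for lid, s in enumerate(structures, start=1):
        m = labels == lid
        chi[m], r2star[m], magnitude[m] = s.chi, s.r2star, s.magnitude

    lesions = _scatter_lesions(grid, brain, csf, labels, seed, n_lesions)
    chi[lesions] = _LESION_CHI
    r2star[lesions] = _TISSUE_R2STAR + _LESION_DR2STAR
    magnitude[lesions] = _LESION_MAG

    return SusceptibilityPhantom(
        grid=grid,
        chi=chi,
        labels=labels,
        label_names=label_names,
        brain_mask=brain,
        csf_mask=csf,
        lesion_mask=lesions,
        r2star_map=r2star,
        magnitude_map=magnitude,
    )


def _scatter_lesions(grid, brain, csf, labels, seed, n_lesions) -> np.ndarray:
    """Drop spherical lesions into unlabeled brain tissue, rejecting overlap
    with DGM structures and CSF.  Radii span the lesion-volume threshold so
    some default lesions are filtered out downstream."""
    lesions = np.zeros(grid.shape, dtype=bool)
    if n_lesions == 0:
        return lesions
    rng = np.random.default_rng(seed)
    eligible = brain & ~csf & (labels == 0)
    idx = np.argwhere(eligible)
    x, y, z = grid.coordinates_mm()
    placed = 0
    for _ in range(n_lesions * 50):
        if placed >= n_lesions:
            break
        i, j, k = idx[rng.integers(len(idx))]
        r = rng.uniform(1.2, 3.2)
        cx, cy, cz = x[i, 0, 0], y[0, j, 0], z[0, 0, k]
        m = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        if np.any(m & ~eligible) or np.any(m & lesions):
            continue
        lesions |= m
        placed += 1
    return lesions
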