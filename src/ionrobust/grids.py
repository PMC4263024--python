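"""Voxel containers shared by the whole pipeline.

The patient frame is a right-handed Cartesian system with axes
(LR, AP, SI): x grows to the patient's left, y to anterior, z to superior.
Arrays are indexed ``[ix, iy, iz]`` and voxel centers sit at
``origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

AXES = ("LR", "AP", "SI")

#: Relative water-equivalent density assigned to air.  Kept slightly above
#: zero so water-equivalent path lengths through air cavities remain finite
#: and ray tracing never divides by zero.
AIR_DENSITY = 1e-3


class GridError(ValueError):
    """Raised for inconsistent grid geometry or infeasible parameters."""


@dataclass
class DensityGrid:
    """Relative water-equivalent density (water = 1) on a regular voxel grid.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Relative stopping-power values, all >= 0.
    spacing : tuple of float
        Voxel spacing in mm along (LR, AP, SI); strictly positive.
    origin : tuple of float
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axes: tuple[str, str, str] = AXES

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise GridError("density grid must be 3-D")
        if np.any(self.voxels < 0):
            raise GridError("densities must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GridError("spacing must be three positive values")
        self.origin = tuple(float(o) for o in self.origin)
        if sorted(self.axes) != sorted(AXES):
            raise GridError(f"axes must be a permutation of {AXES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (n, 3) of voxel centers, optionally masked."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.origin + idx * np.asarray(self.spacing)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for world points (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (pts - self.origin) / np.asarray(self.spacing)

    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along each axis (mm)."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry.

    Canonical roles: ``ctv``, ``ptv``, ``brainstem``, ``chiasm``,
    ``optic_nerve_ipsi``, ``optic_nerve_contra`` and ``external``.
    """

    grid: DensityGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in list(self.masks):
            self.masks[name] = self._check(name, self.masks[name])

    def _check(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask)
        if mask.shape != self.grid.shape:
            raise GridError(f"mask {name!r} shape {mask.shape} != grid {self.grid.shape}")
        return mask.astype(bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def add(self, name: str, mask: np.ndarray) -> None:
        self.masks[name] = self._check(name, mask)

    def names(self) -> list[str]:
        return list(self.masks)

    def volume_cm3(self, name: str) -> float:
        return int(self.masks[name].sum()) * self.grid.voxel_volume_cm3

    def validate(self) -> None:
        """Check the structural invariants of a planning structure set."""
        if "ctv" in self and "ptv" in self and np.any(self["ctv"] & ~self["ptv"]):
            raise GridError("CTV must be contained in PTV")
        if "external" in self:
            ext = self["external"]
            n_comp = ndimage.label(ext)[1]
            if n_comp != 1:
                raise GridError(f"external contour has {n_comp} connected components")
            for name, mask in self.masks.items():
                if name != "external" and np.any(mask & ~ext):
                    raise GridError(f"structure {name!r} extends outside external")


def _affine(grid: DensityGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def save_density(grid: DensityGrid, path) -> None:
    nib.save(nib.Nifti1Image(grid.voxels.astype(np.float32), _affine(grid)), str(path))


def load_density(path) -> DensityGrid:
    img = nib.load(str(path))
    aff = img.affine
    return DensityGrid(
        voxels=np.asanyarray(img.dataobj, dtype=np.float64),
        spacing=tuple(np.diag(aff)[:3]),
        origin=tuple(aff[:3, 3]),
    )


def save_mask(grid: DensityGrid, mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(grid)), str(path))


def load_mask(grid: DensityGrid, path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.shape != grid.shape:
        raise GridError(f"mask shape {arr.shape} != grid {grid.shape}")
    return arr.astype(bool)
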