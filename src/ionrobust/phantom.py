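"""Synthetic skull-base-like phantoms.

Clinical CTs of skull-base chordoma/chondrosarcoma patients are not
redistributable, so the study runs on generated phantoms that reproduce the
geometric features that drive setup-error sensitivity in that region:

* a soft-tissue "head" bounded by an external contour, air outside it;
* a target (CTV) of clinically representative volume near the center;
* a dense lateral bone slab whose edge crosses the mediolateral entrance
  channel, i.e. a strong bone/soft-tissue interface transverse to
  lateral-opposed beams;
* an air cavity (sinus-like) adjacent to the target;
* an abutting dorsal organ at risk ("brainstem") plus paired lateral organs
  ("optic nerves") and a midline one ("chiasm").

Generation is a pure function of (spec, seed): identical inputs give
bit-identical grids and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import AIR_DENSITY, DensityGrid, GridError, StructureSet


class ParameterError(ValueError):
    """Raised when a phantom specification is invalid or infeasible."""


# ---------------------------------------------------------------------------
# margin expansion


def margin_structure(spacing, lr_mm: float, ap_mm: float, si_mm: float) -> np.ndarray:
    """Boolean structuring element for an anisotropic margin expansion.

    A voxel offset ``o`` (in voxels) is part of the element iff the voxel
    center lies inside the ellipsoid with semi-axes (lr, ap, si) mm, i.e.
    sum((o * spacing / margin)^2) <= 1.  A zero margin collapses that axis:
    only zero offset is allowed along it.
    """
    margins = np.array([lr_mm, ap_mm, si_mm], dtype=float)
    if np.any(margins < 0):
        raise ParameterError("margins must be non-negative")
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(np.where(spacing > 0, margins / spacing, 0)).astype(int)
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    off = np.stack(grids, axis=-1) * spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(margins > 0, off / margins, np.where(off == 0, 0.0, np.inf))
    return (scaled**2).sum(axis=-1) <= 1.0 + 1e-12


def expand_margin(
    mask: np.ndarray, spacing, lr_mm: float, ap_mm: float, si_mm: float
) -> np.ndarray:
    """Anisotropic (ellipsoidal-metric) margin expansion of a binary mask.

    Output contains a voxel iff its center lies within the anisotropic
    distance (semi-axes ``lr_mm``, ``ap_mm``, ``si_mm``) of some input voxel
    center; this is the CTV-to-PTV recipe of 2 mm LR/AP and 2.5-3 mm SI.
    """
    mask = np.asarray(mask, dtype=bool)
    if (lr_mm, ap_mm, si_mm) == (0.0, 0.0, 0.0):
        return mask.copy()
    struct = margin_structure(spacing, lr_mm, ap_mm, si_mm)
    return ndimage.binary_dilation(mask, structure=struct)


def si_margin_for_slices(si_spacing_mm: float) -> float:
    """SI margin tied to slice spacing: 3 mm for 3 mm slices, else 2.5 mm."""
    return 3.0 if si_spacing_mm >= 3.0 else 2.5


def apply_external_override(grid: DensityGrid, external_mask: np.ndarray) -> DensityGrid:
    """Override densities outside the external contour with air."""
    external_mask = np.asarray(external_mask, dtype=bool)
    if external_mask.shape != grid.shape:
        raise GridError("external mask shape does not match grid")
    voxels = np.where(external_mask, grid.voxels, AIR_DENSITY)
    return DensityGrid(voxels, grid.spacing, grid.origin, grid.axes)


# ---------------------------------------------------------------------------
# phantom specification


@dataclass
class PhantomSpec:
    """Parameters of the skull-base-like phantom family.

    Geometry defaults emulate the study conditions: CTV volumes within
    15.6-90.7 cm^3, a bone slab (rel. density ``bone_density``) in the
    lateral entrance channel with its edge near the target midplane, an
    air cavity anterior-inferior to the target, and an abutting dorsal OAR.
    Lengths in mm, densities relative to water.
    """

    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)
    # target: ellipsoid semi-axes; jittered per seed by +-15 %
    ctv_semiaxes_mm: tuple[float, float, float] = (20.0, 19.0, 17.0)
    ctv_volume_range_cm3: tuple[float, float] = (15.6, 90.7)
    size_jitter: float = 0.15
    center_jitter_mm: float = 3.0
    # organs at risk
    oar_abuts: bool = True
    brainstem_radius_mm: float = 8.0
    optic_nerve_radius_mm: float = 2.5
    # heterogeneities
    bone_density: float = 1.6
    bone_slab_thickness_mm: float = 12.0
    bone_slab_si_halfwidth_mm: float = 14.0
    air_cavity_radius_mm: float = 10.0
    air_density: float = AIR_DENSITY
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 4 for n in self.shape):
            raise ParameterError("grid shape must be 3 axes of more than 4 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be positive")
        if any(a <= 0 for a in self.ctv_semiaxes_mm):
            raise ParameterError("target semi-axes must be positive")
        if not 0 <= self.size_jitter < 0.5:
            raise ParameterError("size jitter must be in [0, 0.5)")
        if self.bone_density <= 0 or self.air_density <= 0:
            raise ParameterError("densities must be positive")
        extent = (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        needed = 2 * (1 + self.size_jitter) * np.asarray(self.ctv_semiaxes_mm)
        if np.any(needed > 0.8 * extent):
            raise ParameterError("target does not fit inside the grid")

    @property
    def si_margin_mm(self) -> float:
        return si_margin_for_slices(self.spacing[2])


def _ellipsoid(coords, center, semiaxes) -> np.ndarray:
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _cylinder_z(coords, center_xy, radius, z_lo, z_hi) -> np.ndarray:
    x, y, z = coords
    cx, cy = center_xy
    return ((x - cx) ** 2 + (y - cy) ** 2 <= radius**2) & (z >= z_lo) & (z <= z_hi)


def make_skullbase_phantom(spec: PhantomSpec) -> tuple[DensityGrid, StructureSet]:
    """Generate a heterogeneous skull-base-like phantom.

    Returns the density grid (external override applied) and the structure
    set with masks ``ctv``, ``ptv``, ``brainstem``, ``chiasm``,
    ``optic_nerve_ipsi``, ``optic_nerve_contra`` and ``external``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.shape)
    spacing = np.asarray(spec.spacing)
    extent = (np.asarray(shape) - 1) * spacing

    # world coordinate fields (voxel centers, origin at voxel 0)
    coords = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    center = extent / 2.0

    # --- target -----------------------------------------------------------
    semi = np.asarray(spec.ctv_semiaxes_mm) * (
        1.0 + rng.uniform(-spec.size_jitter, spec.size_jitter, size=3)
    )
    tgt_center = center + rng.uniform(-spec.center_jitter_mm, spec.center_jitter_mm, 3)
    ctv = _ellipsoid(coords, tgt_center, semi)

    grid0 = DensityGrid(np.ones(shape), tuple(spacing))
    vol = int(ctv.sum()) * grid0.voxel_volume_cm3
    lo, hi = spec.ctv_volume_range_cm3
    if not lo <= vol <= hi:
        raise ParameterError(
            f"CTV volume {vol:.1f} cm^3 outside configured range [{lo}, {hi}]"
        )

    ptv = expand_margin(ctv, spacing, 2.0, 2.0, spec.si_margin_mm)

    # --- external contour: head ellipsoid ---------------------------------
    head = _ellipsoid(coords, center, 0.47 * extent)

    # --- density ----------------------------------------------------------
    density = np.ones(shape)

    # lateral bone slab on the patient-left entrance channel; its AP edge
    # sits at the target midplane so LR rays to the dorsal target half cross
    # bone while ventral rays do not (the interface failure mode).  The slab
    # is limited in SI so cranially tilted beams can avoid it.
    slab_outer_x = tgt_center[0] + semi[0] + 6.0
    slab = (
        (coords[0] >= slab_outer_x)
        & (coords[0] <= slab_outer_x + spec.bone_slab_thickness_mm)
        & (coords[1] <= tgt_center[1] + rng.uniform(-2.0, 2.0))
        & (np.abs(coords[2] - tgt_center[2]) <= spec.bone_slab_si_halfwidth_mm)
    )
    density[slab] = spec.bone_density

    # sinus-like air cavity, anterior-inferior to the target
    cavity_center = tgt_center + np.array(
        [
            rng.uniform(-4.0, 4.0),
            semi[1] + spec.air_cavity_radius_mm + 2.0,
            -(semi[2] * 0.5 + rng.uniform(0.0, 4.0)),
        ]
    )
    cavity = _ellipsoid(coords, cavity_center, np.full(3, spec.air_cavity_radius_mm))
    density[cavity] = spec.air_density

    # target and OAR volumes are soft tissue
    density[ptv] = 1.0

    # --- organs at risk ----------------------------------------------------
    # dorsal brainstem: SI cylinder overlapping the PTV, then clipped so it
    # abuts (shares a face with) the PTV without overlap.
    bs_y = tgt_center[1] - semi[1] - (0.0 if spec.oar_abuts else 6.0)
    brainstem = _cylinder_z(
        coords,
        (tgt_center[0], bs_y - spec.brainstem_radius_mm + 2.0),
        spec.brainstem_radius_mm,
        tgt_center[2] - 2.5 * semi[2],
        tgt_center[2] + 1.2 * semi[2],
    )
    brainstem &= ~ptv

    # paired optic nerves: AP-oriented cylinders anterior-superior
    nerve_z = tgt_center[2] + semi[2] * 0.6
    nerve_y_lo = tgt_center[1] + semi[1] * 0.4
    nerves = {}
    for name, side in (("optic_nerve_ipsi", +1.0), ("optic_nerve_contra", -1.0)):
        nx = tgt_center[0] + side * (semi[0] * 0.7 + 4.0)
        m = (
            ((coords[0] - nx) ** 2 + (coords[2] - nerve_z) ** 2
             <= spec.optic_nerve_radius_mm**2)
            & (coords[1] >= nerve_y_lo)
            & (coords[1] <= nerve_y_lo + 22.0)
        )
        nerves[name] = m & ~ptv

    chiasm = (
        (np.abs(coords[0] - tgt_center[0]) <= 6.0)
        & (np.abs(coords[1] - (nerve_y_lo + 3.0)) <= 3.0)
        & (np.abs(coords[2] - nerve_z) <= 3.0)
    ) & ~ptv

    grid = apply_external_override(
        DensityGrid(density, tuple(spacing)), head
    )
    structures = StructureSet(grid)
    structures.add("external", head)
    structures.add("ctv", ctv & head)
    structures.add("ptv", ptv & head)
    structures.add("brainstem", brainstem & head)
    structures.add("chiasm", chiasm & head)
    for name, m in nerves.items():
        structures.add(name, m & head)
    structures.validate()
    return grid, structures


def make_water_phantom(
    shape=(60, 60, 60),
    spacing=(1.0, 1.0, 1.0),
    ctv_side_mm: float | None = None,
    with_oar: bool = False,
) -> tuple[DensityGrid, StructureSet]:
    """Uniform water phantom with a centered cubic CTV (benchmark fixture).

    With ``with_oar`` a brainstem-like box is added abutting the PTV on the
    dorsal (-AP) side.  External is the full grid.
    """
    shape = tuple(int(n) for n in shape)
    if any(n <= 0 for n in shape) or any(s <= 0 for s in spacing):
        raise ParameterError("shape and spacing must be positive")
    spacing = tuple(float(s) for s in spacing)
    extent = (np.asarray(shape) - 1) * np.asarray(spacing)
    if ctv_side_mm is None:
        ctv_side_mm = float(min(extent)) / 3.0
    if ctv_side_mm <= 0 or ctv_side_mm > 0.8 * min(extent):
        raise ParameterError("CTV side infeasible for this grid")

    grid = DensityGrid(np.ones(shape), spacing)
    coords = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    center = extent / 2.0
    half = ctv_side_mm / 2.0
    ctv = np.logical_and.reduce(
        [np.abs(c - m) <= half for c, m in zip(coords, center)]
    )
    ptv = expand_margin(ctv, spacing, 2.0, 2.0, si_margin_for_slices(spacing[2]))

    structures = StructureSet(grid)
    structures.add("external", np.ones(shape, dtype=bool))
    structures.add("ctv", ctv)
    structures.add("ptv", ptv)
    if with_oar:
        ys = np.where(ptv.any(axis=(0, 2)))[0]
        y_lo = int(ys.min())  # PTV dorsal face
        oar = np.zeros(shape, dtype=bool)
        xs = np.where(ptv.any(axis=(1, 2)))[0]
        zs = np.where(ptv.any(axis=(0, 1)))[0]
        oar[
            xs.min() : xs.max() + 1,
            max(0, y_lo - int(round(10.0 / spacing[1]))) : y_lo,
            zs.min() : zs.max() + 1,
        ] = True
        structures.add("brainstem", oar)
    structures.validate()
    return grid, structures
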