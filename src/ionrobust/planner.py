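"""Inverse optimization of spot weights (SFUD and IMPT style).

Three optimization modes mirror clinical practice with scanned beams:

* ``uc`` — unconstrained: all fields' weights optimized jointly on target
  objectives only (no OAR terms);
* ``mc`` — multiple-field modulation (IMPT): joint optimization of all
  fields with OAR maximum-dose terms;
* ``sc`` — single-field modulation (SFUD): each field optimized separately
  to a uniform ``prescription / n_fields`` target dose with proportionally
  scaled OAR limits, then summed.

The objective is quadratic: a two-sided PTV under/overdose term plus
one-sided OAR overdose terms (near-max constraints exclude the allowed
hottest volume fraction), all on RBE-weighted dose normalized by the
prescription.  It is zero iff every objective is met exactly.  Minimization
uses bounded quasi-Newton (L-BFGS-B) with an exact non-negativity bound,
uniform initialization at the weight giving mean PTV dose equal to
prescription, and a fixed iteration/tolerance stop, so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt
from scipy import sparse

from . import dose_engine as de
from .grids import DensityGrid, StructureSet

MAX_ITER = 500
FTOL = 1e-9


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class Prescription:
    """Prescribed RBE-weighted dose and coverage objectives."""

    dose_gyrbe: float
    fractions: int
    ptv_v95_pct: float = 95.0
    ctv_v95_pct: float = 98.0

    def __post_init__(self) -> None:
        if self.dose_gyrbe <= 0:
            raise PlanningError("prescription dose must be positive")
        if self.fractions < 1:
            raise PlanningError("fraction count must be >= 1")


@dataclass(frozen=True)
class OARConstraint:
    """Maximum-dose constraint for one structure.

    ``volume_fraction`` > 0 turns the limit into a near-max constraint: that
    fraction of the structure (e.g. the 1 % abutting surface) may exceed
    ``limit_gyrbe``, but never ``surface_limit_gyrbe``.
    """

    structure: str
    limit_gyrbe: float
    volume_fraction: float = 0.0
    surface_limit_gyrbe: float | None = None

    def __post_init__(self) -> None:
        if self.limit_gyrbe <= 0:
            raise PlanningError("OAR limit must be positive")
        if not 0.0 <= self.volume_fraction < 1.0:
            raise PlanningError("volume fraction must be in [0, 1)")


def default_constraints(species: str) -> list[OARConstraint]:
    """Clinical skull-base OAR limits: optic structures at Dmax, brainstem
    near-max with a relaxed abutting-surface limit (carbon 54/60 Gy(RBE),
    proton 60/63 Gy(RBE))."""
    if species == "carbon":
        dmax, surface = 54.0, 60.0
    elif species == "proton":
        dmax, surface = 60.0, 63.0
    else:
        raise PlanningError(f"unknown species {species!r}")
    return [
        OARConstraint("brainstem", dmax, volume_fraction=0.01,
                      surface_limit_gyrbe=surface),
        OARConstraint("chiasm", dmax),
        OARConstraint("optic_nerve_ipsi", dmax),
        OARConstraint("optic_nerve_contra", dmax),
    ]


@dataclass
class Field:
    """One beam with its raster spots and (after optimization) weights."""

    beam: de.BeamSetup
    spots: list[de.PencilBeamSpot]
    weights: np.ndarray | None = None


@dataclass
class Plan:
    fields: list[Field]
    prescription: Prescription
    constraints: list[OARConstraint]
    mode: str
    species: str
    converged: bool = True
    objective: float = float("nan")

    def all_weights(self) -> np.ndarray:
        return np.concatenate([f.weights for f in self.fields])


# ---------------------------------------------------------------------------
# objective


@dataclass
class PenaltyWeights:
    """Relative importance of the objective terms (dimensionless)."""

    ptv: float = 1.0
    oar: float = 40.0
    normal: float = 0.05  # conformality shoulder outside the PTV


def objective_value(
    dose: np.ndarray,
    ptv_sel: np.ndarray,
    prescription: Prescription,
    oar_terms: list[tuple[np.ndarray, float, float]],
    weights_penalty: float = 0.0,
    penalties: PenaltyWeights | None = None,
    normal_sel: np.ndarray | None = None,
) -> float:
    """Quadratic planning objective on a flat dose vector.

    ``oar_terms`` is a list of (selector, limit, volume_fraction).  The value
    is zero iff the PTV is exactly at prescription, every OAR respects its
    limit and no weight penalty applies.
    """
    pw = penalties or PenaltyWeights()
    p = prescription.dose_gyrbe
    val = pw.ptv * float(np.mean(((dose[ptv_sel] - p) / p) ** 2))
    for sel, limit, vol_frac in oar_terms:
        excess = np.maximum(dose[sel] - limit, 0.0) / p
        if vol_frac > 0.0 and excess.size:
            n_allow = int(np.floor(vol_frac * excess.size))
            if n_allow:
                excess = np.sort(excess)[: excess.size - n_allow]
        val += pw.oar * float(np.mean(excess**2)) if excess.size else 0.0
    if normal_sel is not None and normal_sel.any():
        spill = np.maximum(dose[normal_sel] - p, 0.0) / p
        val += pw.normal * float(np.mean(spill**2))
    return val + weights_penalty


def _objective_and_grad(w, A, ptv_sel, p, oar_terms, pw, normal_sel, ridge):
    dose = A @ w
    resid = np.zeros_like(dose)
    r_ptv = (dose[ptv_sel] - p) / p
    val = pw.ptv * float(np.mean(r_ptv**2))
    resid[ptv_sel] += pw.ptv * 2.0 * r_ptv / (p * r_ptv.size)
    for sel, limit, vol_frac in oar_terms:
        excess = np.maximum(dose[sel] - limit, 0.0) / p
        active = dose[sel] > limit
        if vol_frac > 0.0 and excess.size:
            n_allow = int(np.floor(vol_frac * excess.size))
            if n_allow:
                # exclude the allowed hottest fraction from the penalty
                order = np.argsort(dose[sel])
                keep = np.ones(excess.size, dtype=bool)
                keep[order[excess.size - n_allow:]] = False
                active = active & keep
                excess = excess[keep]
        if excess.size:
            val += pw.oar * float(np.mean(excess**2))
            sub = np.zeros(int(sel.sum()))
            sub[active] = (
                pw.oar * 2.0 * (dose[sel][active] - limit) / (p**2 * excess.size)
            )
            resid[sel] += sub
    if normal_sel is not None and normal_sel.any():
        spill = np.maximum(dose[normal_sel] - p, 0.0) / p
        val += pw.normal * float(np.mean(spill**2))
        resid[normal_sel] += pw.normal * 2.0 * np.maximum(
            dose[normal_sel] - p, 0.0
        ) / (p**2 * spill.size)
    grad = A.T @ resid
    if ridge > 0.0:
        val += ridge * float(w @ w)
        grad = grad + 2.0 * ridge * w
    return val, grad


# ---------------------------------------------------------------------------
# influence matrix


def _normal_shell(structures: StructureSet, margin_vox: int = 4) -> np.ndarray:
    from scipy import ndimage

    ptv = structures["ptv"]
    shell = ndimage.binary_dilation(ptv, iterations=margin_vox) & ~ptv
    if "external" in structures:
        shell &= structures["external"]
    return shell


def influence_matrix(
    grid: DensityGrid,
    fields: list[Field],
    points: np.ndarray,
    wepl_cache: dict | None = None,
) -> sparse.csr_matrix:
    """Sparse RBE-weighted dose-influence matrix (points x all spots)."""
    blocks = []
    for f in fields:
        key = tuple(f.beam.direction)
        wv = None if wepl_cache is None else wepl_cache.get(key)
        if wv is not None:
            idx = np.round((points - np.asarray(grid.origin)) /
                           np.asarray(grid.spacing)).astype(int)
            wepl_pts = wv[idx[:, 0], idx[:, 1], idx[:, 2]]
        else:
            wepl_pts = de.wepl_points(grid, f.beam.direction, points)
        blocks.append(
            de.spot_dose_at_points(
                grid, f.beam, f.spots, points, wepl_at_points=wepl_pts, weighted=True
            )
        )
    return sparse.hstack(blocks, format="csr")


# ---------------------------------------------------------------------------
# optimization


def _solve(A, ptv_sel, prescription, oar_terms, pw, normal_sel, ridge):
    p = prescription.dose_gyrbe
    mean_ptv = np.asarray(A[ptv_sel].sum(axis=0)).ravel().sum() / max(
        int(ptv_sel.sum()), 1
    )
    if mean_ptv <= 0:
        raise PlanningError("spots deposit no dose in the PTV")
    w0 = np.full(A.shape[1], p / mean_ptv)
    res = sciopt.minimize(
        _objective_and_grad,
        w0,
        args=(A, ptv_sel, p, oar_terms, pw, normal_sel, ridge),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * A.shape[1],
        options={"maxiter": MAX_ITER, "ftol": FTOL, "maxcor": 20},
    )
    return np.maximum(res.x, 0.0), bool(res.success), float(res.fun)


def optimize(
    fields: list[Field],
    grid: DensityGrid,
    structures: StructureSet,
    prescription: Prescription,
    constraints: list[OARConstraint],
    mode: str,
    penalties: PenaltyWeights | None = None,
    ridge: float = 0.0,
    wepl_cache: dict | None = None,
) -> Plan:
    """Optimize spot weights under the requested modulation mode.

    Returns a :class:`Plan` with non-negative weights written back into the
    fields.  Infeasible constraint sets are not an error: the optimizer
    returns the best compromise (coverage traded against OAR sparing), as a
    clinical system would.
    """
    if mode not in ("uc", "sc", "mc"):
        raise PlanningError(f"unknown optimization mode {mode!r}")
    species = fields[0].beam.species
    if any(f.beam.species != species for f in fields):
        raise PlanningError("all fields must share one species")
    pw = penalties or PenaltyWeights()

    active = [] if mode == "uc" else [
        c for c in constraints
        if c.structure in structures and structures[c.structure].any()
    ]

    # relevant voxels: PTV + constrained OARs + a conformality shell
    ptv = structures["ptv"]
    normal = _normal_shell(structures)
    sel_masks = [ptv, normal] + [structures[c.structure] for c in active]
    union = np.zeros(grid.shape, dtype=bool)
    for m in sel_masks:
        union |= m
    points = grid.voxel_centers(union)
    flat_union = np.flatnonzero(union)

    def flat_sel(mask):
        return np.isin(flat_union, np.flatnonzero(mask))

    ptv_sel = flat_sel(ptv)
    normal_sel = flat_sel(normal)

    def oar_terms_for(scale: float):
        terms = []
        for c in active:
            sel = flat_sel(structures[c.structure])
            terms.append((sel, c.limit_gyrbe * scale, 0.0))
            if c.volume_fraction > 0.0 and c.surface_limit_gyrbe is not None:
                # near-max: allow the hottest fraction up to the surface limit
                terms[-1] = (sel, c.limit_gyrbe * scale, c.volume_fraction)
                terms.append((sel, c.surface_limit_gyrbe * scale, 0.0))
        return terms

    converged = True
    objective = 0.0
    if mode in ("uc", "mc"):
        A = influence_matrix(grid, fields, points, wepl_cache)
        w, ok, objective = _solve(
            A, ptv_sel, prescription, oar_terms_for(1.0), pw, normal_sel, ridge
        )
        converged = ok
        i0 = 0
        for f in fields:
            f.weights = w[i0 : i0 + len(f.spots)]
            i0 += len(f.spots)
    else:  # sc: each field separately to a uniform fraction of the dose
        frac = 1.0 / len(fields)
        sub_rx = Prescription(
            prescription.dose_gyrbe * frac,
            prescription.fractions,
            prescription.ptv_v95_pct,
            prescription.ctv_v95_pct,
        )
        for f in fields:
            A = influence_matrix(grid, [f], points, wepl_cache)
            w, ok, obj = _solve(
                A, ptv_sel, sub_rx, oar_terms_for(frac), pw, normal_sel, ridge
            )
            converged &= ok
            objective += obj
            f.weights = w
    for f in fields:
        for s, wgt in zip(f.spots, f.weights):
            s.weight = float(wgt)
    return Plan(fields, prescription, constraints, mode, species,
                converged, objective)


def plan_dose(
    plan: Plan, grid: DensityGrid, wepl_cache: dict | None = None
) -> de.DoseGrid:
    """Total plan dose (absorbed and RBE-weighted) on the full grid."""
    total_abs = np.zeros(grid.shape)
    total_w = np.zeros(grid.shape)
    for f in plan.fields:
        key = tuple(f.beam.direction)
        wv = None if wepl_cache is None else wepl_cache.get(key)
        d = de.compute_dose(grid, f.beam, f.spots, f.weights, wepl_vol=wv)
        total_abs += d.absorbed
        if plan.species == "carbon":
            total_w += d.weighted
    if plan.species != "carbon":
        total_w = de.PROTON_RBE * total_abs
    return de.DoseGrid(total_abs, total_w, grid.spacing, grid.origin)


def dose_modulation(
    dose: np.ndarray, oar_masks: dict[str, np.ndarray], prescription: Prescription
) -> float:
    """Ratio of the maximum dose over all constrained OAR voxels to the
    prescription dose (the 'dose modulation' of constrained plans)."""
    masks = [m for m in oar_masks.values() if np.asarray(m).any()]
    if not masks:
        raise PlanningError("no OAR voxels defined")
    peak = max(float(np.asarray(dose)[np.asarray(m, dtype=bool)].max()) for m in masks)
    return peak / prescription.dose_gyrbe
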