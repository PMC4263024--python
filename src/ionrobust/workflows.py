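"""End-to-end study steps shared by the analysis scripts, the pipeline and
the acceptance checks: build a case, plan it, run the shift battery, and the
population comparison between lateral-opposed (LR) and heterogeneity-
minimizing (ROB) beam setups."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import beam_selection as bs
from . import dose_engine as de
from . import metrics as mx
from . import planner as pl
from . import robustness as rb
from .grids import DensityGrid, StructureSet
from .phantom import PhantomSpec, make_skullbase_phantom, make_water_phantom


def default_prescription(species: str) -> pl.Prescription:
    """Study prescriptions: carbon 60 Gy(RBE)/20 fx, proton 66 Gy(RBE)/33 fx."""
    if species == "carbon":
        return pl.Prescription(60.0, 20)
    if species == "proton":
        return pl.Prescription(66.0, 33)
    raise pl.PlanningError(f"unknown species {species!r}")


def lateral_opposed_beams(species: str, **kwargs) -> list[de.BeamSetup]:
    """Two lateral-opposed fields along the LR axis."""
    return [
        de.BeamSetup((1.0, 0.0, 0.0), species, **kwargs),
        de.BeamSetup((-1.0, 0.0, 0.0), species, **kwargs),
    ]


@dataclass
class PlannedCase:
    """A planned case ready for the shift battery."""

    grid: DensityGrid
    structures: StructureSet
    plan: pl.Plan
    dose: de.DoseGrid
    indices: mx.IndexSet
    wepl_cache: dict = field(default_factory=dict)


def build_case(
    grid: DensityGrid,
    structures: StructureSet,
    beams: list[de.BeamSetup],
    mode: str,
    prescription: pl.Prescription | None = None,
    constraints: list[pl.OARConstraint] | None = None,
    penalties: pl.PenaltyWeights | None = None,
) -> PlannedCase:
    """Place spots, optimize weights and evaluate the planned indices."""
    species = beams[0].species
    rx = prescription or default_prescription(species)
    if constraints is None:
        constraints = pl.default_constraints(species)
    cache = {
        tuple(b.direction): de.wepl_volume(grid, b.direction) for b in beams
    }
    fields = [
        pl.Field(b, de.place_spots(structures["ptv"], grid, b,
                                   wepl_vol=cache[tuple(b.direction)]))
        for b in beams
    ]
    plan = pl.optimize(fields, grid, structures, rx, constraints, mode,
                       penalties=penalties, wepl_cache=cache)
    dose = pl.plan_dose(plan, grid, wepl_cache=cache)
    indices = mx.compute_indices(dose.weighted, structures, rx.dose_gyrbe)
    return PlannedCase(grid, structures, plan, dose, indices, cache)


def shift_battery(
    case: PlannedCase, shifts: list[rb.ShiftVector]
) -> list[rb.DeltaRecord]:
    """Recompute the plan under every shift and return the Δ records."""
    rx = case.plan.prescription.dose_gyrbe
    records = []
    for s in shifts:
        dose = rb.recompute_with_shift(
            case.grid, case.structures, case.plan, s, wepl_cache=case.wepl_cache
        )
        idx = mx.compute_indices(dose.weighted, case.structures, rx)
        records.append(rb.delta_indices(case.indices, idx, s))
    return records


def water_benchmark_case(
    species: str,
    mode: str,
    with_oar: bool = False,
    shape=(56, 56, 56),
    spacing=(2.0, 2.0, 2.0),
    ctv_side_mm: float = 24.0,
) -> PlannedCase:
    """Opposed-beam plan on a water phantom (planning-attainability check)."""
    grid, structures = make_water_phantom(shape, spacing, ctv_side_mm, with_oar)
    return build_case(grid, structures, lateral_opposed_beams(species), mode)


def transverse_2mm_shifts() -> list[rb.ShiftVector]:
    """The 2 mm members of the shift set transverse to the LR beam axis."""
    return [s for s in rb.enumerate_shifts([2.0]) if s.x == 0.0]


def study_phantom_spec(seed: int) -> PhantomSpec:
    """Phantom family used by the population studies (one case per seed)."""
    return PhantomSpec(
        shape=(52, 52, 44),
        spacing=(2.5, 2.5, 2.5),
        ctv_semiaxes_mm=(19.0, 18.0, 16.0),
        size_jitter=0.1,
        seed=seed,
    )


def setup_comparison_case(
    seed: int,
    species: str,
    mode: str = "mc",
    candidate_step_deg: float = 15.0,
    score_step_mm: float = 2.0,
    shifts: list[rb.ShiftVector] | None = None,
    spec: PhantomSpec | None = None,
) -> pd.DataFrame:
    """LR vs ROB shift battery for one seeded heterogeneous phantom.

    Returns a tidy frame (case, species, setup, shift label, ΔV95 etc.).
    The ROB setup is chosen by heterogeneity scoring over the default
    candidate fan at ``candidate_step_deg`` resolution.
    """
    spec = spec or study_phantom_spec(seed)
    grid, structures = make_skullbase_phantom(spec)
    if shifts is None:
        shifts = transverse_2mm_shifts()

    setups: dict[str, list[de.BeamSetup]] = {
        "LR": lateral_opposed_beams(species)
    }
    cands = bs.candidate_grid(
        yaw_step_deg=candidate_step_deg, inclination_step_deg=candidate_step_deg
    )
    chosen = bs.select_robust_setup(
        grid, structures["ctv"], cands, step_mm=score_step_mm
    )
    setups["ROB"] = [de.BeamSetup(c.direction, species) for c in chosen]

    rows = []
    for setup_name, beams in setups.items():
        case = build_case(grid, structures, beams, mode)
        for rec in shift_battery(case, shifts):
            row = {
                "case": seed,
                "species": species,
                "setup": setup_name,
                "shift": rec.shift.label,
                "planned_ptv_v95": case.indices.ptv_v95,
                "planned_ctv_v95": case.indices.ctv_v95,
            }
            row.update(rec.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def setup_comparison_study(
    seeds, species_list=("carbon", "proton"), **kwargs
) -> pd.DataFrame:
    """Population LR-vs-ROB comparison over seeded phantoms."""
    frames = [
        setup_comparison_case(seed, species, **kwargs)
        for seed in seeds
        for species in species_list
    ]
    return pd.concat(frames, ignore_index=True)


def median_abs_dv95(study: pd.DataFrame) -> pd.DataFrame:
    """Median |ΔV95%| (CTV) per species and beam setup."""
    out = (
        study.assign(abs_dv95=study["d_ctv_v95"].abs())
        .groupby(["species", "setup"])["abs_dv95"]
        .median()
        .reset_index()
    )
    return out
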