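"""Quantitative robust beam-direction selection.

Clinically, robust setups for skull-base targets are chosen by inspecting
candidate entrance channels and avoiding strong density interfaces.  Here
that visual selection is operationalized: a candidate direction is scored by
how much the water-equivalent path length (WEPL) to each target voxel
changes under small transverse probe shifts of the field.  In a laterally
homogeneous medium the score is zero; a bone/air edge crossing the entrance
channel produces a large score.

Scores are computed on the *water-excess* WEPL (WEPL minus the unit-density
geometric path inside the grid), so that a uniform water block scores
exactly zero for every incidence angle — the spread then measures genuine
density structure, not entry-face obliquity.

Candidate geometry follows the clinical degrees of freedom: isocentric couch
yaw tilting a lateral beam toward cranial, combined with inclination about
the longitudinal (SI) axis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import dose_engine as de
from .grids import DensityGrid, GridError
from .robustness import enumerate_shifts


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateDirection:
    """Candidate field direction from couch yaw and beam inclination.

    ``side`` is +1 for entry from the patient's left, -1 from the right;
    ``yaw_deg`` tilts the beam toward cranial (it then travels inferiorly),
    ``inclination_deg`` rotates about the SI axis toward anterior.
    """

    yaw_deg: float
    inclination_deg: float
    side: int = 1
    feasible: bool = True

    @property
    def direction(self) -> tuple[float, float, float]:
        yaw = np.radians(self.yaw_deg)
        inc = np.radians(self.inclination_deg)
        d = np.array(
            [
                self.side * np.cos(yaw) * np.cos(inc),
                np.cos(yaw) * np.sin(inc),
                -np.sin(yaw),
            ]
        )
        return tuple(d / np.linalg.norm(d))


def candidate_grid(
    yaw_max_deg: float = 60.0,
    yaw_step_deg: float = 5.0,
    inclination_max_deg: float = 45.0,
    inclination_step_deg: float = 5.0,
    sides=(1, -1),
) -> list[CandidateDirection]:
    """Default candidate fan: yaw 0..yaw_max cranial x inclination
    -max..+max, on both lateral sides, in enumeration order."""
    yaws = np.arange(0.0, yaw_max_deg + 1e-9, yaw_step_deg)
    incs = np.arange(-inclination_max_deg, inclination_max_deg + 1e-9,
                     inclination_step_deg)
    return [
        CandidateDirection(float(y), float(i), side=s)
        for s in sides
        for y in yaws
        for i in incs
    ]


def _default_probes(direction: np.ndarray) -> list[np.ndarray]:
    """Transverse components of the 1 mm shift-set members (deduplicated)."""
    d = np.asarray(direction)
    probes: list[np.ndarray] = [np.zeros(3)]
    for s in enumerate_shifts([1.0]):
        vec = s.as_array()
        t = vec - (vec @ d) * d
        if np.linalg.norm(t) < 1e-9:
            continue
        if any(np.allclose(t, q, atol=1e-9) for q in probes):
            continue
        probes.append(t)
    return probes


def heterogeneity_score(
    grid: DensityGrid,
    target_mask: np.ndarray,
    direction,
    probe_shifts=None,
    step_mm: float = de.RAY_STEP_MM,
    aggregate: str = "mean",
) -> float:
    """Mean (or max) over target voxels of the spread of water-excess WEPL
    across transverse probe shifts of the field; >= 0, zero for laterally
    homogeneous media."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if probe_shifts is None:
        probes = _default_probes(d)
    else:
        probes = [np.zeros(3)] + [np.asarray(p, dtype=float) for p in probe_shifts]
    centers = grid.voxel_centers(np.asarray(target_mask, dtype=bool))
    if centers.size == 0:
        raise SelectionError("target mask is empty")

    water = DensityGrid(np.ones(grid.shape), grid.spacing, grid.origin)
    vals = []
    for p in probes:
        pts = centers + p
        try:
            w = de.wepl_points(grid, d, pts, step_mm=step_mm)
            w0 = de.wepl_points(water, d, pts, step_mm=step_mm)
        except GridError as exc:
            raise SelectionError(
                "probed target points leave the grid along this direction"
            ) from exc
        vals.append(w - w0)
    stack = np.stack(vals)  # (n_probes, n_voxels)
    spread = stack.max(axis=0) - stack.min(axis=0)
    if aggregate == "mean":
        return float(spread.mean())
    if aggregate == "max":
        return float(spread.max())
    raise SelectionError(f"unknown aggregation {aggregate!r}")


def angular_separation_deg(a: CandidateDirection, b: CandidateDirection) -> float:
    da = np.asarray(a.direction)
    db = np.asarray(b.direction)
    return float(np.degrees(np.arccos(np.clip(da @ db, -1.0, 1.0))))


def select_robust_setup(
    grid: DensityGrid,
    target_mask: np.ndarray,
    candidates: list[CandidateDirection],
    n_beams: int = 2,
    min_separation_deg: float = 30.0,
    scores: list[float] | None = None,
    step_mm: float = de.RAY_STEP_MM,
) -> list[CandidateDirection]:
    """Pick the ``n_beams`` feasible candidates minimizing the total
    heterogeneity score, subject to a pairwise minimum angular separation.

    Exhaustive over combinations; ties broken deterministically by candidate
    enumeration order.  Precomputed ``scores`` (aligned with ``candidates``)
    may be supplied to avoid re-tracing.
    """
    feasible = [(i, c) for i, c in enumerate(candidates) if c.feasible]
    if len(feasible) < n_beams:
        raise SelectionError(
            f"need at least {n_beams} feasible candidates, have {len(feasible)}"
        )
    if scores is None:
        scores = [np.nan] * len(candidates)
        for i, c in feasible:
            scores[i] = heterogeneity_score(
                grid, target_mask, c.direction, step_mm=step_mm
            )
    best = None
    for combo in itertools.combinations(feasible, n_beams):
        if any(
            angular_separation_deg(a[1], b[1]) < min_separation_deg
            for a, b in itertools.combinations(combo, 2)
        ):
            continue
        total = sum(scores[i] for i, _ in combo)
        key = (total, tuple(i for i, _ in combo))
        if best is None or key < best[0]:
            best = (key, combo)
    if best is None:
        raise SelectionError("no candidate pair satisfies the separation constraint")
    return [c for _, c in best[1]]
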