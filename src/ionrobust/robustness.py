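"""Setup-error robustness battery.

Rigid patient positioning errors are simulated by translating the
irradiation fields with respect to the density grid (structures stay fixed)
and recomputing the dose with frozen spot weights — no reoptimization.  For
each shift the plan-quality indices are re-evaluated against the unshifted
masks and reported as signed differences Δ = shifted − initial.

The tested shift set S is the complete enumeration of vectors whose
components along (LR, AP, SI) are either zero or equal in absolute value,
with 3-D magnitude in a configured set; magnitudes {1, 2} mm give the 52
shifts (26 per magnitude: 6 single-axis, 12 two-axis, 8 three-axis).

In the parallel-beam model a shift component along a field's axis changes
neither the spot lattice seen by the anatomy nor any water-equivalent
depth, so purely along-beam shifts leave the dose invariant — the physical
rationale for treating only transverse components as perturbing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import dose_engine as de
from .grids import DensityGrid, GridError, StructureSet
from .metrics import IndexSet
from .planner import Plan


class RobustnessError(ValueError):
    pass


@dataclass(frozen=True)
class ShiftVector:
    """Rigid translation (mm) along (LR, AP, SI)."""

    x: float
    y: float
    z: float

    @property
    def magnitude(self) -> float:
        return float(np.sqrt(self.x**2 + self.y**2 + self.z**2))

    @property
    def label(self) -> str:
        sym = {1: "+", -1: "-", 0: "0"}
        comps = ",".join(sym[int(np.sign(c))] for c in (self.x, self.y, self.z))
        return f"{self.magnitude:g}({comps})"

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def enumerate_shifts(magnitudes) -> list[ShiftVector]:
    """All shifts with components in {0, ±c}, equal absolute value where
    nonzero, and 3-D magnitude in ``magnitudes`` (26 per magnitude)."""
    mags = sorted(set(float(m) for m in magnitudes))
    if any(m <= 0 for m in mags):
        raise RobustnessError("shift magnitudes must be positive")
    out = []
    for m in mags:
        for pattern in itertools.product((-1, 0, 1), repeat=3):
            k = sum(abs(p) for p in pattern)
            if k == 0:
                continue
            c = m / np.sqrt(k)
            out.append(ShiftVector(*(p * c for p in pattern)))
    return out


def recompute_with_shift(
    grid: DensityGrid,
    structures: StructureSet,
    plan: Plan,
    shift: ShiftVector,
    wepl_cache: dict | None = None,
) -> de.DoseGrid:
    """Recompute the plan dose with all fields rigidly translated by ``shift``.

    Spot weights are frozen; only the transverse component of the shift per
    field perturbs the dose (parallel-beam model), and a zero shift
    reproduces the planned dose bit-exactly.
    """
    s = shift.as_array()
    if np.any(np.abs(s) > 0.25 * grid.extent_mm()):
        raise GridError("shift moves the fields outside the grid support")
    total_abs = np.zeros(grid.shape)
    total_w = np.zeros(grid.shape)
    for f in plan.fields:
        u, v, _ = f.beam.frame()
        key = tuple(f.beam.direction)
        wv = None if wepl_cache is None else wepl_cache.get(key)
        d = de.compute_dose(
            grid, f.beam, f.spots, f.weights, wepl_vol=wv,
            lateral_shift=(float(s @ u), float(s @ v)),
        )
        total_abs += d.absorbed
        if plan.species == "carbon":
            total_w += d.weighted
    if plan.species != "carbon":
        total_w = de.PROTON_RBE * total_abs
    return de.DoseGrid(total_abs, total_w, grid.spacing, grid.origin)


@dataclass
class DeltaRecord:
    """Signed index changes (shifted − initial) for one shift."""

    shift: ShiftVector
    d_ptv_v95: float
    d_ctv_v95: float
    d_ptv_hi: float
    d_ctv_hi: float
    d_dmax: dict[str, float] = field(default_factory=dict)
    d_dnearmax_brainstem: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {
            "d_ptv_v95": self.d_ptv_v95,
            "d_ctv_v95": self.d_ctv_v95,
            "d_ptv_hi": self.d_ptv_hi,
            "d_ctv_hi": self.d_ctv_hi,
        }
        for k, v in self.d_dmax.items():
            out[f"d_dmax_{k}"] = v
        if self.d_dnearmax_brainstem is not None:
            out["d_dnearmax_brainstem"] = self.d_dnearmax_brainstem
        return out


def delta_indices(
    initial: IndexSet, shifted: IndexSet, shift: ShiftVector
) -> DeltaRecord:
    """Componentwise shifted − initial."""
    if set(initial.dmax) != set(shifted.dmax):
        raise RobustnessError("index sets cover different OAR structures")
    if (initial.dnearmax_brainstem is None) != (shifted.dnearmax_brainstem is None):
        raise RobustnessError("index sets cover different structures (brainstem)")
    dnm = None
    if initial.dnearmax_brainstem is not None:
        dnm = shifted.dnearmax_brainstem - initial.dnearmax_brainstem
    return DeltaRecord(
        shift=shift,
        d_ptv_v95=shifted.ptv_v95 - initial.ptv_v95,
        d_ctv_v95=shifted.ctv_v95 - initial.ctv_v95,
        d_ptv_hi=shifted.ptv_hi - initial.ptv_hi,
        d_ctv_hi=shifted.ctv_hi - initial.ctv_hi,
        d_dmax={k: shifted.dmax[k] - initial.dmax[k] for k in initial.dmax},
        d_dnearmax_brainstem=dnm,
    )


#: population histogram thresholds: |ΔV95|, |ΔHI| in pp; |ΔD| in Gy(RBE)
DEFAULT_THRESHOLDS = {"v95_pp": 1.0, "hi_pp": 1.0, "dose_gyrbe": 2.0}


@dataclass
class RobustnessSummary:
    """Population statistics of Δ indices across records."""

    n_records: int
    stats: dict[str, dict[str, float]]
    fraction_within: dict[str, float]
    thresholds: dict[str, float]


def aggregate_population(
    records: list[DeltaRecord], thresholds: dict[str, float] | None = None
) -> RobustnessSummary:
    """Median/quartiles/min/max per index plus the fraction of records with
    |Δ| below the configured thresholds (order-invariant, deterministic)."""
    if not records:
        raise RobustnessError("no delta records to aggregate")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    series: dict[str, list[float]] = {}
    for rec in records:
        for k, v in rec.as_dict().items():
            series.setdefault(k, []).append(v)
    stats_out = {}
    frac = {}
    for k, vals in series.items():
        arr = np.asarray(vals, dtype=float)
        stats_out[k] = {
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
        if "v95" in k:
            t = thr["v95_pp"]
        elif "hi" in k:
            t = thr["hi_pp"]
        else:
            t = thr["dose_gyrbe"]
        frac[k] = float(np.mean(np.abs(arr) < t))
    return RobustnessSummary(len(records), stats_out, frac, thr)


def sign_test(paired_deltas_a, paired_deltas_b) -> float:
    """Two-sided exact binomial sign test on paired differences (a − b).

    Ties (zero differences) are dropped; an all-tie input is an error.
    """
    a = np.asarray(paired_deltas_a, dtype=float)
    b = np.asarray(paired_deltas_b, dtype=float)
    if a.shape != b.shape:
        raise RobustnessError("paired samples must have equal length")
    diff = a - b
    diff = diff[diff != 0.0]
    if diff.size == 0:
        raise RobustnessError(
            "sign test undefined: all pairs are tied (zero differences)"
        )
    k = int(np.sum(diff > 0))
    return float(stats.binomtest(k, diff.size, 0.5, alternative="two-sided").pvalue)
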