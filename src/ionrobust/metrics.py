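"""DVH construction and dosimetric plan-quality indices.

All indices depend only on the multiset of voxel doses within a structure
mask (cumulative DVH), except the conformity index which also uses the
prescription-isodose volume outside the structure:

* V95%   — percent of the structure receiving >= 95 % of prescription;
* HI     — D2% - D98%, reported in percentage points of prescription;
* CI     — van't Riet conformation number (TV_PIV/TV) * (TV_PIV/PIV);
* Dmax   — hottest voxel; D_near-max — dose exceeded by the hottest 1 %.

Percentile-type doses (D1%, D2%, D98%) are obtained by linear interpolation
on the cumulative curve, which is stable across bin widths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: DVH bin width as a fraction of the prescription dose
DVH_BIN_FRACTION = 1e-3


class MetricsError(ValueError):
    pass


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``volume_pct[i]`` is the percentage of the structure receiving at least
    ``dose[i]``; the curve starts at 100 % at dose 0 and is monotone
    non-increasing, reaching 0 beyond the maximum voxel dose.
    """

    dose: np.ndarray
    volume_pct: np.ndarray
    structure: str = ""

    def __post_init__(self) -> None:
        if len(self.dose) != len(self.volume_pct):
            raise MetricsError("dose and volume axes must have equal length")


def cumulative_dvh(
    dose: np.ndarray, mask: np.ndarray, bin_width: float, structure: str = ""
) -> DVHCurve:
    """Cumulative DVH by voxel counting: V(d) = 100 |{v: dose_v >= d}| / |mask|."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MetricsError("empty structure mask")
    if bin_width <= 0:
        raise MetricsError("bin width must be positive")
    vals = np.asarray(dose)[mask].ravel()
    edges = np.arange(0.0, vals.max() + 2 * bin_width, bin_width)
    # fraction of voxels with dose >= edge
    counts = np.searchsorted(np.sort(vals), edges, side="left")
    vol = 100.0 * (len(vals) - counts) / len(vals)
    return DVHCurve(edges, vol, structure)


def v_at(dvh: DVHCurve, dose_level: float) -> float:
    """Volume percent receiving at least ``dose_level`` (linear on the curve)."""
    if dose_level < 0:
        raise MetricsError("dose level must be >= 0")
    return float(np.interp(dose_level, dvh.dose, dvh.volume_pct, right=0.0))


def d_at(dvh: DVHCurve, volume_percent: float) -> float:
    """Dose received by at least ``volume_percent`` of the structure.

    Linear interpolation of the inverse cumulative curve; for plateaus the
    highest dose still reaching the requested volume is returned.
    """
    if not 0 < volume_percent <= 100:
        raise MetricsError("volume percent must be in (0, 100]")
    vol = dvh.volume_pct
    dose = dvh.dose
    if volume_percent <= vol[-1]:
        return float(dose[-1])
    # rightmost crossing: first index where volume drops below the query
    below = np.nonzero(vol < volume_percent)[0]
    if len(below) == 0:
        return float(dose[-1])
    i = below[0]
    if i == 0:
        return float(dose[0])
    v0, v1 = vol[i - 1], vol[i]
    d0, d1 = dose[i - 1], dose[i]
    if v0 == v1:
        return float(d0)
    return float(d0 + (d1 - d0) * (v0 - volume_percent) / (v0 - v1))


def v95(dvh: DVHCurve, prescription: float) -> float:
    return v_at(dvh, 0.95 * prescription)


def homogeneity_index(dvh: DVHCurve, prescription: float) -> float:
    """HI = D2% - D98%, in percentage points of the prescription dose."""
    return 100.0 * (d_at(dvh, 2.0) - d_at(dvh, 98.0)) / prescription


def conformity_index(
    dose: np.ndarray, ptv_mask: np.ndarray, level: float
) -> float:
    """van't Riet conformation number of the ``level`` isodose to the PTV."""
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise MetricsError("empty PTV mask")
    piv = np.asarray(dose) >= level
    n_piv = int(piv.sum())
    if n_piv == 0:
        return 0.0
    n_tv = int(ptv_mask.sum())
    n_both = int((piv & ptv_mask).sum())
    return (n_both / n_tv) * (n_both / n_piv)


def dmax_and_near_max(
    dose: np.ndarray, mask: np.ndarray, bin_width: float
) -> tuple[float, float]:
    """(Dmax, D_near-max at 1 % volume) for a structure."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MetricsError("empty structure mask")
    dvh = cumulative_dvh(dose, mask, bin_width)
    return float(np.asarray(dose)[mask].max()), d_at(dvh, 1.0)


OPTIC_STRUCTURES = ("chiasm", "optic_nerve_ipsi", "optic_nerve_contra")


@dataclass
class IndexSet:
    """All plan-quality indices evaluated for one dose distribution."""

    ptv_v95: float
    ctv_v95: float
    ptv_hi: float
    ctv_hi: float
    ci: float
    dmax: dict[str, float] = field(default_factory=dict)
    dnearmax_brainstem: float | None = None
    dose_modulation: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {
            "ptv_v95": self.ptv_v95,
            "ctv_v95": self.ctv_v95,
            "ptv_hi": self.ptv_hi,
            "ctv_hi": self.ctv_hi,
            "ci": self.ci,
        }
        for name, val in self.dmax.items():
            out[f"dmax_{name}"] = val
        if self.dnearmax_brainstem is not None:
            out["dnearmax_brainstem"] = self.dnearmax_brainstem
        if self.dose_modulation is not None:
            out["dose_modulation"] = self.dose_modulation
        return out


def compute_indices(
    dose: np.ndarray,
    structures,
    prescription: float,
    oar_names: tuple[str, ...] | None = None,
) -> IndexSet:
    """Evaluate the full index set on an (RBE-weighted) dose array.

    ``structures`` is a :class:`~ionrobust.grids.StructureSet` with at least
    ``ctv`` and ``ptv``; OAR indices are computed for whichever of the
    canonical OARs are present (or the explicit ``oar_names``).
    """
    bw = DVH_BIN_FRACTION * prescription
    dvh_ptv = cumulative_dvh(dose, structures["ptv"], bw, "ptv")
    dvh_ctv = cumulative_dvh(dose, structures["ctv"], bw, "ctv")
    if oar_names is None:
        oar_names = tuple(n for n in OPTIC_STRUCTURES if n in structures
                          and structures[n].any())
    dmax = {}
    for name in oar_names:
        dmax[name] = float(np.asarray(dose)[structures[name]].max())
    dnm = None
    if "brainstem" in structures and structures["brainstem"].any():
        _, dnm = dmax_and_near_max(dose, structures["brainstem"], bw)
    constrained = list(dmax.values()) + ([dnm] if dnm is not None else [])
    all_oars = list(oar_names) + (
        ["brainstem"] if "brainstem" in structures and structures["brainstem"].any() else []
    )
    modulation = None
    if all_oars:
        peak = max(float(np.asarray(dose)[structures[n]].max()) for n in all_oars)
        modulation = peak / prescription
    return IndexSet(
        ptv_v95=v95(dvh_ptv, prescription),
        ctv_v95=v95(dvh_ctv, prescription),
        ptv_hi=homogeneity_index(dvh_ptv, prescription),
        ctv_hi=homogeneity_index(dvh_ctv, prescription),
        ci=conformity_index(dose, structures["ptv"], 0.95 * prescription),
        dmax=dmax,
        dnearmax_brainstem=dnm,
        dose_modulation=modulation,
    )
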