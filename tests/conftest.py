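"""Shared fixtures.

The heavier planning fixtures are session-scoped so the attainability and
robustness checks reuse one optimization per species/mode.
"""

from __future__ import annotations

import numpy as np
import pytest

from ionrobust import dose_engine as de
from ionrobust import phantom as ph
from ionrobust import workflows as wf


@pytest.fixture(scope="session")
def water_small():
    """Small uniform water phantom (fast dose-engine checks)."""
    return ph.make_water_phantom((40, 40, 40), (2.0, 2.0, 2.0), ctv_side_mm=20.0)


@pytest.fixture(scope="session")
def skullbase_default():
    """Default heterogeneous phantom, seed 0."""
    return ph.make_skullbase_phantom(ph.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def water_uc_case_carbon():
    """Carbon unconstrained opposed-beam plan on a small water phantom."""
    return wf.water_benchmark_case(
        "carbon", "uc", shape=(40, 40, 40), spacing=(2.0, 2.0, 2.0),
        ctv_side_mm=20.0
    )


@pytest.fixture(scope="session")
def water_benchmarks():
    """Planning-attainability battery: species x mode on the water phantom."""
    cases = {}
    for species in ("carbon", "proton"):
        for mode in ("uc", "sc", "mc"):
            cases[(species, mode)] = wf.water_benchmark_case(species, mode)
    return cases


@pytest.fixture(scope="session")
def water_carbon_constrained():
    """Carbon mc plan on the water phantom with an abutting brainstem OAR."""
    return wf.water_benchmark_case("carbon", "mc", with_oar=True)


@pytest.fixture(scope="session")
def lr_rob_study():
    """Population LR-vs-ROB shift study on 10 seeded heterogeneous phantoms."""
    return wf.setup_comparison_study(seeds=range(1, 11))


def brute_force_dose(grid, beam, spots, weights):
    """Independent per-voxel triple-sum superposition oracle (absorbed dose).

    Deliberately naive: per spot, per voxel, point WEPL + analytic Bragg
    curve + exact Gaussian, no lookup tables, no layer factorization, no
    lateral cutoff.
    """
    centers = grid.voxel_centers()
    wepl_v = de.wepl_points(grid, beam.direction, centers) + beam.bolus_mm
    u, v, _ = beam.frame()
    pu = centers @ u
    pv = centers @ v
    dose = np.zeros(len(centers))
    for s, w in zip(spots, weights):
        sigma = s.fwhm_mm * de.FWHM_TO_SIGMA
        bragg = de.depth_dose(s.range_mm, wepl_v, beam.species,
                              beam.machine.depth_dose)
        lat = np.exp(
            -((pu - s.u_mm) ** 2 + (pv - s.v_mm) ** 2) / (2 * sigma**2)
        )
        dose += w * bragg * lat
    return dose.reshape(grid.shape)
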