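"""Ray tracing, Bragg curve, spot placement and superposition."""

import numpy as np
import pytest

from conftest import brute_force_dose
from ionrobust import dose_engine as de
from ionrobust.grids import DensityGrid, GridError
from ionrobust.phantom import make_water_phantom


@pytest.fixture(scope="module")
def slab_grid():
    """50 mm water followed by 50 mm of density 2.0 along +LR (1 mm voxels)."""
    vox = np.ones((100, 21, 21))
    vox[50:] = 2.0
    return DensityGrid(vox, (1.0, 1.0, 1.0))


class TestWEPL:
    def test_water_geometric_depth(self):
        grid = DensityGrid(np.ones((101, 11, 11)), (1.0, 1.0, 1.0))
        # upstream face at x = -0.5; 100 mm of water down to this point
        w = de.wepl(grid, (1, 0, 0), (99.5, 5.0, 5.0))
        assert w == pytest.approx(100.0, abs=0.5 * grid.spacing[0])

    def test_slab_closed_form(self, slab_grid):
        # water from the face at -0.5 to the interface at 49.5 (50 mm), then
        # 50 mm at density 2.0 -> 150 mm WEPL
        w = de.wepl(slab_grid, (1, 0, 0), (99.5, 10.0, 10.0))
        assert w == pytest.approx(150.0, abs=0.8)

    def test_bolus_offset_at_entrance(self, water_small):
        grid, _ = water_small
        w = de.wepl(grid, (1, 0, 0), (0.0, 40.0, 40.0), bolus_mm=20.0)
        assert w == pytest.approx(20.0, abs=0.5 * grid.spacing[0] + 1e-9)

    def test_point_outside_grid_rejected(self, water_small):
        grid, _ = water_small
        with pytest.raises(GridError):
            de.wepl(grid, (1, 0, 0), (500.0, 40.0, 40.0))

    def test_oblique_matches_axis_in_uniform_water(self, water_small):
        grid, _ = water_small
        p = np.array([40.0, 40.0, 40.0])
        d = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        w = de.wepl(grid, d, p)
        # geometric distance to the nearest upstream face along -d
        expect = np.sqrt(2) * (p[0] + 1.0)
        assert w == pytest.approx(expect, abs=1.0)

    def test_volume_matches_pointwise(self, slab_grid):
        wv = de.wepl_volume(slab_grid, (1, 0, 0))
        pts = [(30.0, 10.0, 10.0), (75.0, 5.0, 15.0)]
        for p in pts:
            idx = tuple(int(round(c)) for c in p)
            assert wv[idx] == pytest.approx(
                de.wepl(slab_grid, (1, 0, 0), p), abs=1e-9
            )


class TestDepthDose:
    @pytest.mark.parametrize("species", ["carbon", "proton"])
    def test_peak_normalized_at_range(self, species):
        assert de.depth_dose(100.0, 100.0, species) == pytest.approx(1.0)

    @pytest.mark.parametrize("species", ["carbon", "proton"])
    def test_distal_falloff(self, species):
        w = de.falloff_width_mm(species)
        assert de.depth_dose(100.0, 100.0 + 5 * w, species) < 0.01

    @pytest.mark.parametrize("species", ["carbon", "proton"])
    def test_entrance_plateau_fraction(self, species):
        entrance = de.depth_dose(150.0, 0.0, species)
        assert 0.2 <= entrance <= 0.5

    def test_nonnegative_and_finite(self):
        z = np.linspace(-5, 200, 500)
        d = de.depth_dose(120.0, z, "carbon")
        assert np.all(d >= 0) and np.all(np.isfinite(d))

    def test_invalid_range(self):
        with pytest.raises(de.BeamError):
            de.depth_dose(-1.0, 10.0, "proton")


class TestSpotFWHM:
    @pytest.mark.parametrize("species,lo,hi", [
        ("carbon", 7.5, 5.0),
        ("proton", 11.0, 5.5),
    ])
    def test_machine_endpoints(self, species, lo, hi):
        m = de.default_machine(species)
        assert de.spot_fwhm(m.range_min_mm, species) == pytest.approx(lo)
        assert de.spot_fwhm(m.range_max_mm, species) == pytest.approx(hi)

    def test_monotone_nonincreasing(self):
        r = np.linspace(20, 300, 50)
        f = [de.spot_fwhm(x, "carbon") for x in r]
        assert np.all(np.diff(f) <= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(de.BeamError):
            de.spot_fwhm(10.0, "carbon")


class TestPlaceSpots:
    def test_carbon_layer_step_3mm(self, water_small):
        grid, structures = water_small
        beam = de.BeamSetup((1, 0, 0), "carbon")
        spots = de.place_spots(structures["ptv"], grid, beam)
        ranges = sorted({s.range_mm for s in spots})
        assert np.allclose(np.diff(ranges), 3.0)

    def test_proton_lattice_pitch_3mm(self, water_small):
        grid, structures = water_small
        beam = de.BeamSetup((1, 0, 0), "proton")
        spots = de.place_spots(structures["ptv"], grid, beam)
        ranges = sorted({s.range_mm for s in spots})
        assert np.allclose(np.diff(ranges), 2.0)
        layer = [s for s in spots if s.range_mm == ranges[0]]
        us = sorted({s.u_mm for s in layer})
        assert np.allclose(np.diff(us), 3.0)

    def test_tolerance_dilation_strictly_monotone(self, water_small):
        grid, structures = water_small
        n = {}
        for tol in (0.0, 1.0):
            beam = de.BeamSetup((1, 0, 0), "carbon", tolerance=tol)
            n[tol] = len(de.place_spots(structures["ptv"], grid, beam))
        assert n[1.0] > n[0.0]

    def test_every_target_voxel_bracketed(self, water_small):
        grid, structures = water_small
        beam = de.BeamSetup((1, 0, 0), "carbon")
        wv = de.wepl_volume(grid, beam.direction)
        spots = de.place_spots(structures["ptv"], grid, beam, wepl_vol=wv)
        ranges = np.array(sorted({s.range_mm for s in spots}))
        depth = wv[structures["ptv"]]
        assert ranges.min() <= depth.min() and ranges.max() >= depth.max()

    def test_shallow_target_needs_bolus(self):
        grid, structures = make_water_phantom((40, 40, 40), (1, 1, 1),
                                              ctv_side_mm=14.0)
        beam = de.BeamSetup((1, 0, 0), "carbon")
        with pytest.raises(de.BeamError, match="bolus"):
            de.place_spots(structures["ctv"], grid, beam)
        with_bolus = de.BeamSetup((1, 0, 0), "carbon", bolus_mm=20.0)
        assert de.place_spots(structures["ctv"], grid, with_bolus)


@pytest.fixture(scope="module")
def few_spots(water_small):
    grid, _ = water_small
    beam = de.BeamSetup((1, 0, 0), "carbon")
    spots = [
        de.PencilBeamSpot(0, 40.0, 40.0, 45.0, 6.5),
        de.PencilBeamSpot(0, 44.0, 38.0, 45.0, 6.5),
        de.PencilBeamSpot(1, 40.0, 42.0, 48.0, 6.4),
    ]
    return grid, beam, spots


class TestComputeDose:
    def test_zero_weights_zero_dose(self, few_spots):
        grid, beam, spots = few_spots
        d = de.compute_dose(grid, beam, spots, np.zeros(3))
        assert not d.absorbed.any() and not d.weighted.any()

    def test_linearity_in_weights(self, few_spots):
        grid, beam, spots = few_spots
        w = np.array([1.0, 2.0, 0.5])
        d1 = de.compute_dose(grid, beam, spots, w)
        d2 = de.compute_dose(grid, beam, spots, 2 * w)
        assert np.allclose(d2.absorbed, 2 * d1.absorbed, rtol=1e-12)

    def test_negative_weight_rejected(self, few_spots):
        grid, beam, spots = few_spots
        with pytest.raises(de.BeamError):
            de.compute_dose(grid, beam, spots, np.array([1.0, -0.1, 0.0]))

    def test_single_spot_peak_at_range(self, water_small):
        grid, _ = water_small
        beam = de.BeamSetup((1, 0, 0), "carbon")
        spot = de.PencilBeamSpot(0, 40.0, 40.0, 50.0, 6.5)
        d = de.compute_dose(grid, beam, [spot], np.array([1.0]))
        axis = d.absorbed[:, 20, 20]
        wv = de.wepl_volume(grid, beam.direction)
        peak_wepl = wv[np.argmax(axis), 20, 20]
        assert peak_wepl == pytest.approx(50.0, abs=grid.spacing[0])

    def test_matches_brute_force_axis_aligned(self, slab_grid):
        beam = de.BeamSetup((1, 0, 0), "carbon")
        rng = np.random.default_rng(3)
        spots = [
            de.PencilBeamSpot(0, float(u), float(v), float(r), 6.0)
            for u, v, r in zip(
                rng.uniform(6, 14, 8), rng.uniform(6, 14, 8),
                rng.uniform(60, 120, 8)
            )
        ]
        w = rng.uniform(0.2, 1.0, 8)
        got = de.compute_dose(slab_grid, beam, spots, w).absorbed
        want = brute_force_dose(slab_grid, beam, spots, w)
        assert np.allclose(got, want, rtol=2e-3, atol=2e-4 * want.max())

    def test_matches_brute_force_oblique(self, water_small):
        grid, _ = water_small
        d = np.array([0.8, 0.6, 0.0])
        beam = de.BeamSetup(tuple(d), "proton")
        spots = [de.PencilBeamSpot(0, -10.0, 40.0, 60.0, 8.0),
                 de.PencilBeamSpot(0, -4.0, 44.0, 62.0, 8.0)]
        w = np.array([1.0, 0.7])
        got = de.compute_dose(grid, beam, spots, w).absorbed
        want = brute_force_dose(grid, beam, spots, w)
        # oblique incidence uses a 1 mm fluence lattice -> small smoothing
        assert np.allclose(got, want, rtol=0.05, atol=5e-3 * want.max())

    def test_translation_equivariance_in_water(self, water_small):
        grid, _ = water_small
        beam = de.BeamSetup((1, 0, 0), "carbon")
        spots = [de.PencilBeamSpot(0, 36.0, 40.0, 50.0, 6.5),
                 de.PencilBeamSpot(0, 42.0, 40.0, 53.0, 6.5)]
        w = np.array([1.0, 0.8])
        base = de.compute_dose(grid, beam, spots, w).absorbed
        # +4 mm along v (SI) = 2 voxels at 2 mm spacing
        moved = [de.PencilBeamSpot(s.layer, s.u_mm, s.v_mm + 4.0, s.range_mm,
                                   s.fwhm_mm) for s in spots]
        shifted = de.compute_dose(grid, beam, moved, w).absorbed
        assert np.allclose(shifted[:, :, 2:], base[:, :, :-2],
                           rtol=1e-9, atol=1e-12)

    def test_lateral_half_value_at_half_fwhm(self, water_small):
        grid, _ = water_small
        beam = de.BeamSetup((1, 0, 0), "carbon")
        spot = de.PencilBeamSpot(0, 40.0, 40.0, 50.0, 6.0)
        pts = np.array([[30.0, 40.0, 40.0], [30.0, 40.0, 43.0]])
        mat = de.spot_dose_at_points(grid, beam, [spot], pts,
                                     weighted=False).toarray()
        assert mat[1, 0] == pytest.approx(0.5 * mat[0, 0], rel=1e-9)


class TestRBE:
    def test_proton_fixed_ratio(self, water_small):
        grid, structures = water_small
        beam = de.BeamSetup((1, 0, 0), "proton")
        spots = de.place_spots(structures["ptv"], grid, beam)
        d = de.compute_dose(grid, beam, spots, np.ones(len(spots)))
        nz = d.absorbed > 0
        assert np.allclose(d.weighted[nz] / d.absorbed[nz], 1.1, rtol=1e-12)

    def test_apply_rbe_proton(self):
        dose = de.DoseGrid(np.full((4, 4, 4), 2.0), np.zeros((4, 4, 4)),
                           (1, 1, 1))
        out = de.apply_rbe(dose, "proton")
        assert np.allclose(out.weighted, 2.2)

    def test_zero_dose_stays_zero(self):
        dose = de.DoseGrid(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), (1, 1, 1))
        out = de.apply_rbe(dose, "carbon",
                           residual_range_mm=np.full((4, 4, 4), 10.0))
        assert not out.weighted.any()

    def test_carbon_rbe_higher_near_end_of_range(self, water_small):
        grid, structures = water_small
        beam = de.BeamSetup((1, 0, 0), "carbon")
        spots = [de.PencilBeamSpot(0, 40.0, 40.0, 60.0, 6.2)]
        d = de.compute_dose(grid, beam, spots, np.array([1.0]))
        nz = d.absorbed > 1e-6
        rbe = np.where(nz, d.weighted / np.where(nz, d.absorbed, 1.0), 0.0)
        wv = de.wepl_volume(grid, beam.direction)
        plateau = rbe[(wv < 20) & nz]
        peak = rbe[(np.abs(wv - 60) < 2) & nz]
        assert peak.mean() > plateau.mean()
        assert np.all(d.weighted[nz] >= d.absorbed[nz])

    def test_unknown_species_rejected(self):
        dose = de.DoseGrid(np.ones((2, 2, 2)), np.ones((2, 2, 2)), (1, 1, 1))
        with pytest.raises(de.BeamError):
            de.apply_rbe(dose, "helium")
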