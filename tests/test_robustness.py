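"""Shift-set enumeration, shifted recomputation and Δ statistics."""

import itertools

import numpy as np
import pytest

from ionrobust import dose_engine as de
from ionrobust import metrics as mx
from ionrobust import robustness as rb
from ionrobust import workflows as wf
from ionrobust.planner import Field, Plan, Prescription


class TestEnumerateShifts:
    def test_full_set_has_52_members(self):
        shifts = rb.enumerate_shifts([1.0, 2.0])
        assert len(shifts) == 52
        by_mag = {}
        for s in shifts:
            by_mag.setdefault(round(s.magnitude, 9), []).append(s)
        assert {k: len(v) for k, v in by_mag.items()} == {1.0: 26, 2.0: 26}

    def test_single_magnitude_combinatorics(self):
        shifts = rb.enumerate_shifts([1.0])
        assert len(shifts) == 26
        counts = {1: 0, 2: 0, 3: 0}
        for s in shifts:
            k = sum(c != 0 for c in (s.x, s.y, s.z))
            counts[k] += 1
            nz = [abs(c) for c in (s.x, s.y, s.z) if c != 0]
            assert np.allclose(nz, nz[0])  # equal absolute components
            assert s.magnitude == pytest.approx(1.0)
        assert counts == {1: 6, 2: 12, 3: 8}

    def test_closed_under_negation_and_permutation(self):
        shifts = {(round(s.x, 9), round(s.y, 9), round(s.z, 9))
                  for s in rb.enumerate_shifts([1.0, 2.0])}
        for v in shifts:
            assert tuple(-c for c in v) in shifts
            for perm in itertools.permutations(v):
                assert perm in shifts

    def test_no_duplicates_no_null(self):
        shifts = rb.enumerate_shifts([1.0, 2.0])
        vecs = {tuple(np.round(s.as_array(), 9)) for s in shifts}
        assert len(vecs) == len(shifts)
        assert (0.0, 0.0, 0.0) not in vecs

    def test_empty_and_invalid(self):
        assert rb.enumerate_shifts([]) == []
        with pytest.raises(rb.RobustnessError):
            rb.enumerate_shifts([0.0])


@pytest.fixture(scope="module")
def single_beam_case(water_small):
    """One-field carbon plan with uniform weights on the water phantom."""
    grid, structures = water_small
    beam = de.BeamSetup((1.0, 0.0, 0.0), "carbon")
    wv = de.wepl_volume(grid, beam.direction)
    spots = de.place_spots(structures["ptv"], grid, beam, wepl_vol=wv)
    w = np.full(len(spots), 0.5)
    field = Field(beam, spots, w)
    plan = Plan([field], Prescription(60.0, 20), [], "uc", "carbon")
    cache = {tuple(beam.direction): wv}
    return grid, structures, plan, cache


class TestRecomputeWithShift:
    def test_zero_shift_bit_exact(self, single_beam_case):
        grid, structures, plan, cache = single_beam_case
        planned = rb.recompute_with_shift(grid, structures, plan,
                                          rb.ShiftVector(0, 0, 0), cache)
        again = rb.recompute_with_shift(grid, structures, plan,
                                        rb.ShiftVector(0, 0, 0), cache)
        from ionrobust.planner import plan_dose

        base = plan_dose(plan, grid, cache)
        assert np.array_equal(planned.weighted, base.weighted)
        assert np.array_equal(planned.weighted, again.weighted)

    def test_along_beam_shift_invariant(self, single_beam_case):
        grid, structures, plan, cache = single_beam_case
        base = rb.recompute_with_shift(grid, structures, plan,
                                       rb.ShiftVector(0, 0, 0), cache)
        along = rb.recompute_with_shift(grid, structures, plan,
                                        rb.ShiftVector(2.0, 0, 0), cache)
        assert np.array_equal(base.weighted, along.weighted)

    def test_lateral_shift_translates_dose_in_water(self, single_beam_case):
        grid, structures, plan, cache = single_beam_case
        base = rb.recompute_with_shift(grid, structures, plan,
                                       rb.ShiftVector(0, 0, 0), cache)
        # 2 mm along AP = 1 voxel; field shifted => dose pattern translated
        shifted = rb.recompute_with_shift(grid, structures, plan,
                                          rb.ShiftVector(0, 2.0, 0), cache)
        # interior comparison away from the rolled-in boundary plane
        assert np.allclose(shifted.weighted[:, 1:, :],
                           base.weighted[:, :-1, :], rtol=1e-9, atol=1e-12)

    def test_excessive_shift_rejected(self, single_beam_case):
        grid, structures, plan, cache = single_beam_case
        with pytest.raises(Exception):
            rb.recompute_with_shift(grid, structures, plan,
                                    rb.ShiftVector(0, 500.0, 0), cache)


def _index_set(**kw):
    base = dict(ptv_v95=99.8, ctv_v95=100.0, ptv_hi=4.0, ctv_hi=3.0, ci=0.85,
                dmax={"chiasm": 54.0}, dnearmax_brainstem=53.0)
    base.update(kw)
    return mx.IndexSet(**base)


class TestDeltaIndices:
    def test_identical_sets_zero(self):
        rec = rb.delta_indices(_index_set(), _index_set(),
                               rb.ShiftVector(1, 0, 0))
        assert all(v == 0.0 for v in rec.as_dict().values())

    def test_sign_convention_reduction_negative(self):
        a = _index_set(ctv_v95=99.8)
        b = _index_set(ctv_v95=96.3)
        rec = rb.delta_indices(a, b, rb.ShiftVector(0, 2, 0))
        assert rec.d_ctv_v95 == pytest.approx(-3.5)

    def test_antisymmetric(self):
        a = _index_set(dmax={"chiasm": 50.0})
        b = _index_set(dmax={"chiasm": 53.0})
        ab = rb.delta_indices(a, b, rb.ShiftVector(1, 0, 0))
        ba = rb.delta_indices(b, a, rb.ShiftVector(1, 0, 0))
        assert ab.d_dmax["chiasm"] == -ba.d_dmax["chiasm"] == 3.0

    def test_structure_mismatch_rejected(self):
        a = _index_set()
        b = _index_set(dmax={"optic_nerve_ipsi": 40.0})
        with pytest.raises(rb.RobustnessError):
            rb.delta_indices(a, b, rb.ShiftVector(1, 0, 0))


class TestAggregatePopulation:
    def _record(self, dv95, shift=rb.ShiftVector(1, 0, 0)):
        return rb.DeltaRecord(shift, d_ptv_v95=dv95, d_ctv_v95=dv95,
                              d_ptv_hi=0.1, d_ctv_hi=0.1)

    def test_single_record(self):
        summary = rb.aggregate_population([self._record(-0.4)])
        assert summary.n_records == 1
        assert summary.stats["d_ctv_v95"]["median"] == -0.4
        assert summary.fraction_within["d_ctv_v95"] == 1.0

    def test_threshold_counting(self):
        records = [self._record(v) for v in (-0.5, -1.5, -3.0)]
        summary = rb.aggregate_population(records, {"v95_pp": 1.0})
        assert summary.fraction_within["d_ctv_v95"] == pytest.approx(1 / 3)

    def test_quartiles_ordered_and_order_invariant(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(-1, 2, 25)
        records = [self._record(v) for v in vals]
        s1 = rb.aggregate_population(records)
        s2 = rb.aggregate_population(records[::-1])
        st = s1.stats["d_ctv_v95"]
        assert st["min"] <= st["q1"] <= st["median"] <= st["q3"] <= st["max"]
        assert s1.stats == s2.stats

    def test_empty_rejected(self):
        with pytest.raises(rb.RobustnessError):
            rb.aggregate_population([])


class TestSignTest:
    def test_eight_concordant_pairs(self):
        a = np.arange(1.0, 9.0)
        b = a - 1.0
        assert rb.sign_test(a, b) == pytest.approx(0.0078125)

    def test_balanced_signs(self):
        a = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        b = np.zeros(8)
        assert rb.sign_test(a, b) == pytest.approx(1.0)

    def test_ties_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 5.0, 5.0])
        b = np.array([0.0, 1.0, 2.0, 5.0, 5.0])
        # two ties dropped -> 3 positives of 3
        assert rb.sign_test(a, b) == pytest.approx(2 * 0.5**3)

    def test_all_ties_error(self):
        with pytest.raises(rb.RobustnessError, match="tie"):
            rb.sign_test(np.ones(4), np.ones(4))

    def test_length_mismatch(self):
        with pytest.raises(rb.RobustnessError):
            rb.sign_test(np.ones(3), np.ones(4))
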