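"""DVH computation and plan-quality indices against counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as npst

from liverkbp import (
    CumulativeDVH,
    DoseGrid,
    StructureMask,
    compute_cumulative_dvh,
    compute_plan_metrics,
    conformity_index,
    dose_at_volume,
    dose_statistics,
    homogeneity_index,
    mean_dvh_curve,
    volume_at_dose,
)
from liverkbp.dvh import dvhs_from_csv, dvhs_to_csv, structure_doses
from liverkbp.errors import (
    CongruenceError,
    DegeneratePlanError,
    DomainError,
    EmptyStructureError,
)


class TestCumulativeDVH:
    def test_uniform_dose_is_a_step_at_the_plateau(self, uniform_plan):
        dose, mask = uniform_plan
        dvh = compute_cumulative_dvh(dose, mask)
        assert dvh.total_volume_cc == pytest.approx(1.0)
        assert dvh.rel_volume_at(0.0) == 1.0
        assert dvh.rel_volume_at(50.0) == 1.0
        assert dvh.rel_volume_at(50.1) == 0.0

    def test_two_level_structure_half_volume_between_levels(self, two_level_plan):
        dose, mask = two_level_plan
        dvh = compute_cumulative_dvh(dose, mask)
        assert dvh.rel_volume_at(20.0) == pytest.approx(0.5)
        assert dvh.rel_volume_at(5.0) == 1.0
        assert dvh.rel_volume_at(31.0) == 0.0

    def test_empty_mask_is_an_error(self, uniform_plan):
        dose, _ = uniform_plan
        empty = StructureMask("empty", np.zeros(dose.shape, dtype=bool))
        with pytest.raises(EmptyStructureError):
            compute_cumulative_dvh(dose, empty)

    def test_shape_mismatch_is_an_error(self, uniform_plan):
        dose, _ = uniform_plan
        other = StructureMask("bad", np.ones((5, 5, 5), dtype=bool))
        with pytest.raises(CongruenceError):
            compute_cumulative_dvh(dose, other)

    @settings(deadline=None, max_examples=50)
    @given(
        values=npst.arrays(
            float,
            npst.array_shapes(min_dims=3, max_dims=3, min_side=2, max_side=8),
            elements=st.floats(0, 80, allow_nan=False),
        )
    )
    def test_curve_is_monotone_and_anchored(self, values):
        dose = DoseGrid(values)
        mask = StructureMask("all", np.ones(values.shape, dtype=bool))
        dvh = compute_cumulative_dvh(dose, mask, bin_width_gy=0.5)
        assert np.all(np.diff(dvh.rel_volume) <= 1e-12)
        assert dvh.rel_volume[0] == 1.0
        assert dvh.rel_volume[-1] == 0.0


class TestVolumeAtDose:
    def test_relative_below_plateau_is_total(self, uniform_plan):
        dose, mask = uniform_plan
        doses = structure_doses(dose, mask)
        assert volume_at_dose(doses, 15.0) == 1.0

    def test_absolute_counting(self, two_level_plan):
        dose, mask = two_level_plan
        doses = structure_doses(dose, mask)
        # 50 of 100 one-mm voxels >= 15 Gy -> 0.05 cc
        assert volume_at_dose(doses, 15.0, "absolute", mask.voxel_volume_cc) == pytest.approx(0.05)

    def test_above_maximum_is_zero(self, two_level_plan):
        dose, mask = two_level_plan
        assert volume_at_dose(structure_doses(dose, mask), 60.0) == 0.0

    def test_zero_dose_query_is_one(self, two_level_plan):
        dose, mask = two_level_plan
        assert volume_at_dose(structure_doses(dose, mask), 0.0) == 1.0

    def test_negative_query_rejected(self, two_level_plan):
        dose, mask = two_level_plan
        with pytest.raises(DomainError):
            volume_at_dose(structure_doses(dose, mask), -1.0)

    def test_dvh_route_matches_voxel_route(self, two_level_plan):
        dose, mask = two_level_plan
        dvh = compute_cumulative_dvh(dose, mask)
        doses = structure_doses(dose, mask)
        for d in (0.0, 10.0, 20.0, 30.0):
            assert volume_at_dose(dvh, d) == pytest.approx(volume_at_dose(doses, d))


class TestDoseAtVolume:
    def test_uniform(self):
        doses = np.full(64, 50.0)
        assert dose_at_volume(doses, 2) == 50.0
        assert dose_at_volume(doses, 98) == 50.0

    def test_linear_interpolation_on_1_to_100(self):
        doses = np.arange(1.0, 101.0)
        assert dose_at_volume(doses, 98) == pytest.approx(2.98)

    def test_d100_is_minimum(self):
        doses = np.array([3.0, 7.0, 1.5, 9.0])
        assert dose_at_volume(doses, 100) == 1.5

    @pytest.mark.parametrize("pct", [0.0, -5.0, 100.5])
    def test_domain(self, pct):
        with pytest.raises(DomainError):
            dose_at_volume(np.ones(10), pct)


class TestDoseStatistics:
    def test_uniform(self, uniform_plan):
        assert dose_statistics(*uniform_plan) == (50.0, 50.0)

    def test_two_level(self, two_level_plan):
        mean, mx = dose_statistics(*two_level_plan)
        assert (mean, mx) == (20.0, 30.0)

    def test_single_cold_voxel(self):
        dose = DoseGrid(np.zeros((2, 2, 2)))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        assert dose_statistics(dose, StructureMask("v", mask)) == (0.0, 0.0)

    def test_brute_force_agreement_on_random_grid(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(0, 60, size=(15, 14, 13))
        mask = rng.random((15, 14, 13)) < 0.3
        dose = DoseGrid(values)
        struct = StructureMask("s", mask)
        # plain-python loop oracle
        sel = [values[i, j, k] for i in range(15) for j in range(14) for k in range(13) if mask[i, j, k]]
        mean, mx = dose_statistics(dose, struct)
        assert mean == pytest.approx(sum(sel) / len(sel), abs=1e-12)
        assert mx == max(sel)
        v20 = volume_at_dose(structure_doses(dose, struct), 20.0)
        assert v20 == pytest.approx(sum(d >= 20 for d in sel) / len(sel))


class TestConformityIndex:
    def test_perfect_conformity(self, uniform_plan):
        dose, ptv = uniform_plan
        assert conformity_index(dose, ptv, 50.0) == 1.0

    def test_isodose_spills_equal_volume_outside(self):
        # prescription isodose = PTV plus an equal disjoint volume -> CI = 0.5
        dose = np.zeros((4, 10, 10))
        ptv = np.zeros((4, 10, 10), dtype=bool)
        ptv[0] = True
        dose[0] = 50.0
        dose[2] = 50.0  # same size spill, outside PTV
        ci = conformity_index(DoseGrid(dose), StructureMask("ptv", ptv), 50.0)
        assert ci == pytest.approx(0.5)

    def test_isodose_covers_half_the_ptv_only(self):
        dose = np.zeros((4, 10, 10))
        ptv = np.zeros((4, 10, 10), dtype=bool)
        ptv[:2] = True
        dose[0] = 50.0
        ci = conformity_index(DoseGrid(dose), StructureMask("ptv", ptv), 50.0)
        assert ci == pytest.approx(0.5)

    def test_cold_plan_returns_zero_with_warning(self, uniform_plan):
        dose, ptv = uniform_plan
        with pytest.warns(UserWarning):
            assert conformity_index(dose, ptv, 80.0) == 0.0

    def test_never_exceeds_one_on_random_plans(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = rng.uniform(0, 60, size=(8, 8, 8))
            mask = rng.random((8, 8, 8)) < 0.4
            if not mask.any():
                continue
            ci = conformity_index(DoseGrid(values), StructureMask("p", mask), 30.0)
            assert 0.0 <= ci <= 1.0


class TestHomogeneityIndex:
    def test_uniform_dose_gives_one(self):
        assert homogeneity_index(np.full(128, 52.0)) == 1.0

    def test_constructed_hot_tail(self):
        # 101 sorted voxel doses: positions 0-3 at 50 Gy fix D98% = 50,
        # positions 98-100 at 54 Gy fix D2% = 54 under linear interpolation.
        doses = np.concatenate([np.full(4, 50.0), np.linspace(50.5, 53.5, 94), np.full(3, 54.0)])
        assert doses.size == 101
        assert homogeneity_index(doses) == pytest.approx(54.0 / 50.0)

    def test_at_least_one_on_random_doses(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            doses = rng.uniform(1, 60, size=200)
            assert homogeneity_index(doses) >= 1.0

    def test_zero_d98_is_degenerate(self):
        doses = np.concatenate([np.zeros(99), [50.0]])
        with pytest.raises(DegeneratePlanError):
            homogeneity_index(doses)


class TestMeanDVH:
    def _step(self, drop_gy):
        axis = np.array([0.0, drop_gy, drop_gy + 0.01, 60.0])
        rel = np.array([1.0, 1.0, 0.0, 0.0])
        return CumulativeDVH("s", axis, rel, 100.0)

    def test_idempotent_on_identical_curves(self, two_level_plan):
        dvh = compute_cumulative_dvh(*two_level_plan)
        avg = mean_dvh_curve([dvh] * 5, dose_axis=dvh.dose_axis)
        assert np.allclose(avg.rel_volume, dvh.rel_volume)

    def test_two_steps_average_to_half(self):
        avg = mean_dvh_curve([self._step(10), self._step(30)])
        assert avg.rel_volume_at(20.0) == pytest.approx(0.5)
        assert avg.rel_volume_at(5.0) == pytest.approx(1.0)
        assert avg.rel_volume_at(40.0) == pytest.approx(0.0)

    def test_single_curve_is_itself(self):
        step = self._step(25)
        avg = mean_dvh_curve([step], dose_axis=step.dose_axis)
        assert np.allclose(avg.rel_volume, step.rel_volume)

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            mean_dvh_curve([])

    def test_mean_of_monotone_curves_is_monotone(self, two_level_plan):
        dvh = compute_cumulative_dvh(*two_level_plan)
        avg = mean_dvh_curve([dvh, self._step(12), self._step(28)])
        assert np.all(np.diff(avg.rel_volume) <= 1e-12)


def test_plan_metrics_panel_names_and_values(uniform_plan):
    dose, ptv = uniform_plan
    heart = StructureMask("heart", ptv.mask.copy())
    pm = compute_plan_metrics(dose, {"ptv": ptv, "heart": heart}, 50.0, patient_id="X")
    assert pm["ptv.CI"] == 1.0
    assert pm["ptv.HI"] == 1.0
    assert pm["ptv.mean_cgy"] == pytest.approx(5000.0)
    assert pm["heart.mean_cgy"] == pytest.approx(5000.0)


def test_dvh_csv_round_trip(tmp_path, two_level_plan):
    dvh = compute_cumulative_dvh(*two_level_plan)
    path = tmp_path / "dvh.csv"
    dvhs_to_csv([("P1", dvh)], path)
    (pid, back), = dvhs_from_csv(path)
    assert pid == "P1"
    assert back.structure == dvh.structure
    assert np.allclose(back.dose_axis, dvh.dose_axis)
    assert np.allclose(back.rel_volume, dvh.rel_volume)
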