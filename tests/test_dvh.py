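import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import dvh_counting_oracle
from conftest import make_grid, make_mask, random_case

from boundarydose.dvh import (
    CumulativeDVH,
    DoseGrid,
    DoseMetricSet,
    StructureMask,
    combine_dvhs,
    compute_cumulative_dvh,
    dose_at_volume,
    extract_metrics,
    mean_dose,
    split_target,
)
from boundarydose.errors import AlignmentError, EmptyStructureError


class TestDoseGrid:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DoseGrid(values=np.full((2, 2, 2), -1.0), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            DoseGrid(values=np.full((2, 2, 2), np.nan), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            DoseGrid(values=np.zeros((2, 2)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            DoseGrid(values=np.zeros((2, 2, 2)), spacing=(1, 0, 1))

    def test_voxel_volume(self):
        g = DoseGrid(values=np.zeros((1, 1, 1)), spacing=(2.5, 2.5, 2.5))
        assert g.voxel_volume_cc == pytest.approx(2.5**3 / 1000)


class TestComputeCumulativeDVH:
    def test_uniform_field(self, uniform_40):
        dose, mask = uniform_40
        dvh = compute_cumulative_dvh(dose, mask, bin_width=0.1)
        below = dvh.dose_edges <= 40.0
        assert np.all(dvh.volume_fraction[below] == 1.0)
        assert np.all(dvh.volume_fraction[~below] == 0.0)
        assert dvh.total_volume_cc == pytest.approx(10 * dose.voxel_volume_cc)

    def test_two_voxel_hand_count(self):
        # doses {10, 30}, bin 10: fractions 1, 1, 0.5, 0.5, 0 at 0..40
        values = np.zeros((1, 1, 3))
        values[0, 0, :2] = [10.0, 30.0]
        mask = np.array([[[True, True, False]]])
        dvh = compute_cumulative_dvh(make_grid(values), make_mask(mask), bin_width=10.0)
        np.testing.assert_allclose(dvh.dose_edges, [0, 10, 20, 30, 40])
        np.testing.assert_allclose(dvh.volume_fraction, [1.0, 1.0, 0.5, 0.5, 0.0])

    def test_empty_mask_rejected(self, uniform_40):
        dose, _ = uniform_40
        empty = make_mask(np.zeros(dose.shape, dtype=bool))
        with pytest.raises(EmptyStructureError, match="empty structure"):
            compute_cumulative_dvh(dose, empty)

    def test_misaligned_rejected(self, uniform_40):
        dose, _ = uniform_40
        other = make_mask(np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(AlignmentError, match="misaligned"):
            compute_cumulative_dvh(dose, other)

    def test_bad_bin_width(self, uniform_40):
        dose, mask = uniform_40
        with pytest.raises(ValueError):
            compute_cumulative_dvh(dose, mask, bin_width=0.0)

    def test_matches_counting_oracle_random(self, rng):
        for _ in range(25):
            dose, mask = random_case(rng)
            dvh = compute_cumulative_dvh(dose, mask, bin_width=0.5)
            expected = dvh_counting_oracle(dose.values, mask.values, dvh.dose_edges)
            np.testing.assert_array_equal(dvh.volume_fraction, expected)

    @settings(max_examples=30, deadline=None)
    @given(
        data=st.lists(st.floats(0.0, 80.0), min_size=1, max_size=40),
        bin_width=st.sampled_from([0.05, 0.1, 1.0, 7.3]),
    )
    def test_counting_oracle_property(self, data, bin_width):
        n = len(data)
        values = np.zeros((1, 1, n))
        values[0, 0, :] = data
        mask = np.ones((1, 1, n), dtype=bool)
        dvh = compute_cumulative_dvh(make_grid(values), make_mask(mask), bin_width)
        expected = dvh_counting_oracle(values, mask, dvh.dose_edges)
        np.testing.assert_array_equal(dvh.volume_fraction, expected)
        # curve covers the data: last edge strictly above the max dose
        assert dvh.dose_edges[-1] > max(data)
        assert dvh.volume_fraction[-1] == 0.0


def linear_dvh(step=0.5):
    """volume_fraction(d) = 1 - d/100 on [0, 100]."""
    edges = np.arange(0.0, 100.0 + step / 2, step)
    return CumulativeDVH(
        dose_edges=edges, volume_fraction=1.0 - edges / 100.0, total_volume_cc=100.0
    )


class TestDoseAtVolume:
    def test_uniform_plateau(self, uniform_40):
        dose, mask = uniform_40
        dvh = compute_cumulative_dvh(dose, mask, bin_width=0.1)
        assert dose_at_volume(dvh, 95) == pytest.approx(40.0, abs=0.1)

    def test_linear_curve_analytic_inverse(self):
        dvh = linear_dvh()
        assert dose_at_volume(dvh, 95) == pytest.approx(5.0, abs=1e-9)
        assert dose_at_volume(dvh, 2) == pytest.approx(98.0, abs=1e-9)

    def test_exact_inverse_on_piecewise_linear(self):
        dvh = linear_dvh(step=10.0)
        for v in (1, 2, 25, 50, 95, 99):
            d = dose_at_volume(dvh, v)
            assert np.interp(d, dvh.dose_edges, dvh.volume_fraction) == pytest.approx(
                v / 100.0, abs=1e-12
            )

    def test_monotone_in_volume_percent(self, rng):
        dose, mask = random_case(rng)
        dvh = compute_cumulative_dvh(dose, mask)
        volumes = np.linspace(1, 99, 33)
        doses = [dose_at_volume(dvh, v) for v in volumes]
        assert np.all(np.diff(doses) <= 1e-12)
        assert dose_at_volume(dvh, 2) >= dose_at_volume(dvh, 98)

    def test_never_drops_returns_max_dose(self):
        # curve floors at 0.3 > requested 5%: return max tabulated dose
        edges = np.array([0.0, 10.0, 20.0])
        frac = np.array([1.0, 0.5, 0.3])
        dvh = CumulativeDVH(dose_edges=edges, volume_fraction=frac, total_volume_cc=1.0)
        assert dose_at_volume(dvh, 5) == 20.0

    @pytest.mark.parametrize("bad", [0.0, 100.0, -3.0, 101.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            dose_at_volume(linear_dvh(), bad)


class TestMeanDose:
    def test_uniform(self, uniform_40):
        assert mean_dose(*uniform_40) == 40.0

    def test_two_point(self):
        values = np.zeros((1, 1, 2))
        values[0, 0, :] = [10.0, 30.0]
        assert mean_dose(make_grid(values), make_mask(np.ones((1, 1, 2), bool))) == 20.0

    def test_partition_identity(self, rng):
        dose, mask = random_case(rng)
        split = rng.random(dose.shape) < 0.5
        part_a = make_mask(mask.values & split, "a")
        part_b = make_mask(mask.values & ~split, "b")
        if part_a.is_empty() or part_b.is_empty():
            pytest.skip("degenerate split")
        na, nb = part_a.voxel_count, part_b.voxel_count
        combined = (na * mean_dose(dose, part_a) + nb * mean_dose(dose, part_b)) / (na + nb)
        assert combined == pytest.approx(mean_dose(dose, mask), rel=1e-12)

    def test_empty_mask(self, uniform_40):
        dose, _ = uniform_40
        with pytest.raises(EmptyStructureError):
            mean_dose(dose, make_mask(np.zeros(dose.shape, bool)))


class TestSplitTarget:
    def test_disjoint_lung(self):
        ptv = make_mask(np.array([[[1, 1, 0, 0]]], dtype=bool), "PTV")
        lung = make_mask(np.array([[[0, 0, 0, 1]]], dtype=bool), "Lung")
        ptv_lung, ptv_soft = split_target(ptv, lung)
        assert ptv_lung.is_empty()
        np.testing.assert_array_equal(ptv_soft.values, ptv.values)

    def test_ptv_inside_lung(self):
        ptv = make_mask(np.array([[[1, 1, 0, 0]]], dtype=bool), "PTV")
        lung = make_mask(np.ones((1, 1, 4), dtype=bool), "Lung")
        ptv_lung, ptv_soft = split_target(ptv, lung)
        assert ptv_soft.is_empty()
        np.testing.assert_array_equal(ptv_lung.values, ptv.values)

    def test_counts_sum(self, rng):
        for _ in range(10):
            _, ptv = random_case(rng)
            _, lung = random_case(rng)
            ptv_lung, ptv_soft = split_target(ptv, lung)
            assert ptv_lung.voxel_count + ptv_soft.voxel_count == ptv.voxel_count
            assert not (ptv_lung.values & ptv_soft.values).any()
            np.testing.assert_array_equal(
                ptv_lung.values | ptv_soft.values, ptv.values
            )


class TestCombineDVHs:
    def test_identity_with_zero_volume(self):
        dvh = linear_dvh()
        empty = CumulativeDVH(
            dose_edges=np.array([0.0, 1.0]),
            volume_fraction=np.array([1.0, 0.0]),
            total_volume_cc=0.0,
        )
        out = combine_dvhs(dvh, empty)
        np.testing.assert_array_equal(out.dose_edges, dvh.dose_edges)
        np.testing.assert_array_equal(out.volume_fraction, dvh.volume_fraction)

    def test_self_combination(self):
        dvh = linear_dvh()
        out = combine_dvhs(dvh, dvh)
        np.testing.assert_allclose(out.volume_fraction, dvh.volume_fraction, atol=1e-12)
        assert out.total_volume_cc == pytest.approx(2 * dvh.total_volume_cc)

    def test_zero_combined_volume(self):
        empty = CumulativeDVH(
            dose_edges=np.array([0.0, 1.0]),
            volume_fraction=np.array([1.0, 0.0]),
            total_volume_cc=0.0,
        )
        with pytest.raises(ValueError):
            combine_dvhs(empty, empty)

    def test_partition_identity_random(self, rng):
        # combined sub-DVHs reproduce the whole-structure DVH
        for _ in range(10):
            dose, mask = random_case(rng, shape=(6, 6, 6))
            split = rng.random(dose.shape) < 0.5
            part_a = make_mask(mask.values & split, "a")
            part_b = make_mask(mask.values & ~split, "b")
            if part_a.is_empty() or part_b.is_empty():
                continue
            bw = 0.5
            whole = compute_cumulative_dvh(dose, mask, bw)
            combined = combine_dvhs(
                compute_cumulative_dvh(dose, part_a, bw),
                compute_cumulative_dvh(dose, part_b, bw),
            )
            resampled = np.interp(
                whole.dose_edges, combined.dose_edges, combined.volume_fraction
            )
            np.testing.assert_allclose(resampled, whole.volume_fraction, atol=1e-9)
            assert combined.total_volume_cc == pytest.approx(whole.total_volume_cc)


class TestMetricSet:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            DoseMetricSet(dmean=1.0, d2=1.0, d95=2.0, d98=3.0)

    def test_extract_ordering_on_phantoms(self, rng):
        for _ in range(10):
            dose, mask = random_case(rng)
            m = extract_metrics(dose, mask)
            assert m.d2 >= m.d95 >= m.d98

    def test_empty_structure_gives_absent_metrics(self, uniform_40):
        dose, _ = uniform_40
        m = extract_metrics(dose, make_mask(np.zeros(dose.shape, bool)))
        assert m.as_dict() == {"Dmean": None, "D2": None, "D95": None, "D98": None}
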