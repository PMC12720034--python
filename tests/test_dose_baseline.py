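"""Tests of EQD2 conversion, dose geometry and the baseline correction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from t2rp.baseline import (
    baseline_correct,
    reference_mean,
    reference_mean_with_fallback,
    region_mean,
    select_reference_subvolume,
    split_lung_subvolumes,
)
from t2rp.dosimetry import compute_v20, eqd2, expand_margin
from t2rp.types import DoseGrid, QuantitativeMap

SPACING = (1.0, 1.0, 1.0)


def _dose(values, n=3, d=13.5, kind="physical", spacing=SPACING):
    return DoseGrid(np.asarray(values, dtype=float), kind, n, d, spacing)


class TestEqd2:
    def test_two_gy_per_fraction_is_identity(self):
        dg = _dose(np.full((3, 3, 3), 60.0), n=30, d=2.0)
        out = eqd2(dg, alpha_beta_gy=3.0)
        assert np.allclose(out.values, 60.0)
        assert out.kind == "eqd2"

    def test_zero_dose_maps_to_zero(self):
        out = eqd2(_dose(np.zeros((2, 2, 2))))
        assert np.all(out.values == 0)

    def test_sbrt_prescription_closed_form(self):
        """3 x 13.5 Gy at alpha/beta = 3: EQD2 = 40.5 * 16.5 / 5 = 133.65 Gy."""
        dg = _dose(np.full((2, 2, 2), 40.5), n=3, d=13.5)
        out = eqd2(dg, alpha_beta_gy=3.0)
        assert np.allclose(out.values, 133.65)

    @given(st.floats(min_value=0.1, max_value=80.0), st.floats(min_value=0.1, max_value=80.0))
    def test_monotone_in_dose_for_fixed_scheme(self, d1, d2):
        lo, hi = sorted([d1, d2])
        vals = np.array([[[lo, hi]]])
        out = eqd2(_dose(vals, n=5, d=8.0))
        assert out.values[0, 0, 0] <= out.values[0, 0, 1]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            eqd2(_dose(np.ones((2, 2, 2)), kind="physical"), alpha_beta_gy=-2.0)
        already = eqd2(_dose(np.ones((2, 2, 2))))
        with pytest.raises(ValueError):
            eqd2(already)


class TestV20:
    def test_strict_threshold(self):
        lung = np.ones((3, 3, 3), dtype=bool)
        just_below = eqd2(_dose(np.full((3, 3, 3), 19.9), n=10, d=1.99))
        just_below.values[:] = 19.9  # uniform EQD2 below threshold
        assert not compute_v20(just_below, lung).any()
        above = eqd2(_dose(np.full((3, 3, 3), 25.0), n=10, d=2.5))
        assert above.values.min() > 20.0
        assert np.array_equal(compute_v20(above, lung), lung)

    def test_matches_bruteforce_isoline_count(self, rng):
        lung = rng.random((8, 8, 8)) > 0.3
        values = rng.uniform(0.0, 60.0, size=(8, 8, 8))
        dg = DoseGrid(values, "eqd2", 3, 13.5, SPACING)
        v20 = compute_v20(dg, lung)
        brute = sum(
            1
            for i in range(8)
            for j in range(8)
            for k in range(8)
            if lung[i, j, k] and values[i, j, k] > 20.0
        )
        assert v20.sum() == brute


class TestExpandMargin:
    def test_zero_margin_is_identity(self, rng):
        mask = rng.random((6, 6, 6)) > 0.7
        mask[0, 0, 0] = True
        assert np.array_equal(expand_margin(mask, 0.0, SPACING), mask)

    def test_single_voxel_isotropic_sphere_count(self):
        """5 mm margin at 1 mm isotropic spacing: 515 voxels within radius 5."""
        mask = np.zeros((13, 13, 13), dtype=bool)
        mask[6, 6, 6] = True
        out = expand_margin(mask, 5.0, SPACING)
        # brute-force distance scan
        idx = np.argwhere(np.ones_like(mask))
        d = np.linalg.norm(idx - np.array([6, 6, 6]), axis=1)
        assert out.sum() == (d <= 5.0).sum() == 515

    def test_anisotropic_margin_stays_in_plane(self):
        """8.8 mm slices: a 5 mm margin never crosses to a neighbouring slice."""
        mask = np.zeros((9, 9, 5), dtype=bool)
        mask[4, 4, 2] = True
        out = expand_margin(mask, 5.0, (1.6, 1.6, 8.8))
        assert out[:, :, [0, 1, 3, 4]].sum() == 0
        inplane = np.argwhere(out[:, :, 2]) - np.array([4, 4])
        assert np.abs(inplane).max() == 3  # 5 / 1.6 -> +-3 voxels


def _two_box_lung(n_cc=30):
    lung = np.zeros((20, 40, 8), dtype=bool)
    lung[2:8, 5 : 5 + n_cc, 2:6] = True  # left lung
    lung[12:18, 5 : 5 + n_cc, 2:6] = True  # right lung
    return lung


class TestSubvolumes:
    def test_equal_band_split(self):
        lung = _two_box_lung(30)
        labels = split_lung_subvolumes(lung, cc_axis=1)
        assert set(np.unique(labels)) == {0, 1, 2, 3, 4, 5, 6}
        for lab in range(1, 7):
            band = labels == lab
            occupied = np.unique(np.argwhere(band)[:, 1])
            assert occupied.size == 10  # 30 slices -> three bands of 10
        # labels partition the lung exactly
        assert np.array_equal(labels > 0, lung)

    def test_band_boundaries_near_terciles(self):
        lung = _two_box_lung(31)  # not divisible by three
        labels = split_lung_subvolumes(lung, cc_axis=1)
        sizes = [np.unique(np.argwhere(labels == lab)[:, 1]).size for lab in range(1, 4)]
        assert max(sizes) - min(sizes) <= 1

    def test_wrong_component_count_reported(self):
        lung = np.zeros((10, 10, 4), dtype=bool)
        lung[2:5, 2:8, 1:3] = True
        with pytest.raises(ValueError, match="found 1"):
            split_lung_subvolumes(lung)

    def test_reference_is_contralateral_distal_band(self):
        lung = _two_box_lung(30)
        labels = split_lung_subvolumes(lung, cc_axis=1)
        gtv = np.zeros_like(lung)
        gtv[3:6, 6:9, 3:5] = True  # left lung, low cc index
        ref = select_reference_subvolume(labels, gtv, SPACING)
        assert ref == 6  # right lung, far cc band
        assert not (labels == ref)[gtv].any()

    def test_reference_matches_bruteforce_argmax(self, rng):
        lung = _two_box_lung(24)
        labels = split_lung_subvolumes(lung, cc_axis=1)
        gtv = np.zeros_like(lung)
        gtv[13:16, 7:10, 2:4] = True
        spacing = (1.7, 2.1, 8.8)
        ref = select_reference_subvolume(labels, gtv, spacing)
        gtv_c = np.argwhere(gtv).mean(axis=0) * spacing
        dists = {}
        for lab in range(1, 7):
            c = np.argwhere(labels == lab).mean(axis=0) * spacing
            dists[lab] = np.linalg.norm(c - gtv_c)
        assert ref == max(dists, key=dists.get)


class TestReferenceMean:
    def _setup(self, values):
        qmap = QuantitativeMap(values, SPACING)
        return qmap

    def test_uniform_map_returns_constant(self):
        qmap = self._setup(np.full((6, 6, 4), 30.0))
        ref = np.ones((6, 6, 4), dtype=bool)
        gtv = np.zeros_like(ref)
        gtv[2, 2, 1] = True
        assert reference_mean(qmap, ref, gtv, coronal_axis=2) == pytest.approx(30.0)

    def test_per_slice_means_weighted_equally(self):
        values = np.zeros((4, 4, 2))
        values[:, :, 0] = 10.0
        values[:, :, 1] = 20.0
        qmap = self._setup(values)
        ref = np.zeros((4, 4, 2), dtype=bool)
        ref[0:3, 0, 0] = True  # 3 voxels on slice 0
        ref[0:1, 0, 1] = True  # 1 voxel on slice 1
        gtv = np.zeros_like(ref)
        gtv[3, 3, :] = True  # GTV on both coronal slices
        assert reference_mean(qmap, ref, gtv, coronal_axis=2) == pytest.approx(15.0)

    def test_matches_bruteforce_double_loop(self, rng):
        values = rng.normal(40.0, 5.0, size=(6, 6, 5))
        valid = rng.random((6, 6, 5)) > 0.2
        qmap = QuantitativeMap(values, SPACING, valid_mask=valid)
        ref = rng.random((6, 6, 5)) > 0.5
        gtv = np.zeros((6, 6, 5), dtype=bool)
        gtv[2, 2, 1] = gtv[3, 3, 3] = True
        slice_means = []
        for k in range(5):
            if not gtv[:, :, k].any():
                continue
            sel = ref[:, :, k] & valid[:, :, k]
            if sel.any():
                slice_means.append(values[:, :, k][sel].mean())
        expected = np.mean(slice_means)
        assert reference_mean(qmap, ref, gtv, coronal_axis=2) == pytest.approx(expected)

    def test_fallback_to_next_farthest_band(self):
        lung = _two_box_lung(30)
        labels = split_lung_subvolumes(lung, cc_axis=1)
        gtv = np.zeros_like(lung)
        gtv[3:6, 6:9, 3:5] = True
        values = np.full(lung.shape, 42.0)
        # farthest band (6) invalidated entirely -> fallback must pick another
        valid = lung.copy()
        valid[labels == 6] = False
        qmap = QuantitativeMap(values, SPACING, valid_mask=valid)
        mean, used = reference_mean_with_fallback(qmap, labels, gtv, SPACING, coronal_axis=2)
        assert used != 6
        assert mean == pytest.approx(42.0)


class TestBaselineCorrect:
    def test_uniform_map_zeroed(self):
        qmap = QuantitativeMap(np.full((3, 3, 3), 17.5), SPACING)
        out = baseline_correct(qmap, 17.5)
        assert np.all(out.values == 0.0)

    def test_double_subtraction_is_additive(self, rng):
        qmap = QuantitativeMap(rng.normal(40, 5, (4, 4, 4)), SPACING)
        a = baseline_correct(baseline_correct(qmap, 3.0), 4.0)
        b = baseline_correct(qmap, 7.0)
        assert np.allclose(a.values, b.values)

    def test_histogram_is_exact_affine_shift(self, rng):
        values = rng.normal(40, 5, (5, 5, 5))
        qmap = QuantitativeMap(values, SPACING)
        out = baseline_correct(qmap, 12.25)
        assert np.array_equal(np.sort(out.values.ravel()), np.sort(values.ravel()) - 12.25)
        assert np.array_equal(out.valid_mask, qmap.valid_mask)


class TestRegionMean:
    def test_single_voxel_mask(self):
        values = np.arange(27, dtype=float).reshape(3, 3, 3)
        qmap = QuantitativeMap(values, SPACING)
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        assert region_mean(qmap, mask) == values[1, 2, 0]

    def test_empty_mask_rejected(self):
        qmap = QuantitativeMap(np.ones((3, 3, 3)), SPACING)
        with pytest.raises(ValueError):
            region_mean(qmap, np.zeros((3, 3, 3), dtype=bool))

    def test_matches_bruteforce_sum_count(self, rng):
        values = rng.normal(size=(6, 6, 6))
        valid = rng.random((6, 6, 6)) > 0.3
        mask = rng.random((6, 6, 6)) > 0.5
        qmap = QuantitativeMap(values, SPACING, valid_mask=valid)
        eff = mask & valid
        assert region_mean(qmap, mask) == pytest.approx(values[eff].sum() / eff.sum())
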