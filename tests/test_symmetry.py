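"""ROI extraction, mirror transform, differential map and thresholding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hemitherm import (
    MatrixKind,
    ROISpec,
    TemperatureMatrix,
    ThermalFrame,
    ThresholdPolicy,
    asymmetry_summary,
    differential_map,
    extract_roi,
    mirror_matrix,
    split_hemifaces,
    threshold_map,
)
from hemitherm.errors import (
    DimensionMismatchError,
    EmptyDataError,
    MatrixKindError,
    RoiBoundsError,
    ThresholdError,
)


def tm(values, kind=MatrixKind.DIFFERENTIAL):
    return TemperatureMatrix(np.asarray(values, float), kind)


finite_matrices = arrays(
    dtype=float,
    shape=st.tuples(st.integers(1, 64), st.integers(1, 64)),
    elements=st.floats(-10, 10, allow_nan=False),
)


class TestExtractRoi:
    def test_published_geometry(self):
        # full camera resolution 1024×768 (width×height), published ROI 350×250
        frame = ThermalFrame(np.full((768, 1024), 33.0))
        roi = ROISpec(top=100, left=200, height=350, width=250)
        M = extract_roi(frame, roi, MatrixKind.HEALTHY)
        assert M.shape == (350, 250)

    def test_values_are_offset_indexed(self, rng):
        temps = rng.uniform(30, 36, size=(8, 9))
        frame = ThermalFrame(temps)
        M = extract_roi(frame, ROISpec(2, 3, 4, 5), MatrixKind.DISEASED)
        np.testing.assert_array_equal(M.values, temps[2:6, 3:8])
        assert M.kind is MatrixKind.DISEASED

    def test_whole_frame_identity(self):
        temps = np.linspace(30, 36, 12).reshape(3, 4)
        M = extract_roi(ThermalFrame(temps), ROISpec(0, 0, 3, 4), MatrixKind.HEALTHY)
        np.testing.assert_array_equal(M.values, temps)

    def test_off_by_one_overhang_rejected(self):
        frame = ThermalFrame(np.full((5, 5), 33.0))
        with pytest.raises(RoiBoundsError, match="overhangs"):
            extract_roi(frame, ROISpec(1, 0, 5, 5), MatrixKind.HEALTHY)

    def test_zero_area_roi_rejected(self):
        with pytest.raises(RoiBoundsError):
            ROISpec(0, 0, 0, 3)


class TestMirror:
    def test_index_reversal(self):
        M = tm([[1, 2, 3], [4, 5, 6]])
        np.testing.assert_array_equal(mirror_matrix(M).values, [[3, 2, 1], [6, 5, 4]])

    def test_single_column_fixed_point(self):
        M = tm([[7], [8]])
        np.testing.assert_array_equal(mirror_matrix(M).values, [[7], [8]])

    def test_kind_flips_between_healthy_and_mirrored(self):
        M = tm(np.full((2, 2), 33.0), MatrixKind.HEALTHY)
        assert mirror_matrix(M).kind is MatrixKind.MIRRORED_HEALTHY
        assert mirror_matrix(mirror_matrix(M)).kind is MatrixKind.HEALTHY

    @given(finite_matrices)
    def test_involution(self, values):
        M = tm(values)
        np.testing.assert_array_equal(mirror_matrix(mirror_matrix(M)).values, M.values)


class TestDifferential:
    def test_direct_arithmetic(self):
        D = tm([[37.2, 33.0]], MatrixKind.DISEASED)
        H = tm([[33.0, 34.0]], MatrixKind.HEALTHY)
        R = differential_map(D, H)
        np.testing.assert_allclose(R.values, [[3.2, 0.0]], atol=1e-12)
        assert R.kind is MatrixKind.DIFFERENTIAL

    def test_perfect_thermal_symmetry_gives_zero(self, rng):
        H = tm(rng.uniform(30, 36, (5, 7)), MatrixKind.HEALTHY)
        D = TemperatureMatrix(H.values[:, ::-1].copy(), MatrixKind.DISEASED)
        np.testing.assert_array_equal(differential_map(D, H).values, 0.0)

    def test_invalid_pixel_propagates(self):
        D = tm([[37.2, np.nan]], MatrixKind.DISEASED)
        H = tm([[33.0, 34.0]], MatrixKind.HEALTHY)
        R = differential_map(D, H)
        assert np.isnan(R.values[0, 1])
        assert R.values[0, 0] == pytest.approx(3.2)

    def test_shape_mismatch_names_both_shapes(self):
        D = tm(np.full((2, 3), 34.0), MatrixKind.DISEASED)
        H = tm(np.full((2, 4), 33.0), MatrixKind.HEALTHY)
        with pytest.raises(DimensionMismatchError, match=r"2×3.*2×4"):
            differential_map(D, H)

    def test_kind_contract_enforced(self):
        A = tm(np.full((2, 2), 33.0), MatrixKind.HEALTHY)
        with pytest.raises(MatrixKindError):
            differential_map(A, A)

    @given(finite_matrices, st.floats(-5, 5, allow_nan=False))
    def test_linearity_in_constant_shift(self, values, c):
        H = tm(np.zeros_like(values) + 33.0, MatrixKind.HEALTHY)
        D1 = tm(values + 33.0, MatrixKind.DISEASED)
        D2 = tm(values + 33.0 + c, MatrixKind.DISEASED)
        R1 = differential_map(D1, H).values
        R2 = differential_map(D2, H).values
        np.testing.assert_allclose(R2, R1 + c, atol=1e-9)


class TestThreshold:
    def test_strict_comparison(self):
        R = tm([[3.2, 0.0], [2.9, -1.0]])
        out = threshold_map(R, ThresholdPolicy(3.0))
        np.testing.assert_array_equal(out.values, [[3.2, 0.0], [0.0, 0.0]])
        assert out.kind is MatrixKind.THRESHOLDED

    def test_value_equal_to_cutoff_survives(self):
        out = threshold_map(tm([[3.0, 2.999999]]), ThresholdPolicy(3.0))
        np.testing.assert_array_equal(out.values, [[3.0, 0.0]])

    def test_cutoff_above_max_zeroes_everything(self):
        out = threshold_map(tm([[1.0, 2.5]]), ThresholdPolicy(5.0))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ThresholdError):
            ThresholdPolicy(0.0)
        with pytest.raises(ThresholdError):
            ThresholdPolicy(-2.0)

    def test_invalid_pixels_stay_invalid(self):
        out = threshold_map(tm([[np.nan, 4.0]]), ThresholdPolicy(3.0))
        assert np.isnan(out.values[0, 0]) and out.values[0, 1] == 4.0

    @given(finite_matrices, st.floats(0.1, 8.0, allow_nan=False))
    def test_no_output_value_in_open_gap(self, values, thr):
        out = threshold_map(tm(values), ThresholdPolicy(thr)).values
        assert not np.any((out > 0) & (out < thr))

    @given(finite_matrices)
    def test_nonzero_count_monotone_in_threshold(self, values):
        R = tm(values)
        counts = [
            int((threshold_map(R, ThresholdPolicy(t)).values > 0).sum())
            for t in (0.5, 1.0, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSplitHemifaces:
    def test_symmetric_offsets_half_open(self):
        temps = np.tile(np.arange(10, dtype=float), (4, 1)) + 30.0
        frame = ThermalFrame(temps)
        d, h = split_hemifaces(frame, axis_col=5, roi_height=4, roi_width=3)
        np.testing.assert_array_equal(d.values, temps[:, 2:5])  # left cols [2,5)
        np.testing.assert_array_equal(h.values, temps[:, 5:8])  # right cols [5,8)

    def test_mirror_symmetric_frame_gives_zero_differential(self, rng):
        half = rng.uniform(30, 36, size=(6, 5))
        frame = ThermalFrame(np.hstack([half, half[:, ::-1]]))
        d, h = split_hemifaces(frame, axis_col=5, roi_height=6, roi_width=4)
        np.testing.assert_array_equal(differential_map(d, h).values, 0.0)

    def test_overhang_rejected(self):
        frame = ThermalFrame(np.full((4, 10), 33.0))
        with pytest.raises(RoiBoundsError):
            split_hemifaces(frame, axis_col=1, roi_height=4, roi_width=3)
        with pytest.raises(RoiBoundsError):
            split_hemifaces(frame, axis_col=9, roi_height=4, roi_width=3)

    def test_two_profile_and_split_modes_agree(self, rng):
        # a frontal frame built by abutting the two profile ROIs reproduces
        # the two-profile differential exactly
        left_profile = rng.uniform(30, 36, size=(5, 4))
        right_profile = rng.uniform(30, 36, size=(5, 4))
        D2 = tm(left_profile, MatrixKind.DISEASED)
        H2 = tm(right_profile, MatrixKind.HEALTHY)
        two_profile = differential_map(D2, H2).values

        frame = ThermalFrame(np.hstack([left_profile, right_profile]))
        d, h = split_hemifaces(frame, axis_col=4, roi_height=5, roi_width=4)
        np.testing.assert_array_equal(differential_map(d, h).values, two_profile)


class TestAsymmetrySummary:
    def test_counting_example(self):
        s = asymmetry_summary(tm([[3.2, 0.0], [0.0, 0.0]]), thresholds=(2.0, 3.0))
        assert s["max_delta_t_C"] == pytest.approx(3.2)
        assert s["counts_ge"] == {2.0: 1, 3.0: 1}
        assert s["n_valid"] == 4

    def test_all_zero(self):
        s = asymmetry_summary(tm(np.zeros((3, 3))), thresholds=(2.0,))
        assert s["max_delta_t_C"] == 0.0
        assert s["counts_ge"][2.0] == 0

    def test_invalid_pixels_excluded(self):
        s = asymmetry_summary(tm([[np.nan, 4.0]]), thresholds=(3.0,))
        assert s["n_valid"] == 1
        assert s["mean_delta_t_C"] == pytest.approx(4.0)

    def test_all_invalid_raises(self):
        with pytest.raises(EmptyDataError):
            asymmetry_summary(tm([[np.nan]]))

    def test_wrong_kind_rejected(self):
        with pytest.raises(MatrixKindError):
            asymmetry_summary(tm(np.zeros((2, 2)), MatrixKind.HEALTHY))
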