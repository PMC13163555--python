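"""Unit and property tests of the Gradient-DDP feature pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from graddp.gradient_ddp import (
    FeatureConfig,
    block_statistics,
    circular_mean,
    compute_gradient,
    extract_slice_features,
    gradient_direction,
    gradient_magnitude,
    histogram_features,
    normalize_vector,
    quantize,
    quantize_scalar_reference,
)


class TestComputeGradient:
    def test_constant_slice_gives_zero_fields(self):
        g = compute_gradient(np.full((6, 7), 3.5))
        assert np.all(g.gx == 0) and np.all(g.gy == 0)
        assert np.all(g.gmag == 0)
        assert np.all(g.gdir == 0)  # atan2(0, 0) convention

    def test_affine_image_recovered_exactly(self):
        # I(x, y) = 2x + 3y with x = column, y = row: both central and
        # one-sided first differences are exact on affine images
        yy, xx = np.mgrid[0:5, 0:5]
        g = compute_gradient(2.0 * xx + 3.0 * yy)
        assert np.array_equal(g.gx, np.full((5, 5), 2.0))
        assert np.array_equal(g.gy, np.full((5, 5), 3.0))

    def test_additive_shift_leaves_field_unchanged(self, rng):
        img = rng.normal(size=(12, 9))
        g0, g1 = compute_gradient(img), compute_gradient(img + 7.3)
        np.testing.assert_allclose(g1.gx, g0.gx, atol=1e-12)
        np.testing.assert_allclose(g1.gy, g0.gy, atol=1e-12)

    def test_magnitude_consistency_invariant(self, rng):
        g = compute_gradient(rng.normal(size=(10, 10)))
        np.testing.assert_allclose(g.gmag**2, g.gx**2 + g.gy**2, atol=1e-12)
        assert np.all(g.gmag >= 0)
        assert np.all((g.gdir > -np.pi) & (g.gdir <= np.pi))

    @pytest.mark.parametrize("bad", [np.zeros((1, 5)), np.zeros((5, 1))])
    def test_one_pixel_wide_input_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_gradient(bad)

    def test_non_finite_input_rejected(self):
        img = np.ones((4, 4))
        img[2, 2] = np.nan
        with pytest.raises(ValueError):
            compute_gradient(img)


class TestMagnitudeDirection:
    def test_three_four_five(self):
        assert gradient_magnitude(np.array([3.0]), np.array([4.0]))[0] == 5.0
        assert gradient_magnitude(np.array([0.0]), np.array([0.0]))[0] == 0.0

    def test_magnitude_invariant_to_sign_flips(self, rng):
        gx, gy = rng.normal(size=(2, 8, 8))
        ref = gradient_magnitude(gx, gy)
        for sx in (1, -1):
            for sy in (1, -1):
                np.testing.assert_array_equal(gradient_magnitude(sx * gx, sy * gy), ref)

    @pytest.mark.parametrize(
        "gx,gy,expected",
        [(1.0, 0.0, 0.0), (0.0, 1.0, np.pi / 2), (-1.0, 0.0, np.pi)],
    )
    def test_direction_cardinal_angles(self, gx, gy, expected):
        assert gradient_direction(np.array([gx]), np.array([gy]))[0] == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.zeros((2, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            gradient_direction(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_direction_invariant_to_positive_scaling(self, rng):
        img = rng.normal(size=(9, 9))
        g0, g1 = compute_gradient(img), compute_gradient(3.7 * img)
        np.testing.assert_allclose(g1.gdir, g0.gdir, atol=1e-12)


class TestBlockStatistics:
    def test_single_block_arithmetic_oracle(self):
        gmag = np.arange(9, dtype=float).reshape(3, 3)
        theta = 0.7
        raw = block_statistics(gmag, np.full((3, 3), theta))
        assert raw.b[0] == pytest.approx(4.0)       # mean of 0..8
        assert raw.b[1] == pytest.approx(60 / 9)    # population variance
        assert raw.b[2] == pytest.approx(theta)     # circular mean of constant

    def test_constant_magnitude_has_zero_variance(self):
        raw = block_statistics(np.full((3, 3), 2.5), np.zeros((3, 3)))
        assert raw.b[1] == 0.0

    @pytest.mark.parametrize("delta", [0.1, 0.8, 1.4])
    def test_circular_mean_symmetry(self, delta):
        angles = np.array([np.pi / 2 - delta, np.pi / 2 + delta])
        assert circular_mean(angles) == pytest.approx(np.pi / 2)

    def test_circular_mean_handles_wraparound(self):
        # arithmetic mean of (pi - 0.1, -pi + 0.1) is 0; circular mean is pi
        angles = np.array([np.pi - 0.1, -np.pi + 0.1])
        assert abs(circular_mean(angles)) == pytest.approx(np.pi)

    def test_trailing_rows_discarded_and_row_major_order(self, rng):
        gmag = rng.uniform(size=(7, 8))  # 2x2 grid of 3x3 blocks, remainder dropped
        gdir = rng.uniform(-np.pi, np.pi, size=(7, 8))
        raw = block_statistics(gmag, gdir)
        assert raw.b.size == 3 * 4
        # second block (row-major) covers rows 0:3, cols 3:6
        assert raw.b[3] == pytest.approx(gmag[0:3, 3:6].mean())

    def test_summary_scalars_bracket_the_vector(self, rng):
        raw = block_statistics(rng.uniform(size=(9, 9)), rng.uniform(-3, 3, size=(9, 9)))
        assert raw.bmin <= raw.mu <= raw.bmax

    def test_image_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            block_statistics(np.zeros((2, 5)), np.zeros((2, 5)), block_size=3)


class TestNormalizeVector:
    def test_minmax_example(self):
        np.testing.assert_array_equal(normalize_vector([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0])

    def test_constant_vector_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_vector([4.2] * 5), np.zeros(5))

    def test_idempotence(self, rng):
        for _ in range(100):
            b = rng.normal(size=rng.integers(2, 40))
            once = normalize_vector(b)
            np.testing.assert_allclose(normalize_vector(once), once, atol=1e-15)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize_vector([])


class TestQuantizer:
    def test_anchor_codes(self, rng):
        b = np.array([0.0, 1.0, 0.5, 0.2, 0.8])  # mean 0.5 distinct from min/max
        for mode in ("literal", "monotone"):
            codes = quantize(b, mode=mode).codes
            assert codes[0] == 0   # bmin
            assert codes[1] == 1   # bmax
            assert codes[2] == 6   # mu

    def test_vectorized_matches_scalar_reference(self, rng):
        for mode in ("literal", "monotone"):
            for _ in range(200):
                b = rng.normal(size=int(rng.integers(2, 60)))
                np.testing.assert_array_equal(
                    quantize(b, mode=mode).codes, quantize_scalar_reference(b, mode=mode)
                )

    def test_totality_all_codes_in_range(self, rng):
        for mode in ("literal", "monotone"):
            for _ in range(50):
                b = rng.uniform(-100, 100, size=30)
                codes = quantize(b, mode=mode).codes
                assert codes.shape == b.shape
                assert np.all((codes >= 0) & (codes <= 10))

    def test_monotone_mode_order_preserving_between_anchors(self):
        # strictly increasing values between bmin and mu (and mu and bmax)
        # must receive non-decreasing codes in monotone mode
        b = np.linspace(0, 1, 41)
        codes = quantize(b, mode="monotone").codes
        mu = b.mean()
        inner_low = codes[(b > 0) & (b < mu)]
        inner_high = codes[(b > mu) & (b < 1)]
        assert np.all(np.diff(inner_low) >= 0)
        assert np.all(np.diff(inner_high) >= 0)

    def test_literal_mode_nonmatching_entries_fall_back_to_10(self):
        # negative-mean vectors push the printed upper cut points below mu,
        # so some entries above mu match no printed rule
        b = np.array([-10.0, -9.0, -8.0, -1.0])
        codes = quantize(b, mode="literal").codes
        ref = quantize_scalar_reference(b, mode="literal")
        np.testing.assert_array_equal(codes, ref)
        assert np.all((codes >= 0) & (codes <= 10))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            quantize([0.0, 1.0], mode="bogus")


class TestHistogramFeatures:
    def test_all_zero_codes_concentrate_in_first_bin(self):
        hist = histogram_features(np.zeros(20, dtype=int))
        assert hist[0] == 1.0 and hist[1:].sum() == 0.0

    def test_each_code_lands_in_its_bin(self):
        hist = histogram_features(np.arange(11))
        expected_bins = [min(int(c * 16 / 10), 15) for c in range(11)]
        nz = np.flatnonzero(hist)
        np.testing.assert_array_equal(nz, sorted(set(expected_bins)))
        np.testing.assert_allclose(hist[nz], 1 / 11)

    def test_sums_to_one(self, rng):
        for _ in range(20):
            codes = rng.integers(0, 11, size=rng.integers(1, 200))
            assert histogram_features(codes).sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            histogram_features([])


class TestFullPipeline:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        img=hnp.arrays(np.float64, (9, 9), elements=st.floats(-50, 50)),
        shift=st.floats(-1000, 1000),
    )
    def test_additive_shift_invariance(self, img, shift):
        f0 = extract_slice_features(img)
        f1 = extract_slice_features(img + shift)
        np.testing.assert_allclose(f1.hist, f0.hist, atol=1e-12)

    def test_output_shape_and_normalization(self, rng):
        fv = extract_slice_features(rng.uniform(size=(32, 32)))
        assert fv.hist.shape == (16,)
        assert fv.hist.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fv.hist >= 0)

    def test_deterministic_on_fixed_input(self, rng):
        img = rng.uniform(size=(24, 24))
        a = extract_slice_features(img)
        b = extract_slice_features(img)
        np.testing.assert_array_equal(a.hist, b.hist)

    def test_normalized_histogram_domain_option(self, rng):
        img = rng.uniform(size=(24, 24))
        cfg = FeatureConfig(histogram_domain="normalized")
        fv = extract_slice_features(img, config=cfg)
        assert fv.hist.shape == (16,)
        assert fv.hist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_provenance_records_method_and_mode(self, rng):
        fv = extract_slice_features(rng.uniform(size=(12, 12)), provenance={"subject_id": "s1"})
        assert fv.provenance["method"] == "gradient-ddp"
        assert fv.provenance["quantizer_mode"] == "literal"
        assert fv.provenance["subject_id"] == "s1"
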