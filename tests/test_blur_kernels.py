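import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoderm.blur_kernels import (
    DERIVATIVE_LIKE,
    SMOOTHING,
    FilterBankSpec,
    InvalidParameterError,
    Kernel,
    MotionBlurSpec,
    apply_kernel,
    make_filter,
    make_motion_psf,
)


class TestMotionPSF:
    def test_unit_length_is_identity(self):
        k = make_motion_psf(MotionBlurSpec(1, 37.0))
        assert k.coefficients.shape == (1, 1)
        assert k.coefficients[0, 0] == 1.0

    def test_axis_aligned_line_is_uniform(self):
        # a length-9 horizontal motion spreads exposure evenly over 9 pixels
        k = make_motion_psf(MotionBlurSpec(9, 0))
        assert k.coefficients.shape == (1, 9)
        np.testing.assert_allclose(k.coefficients, 1.0 / 9.0)

    def test_vertical_line_is_uniform_column(self):
        k = make_motion_psf(MotionBlurSpec(9, 90))
        assert k.coefficients.shape == (9, 1)
        np.testing.assert_allclose(k.coefficients, 1.0 / 9.0)

    def test_tilted_support_matches_line_geometry(self):
        # the support must span ceil(19 cos 3 deg) columns and sum to 1
        k = make_motion_psf(MotionBlurSpec(19, 3))
        assert k.coefficients.shape[1] == int(np.ceil(19 * np.cos(np.radians(3))))
        assert k.coefficients.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(k.coefficients >= 0)

    def test_point_reflection_symmetry(self):
        # rotating the motion direction by 180 degrees reflects the PSF
        for length, theta in [(19, 3), (12, 47), (30, 88), (9, 1)]:
            a = make_motion_psf(MotionBlurSpec(length, theta)).coefficients
            b = make_motion_psf(MotionBlurSpec(length, theta + 180)).coefficients
            np.testing.assert_allclose(a, b[::-1, ::-1], atol=1e-12)

    @pytest.mark.parametrize("length,theta", [(0.5, 0), (np.nan, 0), (9, np.inf)])
    def test_invalid_parameters_rejected(self, length, theta):
        with pytest.raises(InvalidParameterError):
            make_motion_psf(MotionBlurSpec(length, theta))

    @given(
        length=st.floats(min_value=1.0, max_value=100.0),
        theta=st.floats(min_value=0.0, max_value=360.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_normalization_property(self, length, theta):
        k = make_motion_psf(MotionBlurSpec(length, theta))
        assert k.kind == SMOOTHING
        assert abs(k.coefficients.sum() - 1.0) < 1e-9
        assert np.all(k.coefficients >= 0)


class TestFilterBank:
    def test_average_is_uniform(self):
        k = make_filter(FilterBankSpec(type=1, hsize=3))
        np.testing.assert_allclose(k.coefficients, np.full((3, 3), 1 / 9))

    def test_gaussian_is_normalized_centered_symmetric(self):
        k = make_filter(FilterBankSpec(type=3, hsize=7, sigma=0.5)).coefficients
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert k[3, 3] == k.max()
        np.testing.assert_allclose(k, np.rot90(k))

    def test_laplacian_sums_to_zero(self):
        k = make_filter(FilterBankSpec(type=4, alpha=0.2))
        assert k.kind == DERIVATIVE_LIKE
        assert k.coefficients.shape == (3, 3)
        assert k.coefficients.sum() == pytest.approx(0.0, abs=1e-12)

    def test_log_sums_to_zero(self):
        k = make_filter(FilterBankSpec(type=5, hsize=9, sigma=0.5))
        assert k.coefficients.sum() == pytest.approx(0.0, abs=1e-12)

    def test_unsharp_sums_to_one(self):
        k = make_filter(FilterBankSpec(type=8, alpha=0.3))
        assert k.kind == DERIVATIVE_LIKE
        assert k.coefficients.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_type_rejected(self):
        with pytest.raises(InvalidParameterError):
            FilterBankSpec(type=9)

    @given(
        type_=st.integers(min_value=1, max_value=8),
        hsize=st.sampled_from([3, 5, 7, 9, 11, 13, 15]),
        radius=st.floats(min_value=1.0, max_value=10.0),
        sigma=st.floats(min_value=0.1, max_value=1.0),
        alpha=st.floats(min_value=0.1, max_value=1.0),
        length=st.floats(min_value=9.0, max_value=100.0),
        theta=st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_kernel_normalization_classes(self, type_, hsize, radius, sigma, alpha, length, theta):
        # smoothing families sum to 1, derivative-like to their analytic total
        k = make_filter(
            FilterBankSpec(type_, hsize, radius, sigma, alpha, length, theta)
        )
        total = k.coefficients.sum()
        if k.kind == SMOOTHING:
            assert abs(total - 1.0) < 1e-9
            assert np.all(k.coefficients >= 0)
        else:
            expected = 1.0 if type_ == 8 else 0.0
            assert abs(total - expected) < 1e-9


class TestApplyKernel:
    def test_flat_field_preserved_by_smoothing(self):
        image = np.full((32, 32), 0.4)
        for spec in [FilterBankSpec(1, hsize=5), FilterBankSpec(3, hsize=7, sigma=0.8)]:
            out = apply_kernel(image, make_filter(spec))
            np.testing.assert_allclose(out, 0.4, atol=1e-12)

    def test_identity_kernel_is_noop(self, rng):
        image = rng.uniform(size=(20, 20))
        out = apply_kernel(image, Kernel(np.array([[1.0]]), SMOOTHING))
        np.testing.assert_allclose(out, image)

    def test_impulse_response_reproduces_kernel(self):
        image = np.zeros((31, 31))
        image[15, 15] = 1.0
        k = make_motion_psf(MotionBlurSpec(9, 0))
        out = apply_kernel(image, k)
        np.testing.assert_allclose(out[15, 11:20], 1.0 / 9.0, atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_color_images_filtered_channelwise(self, rng):
        image = rng.uniform(size=(24, 24, 3))
        k = make_filter(FilterBankSpec(1, hsize=3))
        out = apply_kernel(image, k)
        for c in range(3):
            np.testing.assert_allclose(out[..., c], apply_kernel(image[..., c], k))

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            apply_kernel(np.zeros((5, 5)), make_motion_psf(MotionBlurSpec(9, 0)))

    def test_mean_preserved_under_smoothing(self, rng):
        # symmetric padding keeps the global mean of a smoothing output close
        image = rng.uniform(size=(64, 64))
        out = apply_kernel(image, make_filter(FilterBankSpec(3, hsize=5, sigma=0.8)), clip=False)
        assert abs(out.mean() - image.mean()) < 1e-3

    def test_blur_monotone_in_length(self, lesion_image):
        # total variation of the blurred image is non-increasing in length
        gray = lesion_image.mean(axis=-1)
        tv = []
        for length in [9, 19, 29, 49]:
            b = apply_kernel(gray, make_motion_psf(MotionBlurSpec(length, 0)))
            tv.append(np.abs(np.diff(b, axis=1)).sum() + np.abs(np.diff(b, axis=0)).sum())
        assert all(t2 <= t1 for t1, t2 in zip(tv, tv[1:]))
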