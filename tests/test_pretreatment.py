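"""Exactness and invariance of the eight spectral pretreatments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirmold import (
    PretreatmentSpec,
    apply_pretreatment,
    cwt_transform,
    de_bias,
    detrend,
    min_max,
    msc_apply,
    msc_fit,
    pretreat_sets,
    sg_derivative,
    snv,
)
from nirmold.pretreatment import METHODS, _mexican_hat_kernel


class TestSnv:
    def test_simple_row(self):
        np.testing.assert_allclose(snv([[1.0, 2.0, 3.0]]), [[-1.0, 0.0, 1.0]])

    def test_rows_standardized(self, rng):
        out = snv(rng.normal(size=(5, 40)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="row 1"):
            snv([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])


class TestDeBias:
    def test_examples(self):
        np.testing.assert_allclose(de_bias([[1.0, 2.0, 3.0]]), [[-1, 0, 1]])
        np.testing.assert_allclose(de_bias([[7.0, 7.0, 7.0]]), [[0, 0, 0]])

    def test_idempotent_on_zero_mean_rows(self, rng):
        x = rng.normal(size=(3, 20))
        centred = de_bias(x)
        np.testing.assert_allclose(de_bias(centred), centred, atol=1e-12)


class TestDetrend:
    def test_exact_polynomial_removed(self):
        lam = np.linspace(890, 1720, 50)
        quad = (2.0 + 0.003 * lam + 1e-6 * lam**2)[None, :]
        np.testing.assert_allclose(detrend(quad, 2, lam), 0.0, atol=1e-9)
        line = (1.0 - 0.002 * lam)[None, :]
        np.testing.assert_allclose(detrend(line, 2, lam), 0.0, atol=1e-9)

    def test_residual_orthogonal_to_basis(self, rng):
        # oracle: direct least-squares fit on the raw Vandermonde basis
        lam = np.linspace(890, 1720, 80)
        x = rng.normal(size=(6, 80))
        resid = detrend(x, 2, lam)
        basis = np.vander((lam - lam.mean()) / 415.0, 3, increasing=True)
        np.testing.assert_allclose(resid @ basis, 0.0, atol=1e-8)
        coef, *_ = np.linalg.lstsq(basis, x.T, rcond=None)
        np.testing.assert_allclose(resid, x - (basis @ coef).T, atol=1e-9)

    def test_order_must_be_below_length(self):
        with pytest.raises(ValueError, match="order"):
            detrend(np.ones((1, 3)), order=3)


class TestMinMax:
    def test_examples(self):
        np.testing.assert_allclose(min_max([[2.0, 4.0, 6.0]]), [[0, 0.5, 1]])

    def test_range_exact(self, rng):
        out = min_max(rng.normal(size=(4, 30)))
        np.testing.assert_allclose(out.min(axis=1), 0.0, atol=1e-15)
        np.testing.assert_allclose(out.max(axis=1), 1.0, atol=1e-15)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="row 0"):
            min_max([[3.0, 3.0, 3.0]])


class TestSgDerivative:
    def test_linear_row_gives_slope_per_nm(self):
        lam = np.linspace(890, 1720, 100)
        step = lam[1] - lam[0]
        row = (0.4 + 0.002 * lam)[None, :]
        d1 = sg_derivative(row, 1, window=15, polyorder=2, delta=step)
        np.testing.assert_allclose(d1[0, 7:-7], 0.002, atol=1e-9)

    def test_quadratic_second_derivative_constant(self):
        lam = np.linspace(890, 1720, 100)
        step = lam[1] - lam[0]
        row = (1e-5 * lam**2)[None, :]
        d2 = sg_derivative(row, 2, window=15, polyorder=3, delta=step)
        np.testing.assert_allclose(d2[0, 7:-7], 2e-5, atol=1e-9)

    def test_constant_row_is_zero(self):
        row = np.full((1, 60), 3.7)
        for order in (1, 2):
            np.testing.assert_allclose(sg_derivative(row, order), 0.0,
                                       atol=1e-10)

    @pytest.mark.parametrize("kwargs, match", [
        ({"order": 3}, "order"),
        ({"order": 1, "window": 14}, "odd"),
        ({"order": 1, "window": 201}, "exceeds"),
        ({"order": 1, "window": 5, "polyorder": 5}, "polyorder"),
        ({"order": 2, "window": 5, "polyorder": 1}, "<= polyorder"),
    ])
    def test_precondition_violations_named(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            sg_derivative(np.ones((1, 60)), **kwargs)


class TestCwt:
    def test_constant_maps_to_zero(self):
        out = cwt_transform(np.full((2, 80), 5.0), scale=6.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_linearity(self, rng):
        x, z = rng.normal(size=(2, 1, 90))
        lhs = cwt_transform(2.5 * x - 1.5 * z, scale=5.0)
        rhs = 2.5 * cwt_transform(x, scale=5.0) - 1.5 * cwt_transform(z, scale=5.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_peak_response_maximal_near_centre(self):
        # oracle: dense numerical convolution of the reflected signal
        idx = np.arange(200, dtype=float)
        peak = np.exp(-((idx - 120.0) ** 2) / (2 * 8.0**2))[None, :]
        out = cwt_transform(peak, scale=8.0)
        assert abs(int(np.argmax(np.abs(out[0]))) - 120) <= 2
        kernel = _mexican_hat_kernel(8.0)
        padded = np.concatenate([peak[0][::-1], peak[0], peak[0][::-1]])
        dense = np.convolve(padded, kernel[::-1], mode="same")[200:400]
        np.testing.assert_allclose(out[0], dense, atol=1e-9)

    def test_invalid_scale_and_wavelet(self):
        with pytest.raises(ValueError, match="scale"):
            cwt_transform(np.ones((1, 50)), scale=0.5)
        with pytest.raises(ValueError, match="wavelet"):
            cwt_transform(np.ones((1, 50)), scale=5.0, wavelet="morlet")


class TestMsc:
    def test_reference_is_mean(self, rng):
        r = rng.normal(size=20)
        ref = msc_fit(np.vstack([r, 3 * r]))
        np.testing.assert_allclose(ref.reference_spectrum, 2 * r)

    def test_fixed_point_and_affine_inversion(self, rng):
        r = np.abs(rng.normal(size=30)) + 1.0
        ref = msc_fit(r[None, :])
        np.testing.assert_allclose(msc_apply(r[None, :], ref)[0], r, atol=1e-9)
        np.testing.assert_allclose(msc_apply((2 * r + 3)[None, :], ref)[0], r,
                                   atol=1e-9)

    def test_random_distortion_recovered(self, rng):
        r = np.sin(np.linspace(0, 3, 50)) + 2.0
        ref = msc_fit(r[None, :])
        gains = rng.uniform(0.5, 2.0, size=8)
        offsets = rng.normal(0, 0.5, size=8)
        distorted = gains[:, None] * r + offsets[:, None]
        np.testing.assert_allclose(msc_apply(distorted, ref),
                                   np.tile(r, (8, 1)), atol=1e-9)

    def test_uncorrelated_row_rejected(self):
        ref = msc_fit(np.linspace(0, 1, 20)[None, :])
        with pytest.raises(ValueError, match="row 0"):
            msc_apply(np.zeros((1, 20)), ref)


class TestDispatcher:
    def test_none_is_identity(self, rng):
        x = rng.normal(size=(4, 25))
        (out,), state = apply_pretreatment(PretreatmentSpec("none"), x)
        np.testing.assert_array_equal(out, x)
        assert state is None

    def test_msc_uses_calibration_reference_for_test_rows(self, rng):
        cal = np.abs(rng.normal(size=(10, 30))) + 1.0
        test = np.abs(rng.normal(size=(4, 30))) + 1.0
        (cal_t, test_t), state = apply_pretreatment(
            PretreatmentSpec("msc"), cal, test)
        np.testing.assert_allclose(state.reference_spectrum, cal.mean(axis=0))
        # correcting test rows against their own mean gives a different answer
        own = msc_apply(test, msc_fit(test))
        assert not np.allclose(test_t, own)

    @pytest.mark.parametrize("method", METHODS)
    def test_every_method_finite_same_shape(self, method, small_dataset):
        data, _ = small_dataset
        cal = data.subset(range(0, 60))
        test = data.subset(range(60, 80))
        (cal_t, test_t), _ = pretreat_sets(PretreatmentSpec(method), cal, test)
        for out, src in ((cal_t, cal), (test_t, test)):
            assert out.absorbance.shape == src.absorbance.shape
            assert np.all(np.isfinite(out.absorbance))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PretreatmentSpec("osc")

    def test_aliases_canonicalized(self):
        assert PretreatmentSpec("DT").method == "detrend"
        assert PretreatmentSpec("Min-Max").method == "min-max"


class TestInvariances:
    @given(st.floats(-5, 5), st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_snv_minmax_affine_invariant(self, a, b):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(3, 40))
        distorted = a + b * x
        np.testing.assert_allclose(snv(distorted), snv(x), atol=1e-9)
        np.testing.assert_allclose(min_max(distorted), min_max(x), atol=1e-9)

    def test_msc_then_snv_near_idempotent(self, rng):
        r = np.sin(np.linspace(0, 4, 60)) + 3.0
        gains = rng.uniform(0.8, 1.2, size=6)
        offsets = rng.normal(0, 0.2, size=6)
        family = gains[:, None] * r + offsets[:, None]
        first = snv(msc_apply(family, msc_fit(family)))
        second = snv(msc_apply(first, msc_fit(first)))
        rel = np.linalg.norm(second - first) / np.linalg.norm(first)
        assert rel < 1e-6

    def test_derivative_and_cwt_of_zero_are_zero(self):
        zeros = np.zeros((2, 50))
        np.testing.assert_array_equal(sg_derivative(zeros, 1), 0.0)
        np.testing.assert_array_equal(sg_derivative(zeros, 2), 0.0)
        np.testing.assert_array_equal(cwt_transform(zeros, 5.0), 0.0)
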