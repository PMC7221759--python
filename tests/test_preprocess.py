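"""Pre-treatment correctness: closed-form examples, algebraic invariants,
and independent least-squares / scipy oracles for the Savitzky-Golay core."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from numpy.testing import assert_allclose
from scipy.signal import savgol_coeffs

from gamenir.preprocess import (
    Detrend,
    MovingAverage,
    PreprocessPipeline,
    SNV,
    SavitzkyGolay,
    savgol_coefficients,
    snv_detrend_sg,
)


class TestMovingAverage:
    def test_constant_spectrum_unchanged(self):
        X = np.full((2, 9), 3.5)
        assert_allclose(MovingAverage(5).transform(X), X)

    def test_truncated_edge_means(self):
        out = MovingAverage(3).transform(np.array([[1.0, 2, 3, 4, 5]]))
        assert_allclose(out[0], [1.5, 2, 3, 4, 4.5])

    def test_noise_variance_is_reduced(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 61))
        out = MovingAverage(5).transform(X)
        assert out[:, 10:-10].var() < 0.5 * X[:, 10:-10].var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            MovingAverage(4).transform(np.zeros((1, 9)))


class TestSNV:
    def test_three_point_example(self):
        assert_allclose(SNV().transform(np.array([[1.0, 2.0, 3.0]])),
                        [[-1.0, 0.0, 1.0]])

    def test_row_statistics(self):
        rng = np.random.default_rng(1)
        Z = SNV().transform(rng.normal(size=(20, 40)) * 3 + 7)
        assert np.abs(Z.mean(axis=1)).max() < 1e-12
        assert np.abs(Z.std(axis=1, ddof=1) - 1).max() < 1e-12

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_invariance(self, a, b):
        x = np.linspace(0.0, 1.0, 17) ** 2
        assert_allclose(SNV().transform(a * x[None] + b),
                        SNV().transform(x[None]), atol=1e-9)

    def test_constant_row_names_the_sample(self):
        X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="1"):
            SNV().transform(X)


class TestDetrend:
    wl = np.linspace(920.0, 1651.0, 30)

    def test_annihilates_own_order_polynomial(self):
        row = 3.0 - 0.01 * self.wl + 2e-5 * self.wl**2
        out = Detrend(order=2, wavelengths=self.wl).transform(row[None])
        assert np.abs(out).max() < 1e-10

    def test_linear_baseline_invisible_to_residual(self):
        rng = np.random.default_rng(2)
        row = rng.normal(size=self.wl.size)
        base = Detrend(order=2, wavelengths=self.wl)
        shifted = row + 0.003 * self.wl + 4.0
        assert_allclose(base.transform(row[None]),
                        base.transform(shifted[None]), atol=1e-9)

    def test_residual_orthogonal_to_vandermonde(self):
        # the least-squares residual must satisfy the normal equations
        rng = np.random.default_rng(3)
        row = rng.normal(size=self.wl.size)
        resid = Detrend(order=2, wavelengths=self.wl).transform(row[None])[0]
        V = np.vander(self.wl, 3, increasing=True)
        assert np.abs(V.T @ resid).max() < 1e-8 * np.abs(V).max()

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, self.wl.size))
        step = Detrend(order=2, wavelengths=self.wl)
        once = step.transform(X)
        assert_allclose(step.transform(once), once, atol=1e-10)

    def test_order_must_be_below_channel_count(self):
        with pytest.raises(ValueError):
            Detrend(order=5).transform(np.zeros((1, 4)))


class TestSavgolCoefficients:
    def test_quintic_smoothing_window_closed_form(self):
        # independent oracle: solve the 5-point quadratic fit directly
        t = np.arange(-2.0, 3.0)
        A = np.vander(t, 3, increasing=True)
        oracle = (np.linalg.pinv(A)[0])          # value of the fit at t=0
        mine = savgol_coefficients(5, 2, 0)
        assert_allclose(mine, oracle, atol=1e-12)
        assert_allclose(mine * 35, [-3, 12, 17, 12, -3], atol=1e-10)

    @pytest.mark.parametrize("window,poly,deriv", [
        (5, 2, 0), (5, 2, 1), (7, 2, 1), (7, 2, 2), (9, 2, 2), (9, 3, 1), (11, 4, 2),
    ])
    def test_matches_scipy(self, window, poly, deriv):
        assert_allclose(savgol_coefficients(window, poly, deriv),
                        savgol_coeffs(window, poly, deriv=deriv, use="dot"),
                        atol=1e-10)

    @pytest.mark.parametrize("window,poly", [(5, 2), (7, 2), (9, 3)])
    def test_weight_sums(self, window, poly):
        assert savgol_coefficients(window, poly, 0).sum() == pytest.approx(1.0)
        assert savgol_coefficients(window, poly, 1).sum() == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_by_derivative_parity(self):
        w0 = savgol_coefficients(7, 2, 0)
        w1 = savgol_coefficients(7, 2, 1)
        w2 = savgol_coefficients(7, 2, 2)
        assert_allclose(w0, w0[::-1], atol=1e-12)
        assert_allclose(w1, -w1[::-1], atol=1e-12)
        assert_allclose(w2, w2[::-1], atol=1e-12)

    def test_spacing_scales_derivatives(self):
        assert_allclose(savgol_coefficients(7, 2, 1, spacing=6.2),
                        savgol_coefficients(7, 2, 1) / 6.2)

    @pytest.mark.parametrize("window,poly,deriv", [(4, 2, 1), (7, 7, 1), (7, 2, 3)])
    def test_invalid_parameters(self, window, poly, deriv):
        with pytest.raises(ValueError):
            savgol_coefficients(window, poly, deriv)


class TestSavitzkyGolayFilter:
    wl = np.linspace(920.0, 1540.0, 32)    # uniform 20 nm spacing

    def test_exact_first_derivative_of_a_line(self):
        row = 2.0 * self.wl + 7.0
        out = SavitzkyGolay(7, 2, 1, wavelengths=self.wl).transform(row[None])[0]
        assert_allclose(out, np.full_like(row, 2.0), atol=1e-9)

    def test_exact_second_derivative_of_a_parabola(self):
        row = self.wl**2
        out = SavitzkyGolay(7, 2, 2, wavelengths=self.wl).transform(row[None])[0]
        assert_allclose(out, np.full_like(row, 2.0), atol=1e-7)

    def test_smoothing_reproduces_polynomials(self):
        row = 1.0 + 0.5 * self.wl - 0.002 * self.wl**2
        out = SavitzkyGolay(9, 2, 0, wavelengths=self.wl).transform(row[None])[0]
        assert_allclose(out, row, atol=1e-7 * np.abs(row).max())

    def test_matches_dense_per_window_fit(self):
        # brute-force oracle: at every channel, fit the window around it by
        # dense least squares and evaluate the derivative
        rng = np.random.default_rng(5)
        row = np.cumsum(rng.normal(size=self.wl.size))   # smooth-ish walk
        window, poly, deriv, h = 7, 2, 1, 3
        spacing = self.wl[1] - self.wl[0]
        expected = np.empty_like(row)
        for i in range(row.size):
            lo = min(max(i - h, 0), row.size - window)
            t = (self.wl[lo:lo + window] - self.wl[i]) / spacing
            A = np.vander(t, poly + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(A, row[lo:lo + window], rcond=None)
            expected[i] = coef[deriv] * 1 / spacing  # d/d(lambda) = coef_1/spacing
        out = SavitzkyGolay(window, poly, deriv, wavelengths=self.wl).transform(row[None])[0]
        assert_allclose(out, expected, atol=1e-10)

    def test_non_uniform_axis_rejected(self):
        wl = np.sort(np.random.default_rng(0).uniform(900, 1600, 30))
        with pytest.raises(ValueError, match="uniform"):
            SavitzkyGolay(7, 2, 1, wavelengths=wl).transform(np.zeros((1, 30)))


class TestPipeline:
    def test_empty_pipeline_is_identity(self, toy_set):
        out = PreprocessPipeline([]).apply(toy_set)
        assert_allclose(out.X, toy_set.X)
        assert out.provenance[-1] == "raw"

    def test_steps_compose_in_listed_order(self, toy_set):
        wl = toy_set.wavelengths
        pipe = PreprocessPipeline([SNV(), Detrend(order=2)])
        manual = Detrend(order=2, wavelengths=wl).transform(SNV().transform(toy_set.X))
        assert_allclose(pipe.transform(toy_set.X, wavelengths=wl), manual)

    def test_field_notation_label(self):
        pipe = snv_detrend_sg(2, 7)
        assert pipe.label == "SNV+DT+SGd2(7)"

    def test_yaml_round_trip(self, tmp_path):
        pipe = snv_detrend_sg(1, 9, poly_order=3)
        path = tmp_path / "pipe.yaml"
        pipe.to_yaml(path)
        back = PreprocessPipeline.from_yaml(path)
        assert back.label == pipe.label
        rng = np.random.default_rng(6)
        X = rng.normal(size=(3, 25))
        assert_allclose(back.transform(X), pipe.transform(X))

    def test_step_errors_carry_the_step_index(self):
        pipe = PreprocessPipeline([SNV(), SavitzkyGolay(99, 2, 1)])
        with pytest.raises(ValueError, match="step 1"):
            pipe.transform(np.random.default_rng(0).normal(size=(2, 20)))
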