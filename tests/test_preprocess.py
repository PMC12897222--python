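"""Preprocessing transforms against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grainspec import (DegenerateRowError, ParameterError, PreprocessSpec,
                       Preprocessor, SpectraMatrix, WavelengthGrid,
                       apply_spec, baseline_correct, detrend, msc,
                       sg_derivative, sg_smooth, snv)
from grainspec.preprocess import als_baseline


def _matrix(X, n_bands=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid = WavelengthGrid.default(n_bands=X.shape[1])
    return SpectraMatrix(X, grid)


class TestSavitzkyGolay:
    def test_polynomial_reproduced_at_interior(self):
        x = np.arange(40, dtype=float)
        row = 3.0 + 0.5 * x - 0.02 * x ** 2  # degree 2 = polyorder
        out = sg_smooth(row[None, :], window=11, polyorder=2)
        interior = slice(5, -5)
        np.testing.assert_allclose(out[0, interior], row[interior], atol=1e-10)

    def test_constant_row_unchanged(self):
        out = sg_smooth(np.full((1, 25), 4.2), window=7, polyorder=2)
        np.testing.assert_allclose(out, 4.2, atol=1e-12)

    def test_matches_brute_force_local_regression(self, rng):
        row = rng.normal(size=31)
        window, polyorder = 9, 3
        out = sg_smooth(row[None, :], window, polyorder)
        half = window // 2
        for center in range(half, 31 - half):
            idx = np.arange(center - half, center + half + 1)
            coef = np.polyfit(idx - center, row[idx], polyorder)
            assert out[0, center] == pytest.approx(coef[-1], abs=1e-9)

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 30))
        a, b = 2.5, -1.3
        lhs = sg_smooth((a * x + b * y)[None, :], 11, 2)
        rhs = a * sg_smooth(x[None, :], 11, 2) + b * sg_smooth(y[None, :], 11, 2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    @pytest.mark.parametrize("window,polyorder", [(8, 2), (5, 5), (5, 7)])
    def test_invalid_parameters(self, window, polyorder):
        with pytest.raises(ParameterError):
            sg_smooth(np.zeros((1, 20)), window, polyorder)


class TestSGDerivative:
    def test_linear_ramp_first_derivative(self):
        grid = WavelengthGrid.default(n_bands=64)
        m = SpectraMatrix(2.0 * grid.nm[None, :], grid)
        out = sg_derivative(m, window=11, polyorder=2, order=1)
        np.testing.assert_allclose(out.X[0, 5:-5], 2.0, atol=1e-8)

    def test_quadratic_second_derivative(self):
        grid = WavelengthGrid.default(n_bands=64)
        m = SpectraMatrix((grid.nm ** 2)[None, :], grid)
        out = sg_derivative(m, window=11, polyorder=2, order=2)
        np.testing.assert_allclose(out.X[0, 5:-5], 2.0, atol=1e-6)

    def test_matches_windowed_polyfit_derivative(self, rng):
        row = rng.normal(size=41)
        window, polyorder = 11, 3
        out = sg_derivative(row[None, :], window, polyorder, order=1)
        half = window // 2
        for center in range(half, 41 - half):
            idx = np.arange(center - half, center + half + 1)
            coef = np.polyfit(idx - center, row[idx], polyorder)
            # derivative of the fitted polynomial at the window center
            deriv = coef[-2]
            assert out[0, center] == pytest.approx(deriv, abs=1e-9)

    def test_polyorder_must_cover_order(self):
        with pytest.raises(ParameterError):
            sg_derivative(np.zeros((1, 20)), window=7, polyorder=1, order=2)


class TestMSC:
    def test_reference_row_is_fixed_point(self, rng):
        ref = rng.uniform(0.2, 0.8, 30)
        X = np.vstack([ref, rng.uniform(0.2, 0.8, 30)])
        out, a, b = msc(X, reference=ref, return_coef=True)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)
        assert a[0] == pytest.approx(0.0, abs=1e-10)
        assert b[0] == pytest.approx(1.0, abs=1e-10)

    def test_affine_distortion_inverted_exactly(self, rng):
        ref = rng.uniform(0.2, 0.8, 25)
        row = 2.0 * ref + 3.0
        out, a, b = msc(row[None, :], reference=ref, return_coef=True)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)
        assert a[0] == pytest.approx(3.0, abs=1e-10)
        assert b[0] == pytest.approx(2.0, abs=1e-10)

    def test_matches_two_parameter_ols_oracle(self, rng):
        ref = rng.uniform(0, 1, 20)
        row = rng.uniform(0, 1, 20)
        out, a, b = msc(row[None, :], reference=ref, return_coef=True)
        design = np.column_stack([np.ones(20), ref])
        a_hat, b_hat = np.linalg.lstsq(design, row, rcond=None)[0]
        assert a[0] == pytest.approx(a_hat, abs=1e-10)
        assert b[0] == pytest.approx(b_hat, abs=1e-10)
        np.testing.assert_allclose(out[0], (row - a_hat) / b_hat, atol=1e-10)

    def test_default_reference_is_column_mean(self, rng):
        X = rng.uniform(0, 1, (5, 15))
        np.testing.assert_allclose(msc(X), msc(X, reference=X.mean(axis=0)))

    def test_training_reference_frozen_for_test_rows(self, rng):
        train = _matrix(rng.uniform(0.2, 0.8, (6, 12)))
        test = _matrix(rng.uniform(0.2, 0.8, (3, 12)))
        pre = Preprocessor(PreprocessSpec(method="msc")).fit(train)
        out = pre.transform(test)
        expected = msc(test.X, reference=train.X.mean(axis=0))
        np.testing.assert_allclose(out.X, expected)


class TestSNV:
    def test_hand_computed_row(self):
        out = snv(np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_rows_are_standardised(self, rng):
        out = snv(rng.uniform(0, 1, (7, 23)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_idempotent(self, rng):
        X = rng.uniform(0, 1, (4, 19))
        np.testing.assert_allclose(snv(snv(X)), snv(X), atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(gain=st.floats(0.1, 10.0), offset=st.floats(-5.0, 5.0),
           seed=st.integers(0, 100))
    def test_invariant_to_row_affine_distortion(self, gain, offset, seed):
        x = np.random.default_rng(seed).normal(size=(1, 17))
        np.testing.assert_allclose(snv(gain * x + offset), snv(x), atol=1e-8)

    def test_zero_variance_row_raises(self):
        with pytest.raises(DegenerateRowError, match="1"):
            snv(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))


class TestDetrend:
    def test_annihilates_fitted_order_polynomial(self):
        grid = WavelengthGrid.default(n_bands=50)
        row = 1.0 + 0.002 * grid.nm + 3e-6 * grid.nm ** 2
        out = detrend(SpectraMatrix(row[None, :], grid), polyorder=2)
        np.testing.assert_allclose(out.X, 0.0, atol=1e-9)

    def test_invariant_to_added_polynomial(self, rng):
        grid = WavelengthGrid.default(n_bands=40)
        x = rng.normal(size=40)
        p = 0.5 - 0.001 * grid.nm + 2e-6 * grid.nm ** 2
        a = detrend(SpectraMatrix(x[None, :], grid), polyorder=2)
        b = detrend(SpectraMatrix((x + p)[None, :], grid), polyorder=2)
        np.testing.assert_allclose(a.X, b.X, atol=1e-8)

    def test_matches_polynomial_regression_oracle(self, rng):
        x = rng.normal(size=30)
        out = detrend(x[None, :], polyorder=3)
        t = np.arange(30, dtype=float)
        t = 2 * (t - t.min()) / (t.max() - t.min()) - 1
        fit = np.polynomial.polynomial.polyval(
            t, np.polynomial.polynomial.polyfit(t, x, 3))
        np.testing.assert_allclose(out[0], x - fit, atol=1e-10)


class TestBaselineCorrect:
    def test_constant_row_annihilated(self):
        c = 5.0
        out = baseline_correct(np.full((1, 60), c), lam=1e5)
        assert np.max(np.abs(out)) < 1e-3 * abs(c)

    def test_peak_height_preserved(self):
        x = np.arange(200, dtype=float)
        peak = 1.0 * np.exp(-0.5 * ((x - 100) / 4.0) ** 2)
        out = baseline_correct((0.5 + peak)[None, :], lam=1e5, p=0.01)
        assert out[0, 100] == pytest.approx(1.0, rel=0.05)

    def test_baseline_lies_below_the_spectrum(self):
        """Asymmetric weighting keeps the baseline at or below the signal.

        The converged ALS baseline sits within the reweighting bias
        (order p * peak mass, here a few 1e-3) of the spectrum from
        below; peaks clear it by nearly their full height.
        """
        x = np.arange(150, dtype=float)
        row = 0.5 + 0.002 * x           # drift the smoother can represent
        row[40:45] += 2.0               # peaks the baseline must pass under
        row[90:93] += 1.5
        p = 0.01
        z = als_baseline(row, lam=1e5, p=p, n_iter=10)
        margin = 0.005                   # 0.25% of the tallest peak
        assert np.mean(row >= z - margin) >= 1 - p
        assert np.max(z - row) <= margin
        assert (row - z)[40:45].min() >= 0.95 * 2.0


class TestApplySpec:
    def test_raw_is_identity(self, rng):
        m = _matrix(rng.uniform(0, 1, (4, 20)))
        out = apply_spec(m, PreprocessSpec(method="raw"))
        np.testing.assert_array_equal(out.X, m.X)

    def test_dispatch_matches_direct_call(self, rng):
        m = _matrix(rng.uniform(0, 1, (5, 20)))
        out = apply_spec(m, PreprocessSpec(method="snv"))
        np.testing.assert_allclose(out.X, snv(m.X))

    def test_spec_serialization_round_trip(self, rng):
        m = _matrix(rng.uniform(0, 1, (5, 30)))
        spec = PreprocessSpec(method="sg", window=9, polyorder=3)
        reparsed = PreprocessSpec.from_dict(spec.to_dict())
        np.testing.assert_array_equal(apply_spec(m, spec).X,
                                      apply_spec(m, reparsed).X)

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            PreprocessSpec(method="wavelet")


def test_msc_inverts_generator_scatter_exactly():
    """With scatter only (no noise/baseline/effect), MSC against the true
    base profile recovers it to numerical precision."""
    from grainspec import SynthConfig, generate_spectra
    cfg = SynthConfig(n_healthy=15, n_infested=15, n_bands=40, seed=21,
                      effect_windows=(), gain_sd=0.08, offset_sd=0.02,
                      baseline_sd=0.0, noise_sd=0.0)
    m, truth = generate_spectra(cfg)
    corrected = msc(m.X, reference=truth.base)
    np.testing.assert_allclose(corrected,
                               np.tile(truth.base, (m.n_samples, 1)),
                               atol=1e-8)
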