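"""GE measurement process: nonlinearity, noise families, quantiles, intervals."""

import numpy as np
import pytest
from scipy.integrate import quad

import latentmave as lm
from latentmave.measurement_ge import make_noise_model


def _single_tanh():
    nl = lm.GENonlinearity(K=1)
    nl.a, nl.b, nl.c, nl.d = 0.0, np.array([1.0]), np.array([1.0]), np.array([0.0])
    return nl


class TestNonlinearity:
    def test_tanh_at_zero_and_saturation(self):
        nl = _single_tanh()
        assert nl.g(np.r_[0.0])[0] == 0.0
        assert np.isclose(nl.g(np.r_[50.0])[0], 1.0)

    def test_monotone_on_grid(self):
        rng = np.random.default_rng(0)
        nl = lm.GENonlinearity(K=8, monotonic=True, seed=1)
        nl.b = rng.uniform(0.1, 2, 8)
        nl.c = rng.uniform(0.1, 2, 8)
        nl.d = rng.normal(size=8)
        g = nl.g(np.linspace(-5, 5, 500))
        assert np.all(np.diff(g) >= 0)

    def test_shift_scale_reparameterization(self):
        nl = lm.GENonlinearity(K=3, seed=2)
        phi = np.linspace(-2, 2, 11)
        expected = nl.g(0.7 + 1.3 * phi)
        nl.shift_scale_phi(0.7, 1.3)
        assert np.allclose(nl.g(phi), expected)

    def test_linear_nonlinearity(self):
        nl = lm.LinearNonlinearity()
        nl.a, nl.m = 2.0, -0.5
        assert np.allclose(nl.g(np.r_[0.0, 2.0]), [2.0, 1.0])


class TestNoiseScale:
    def test_homoscedastic_constants(self):
        n = lm.GaussianNoise(poly_order=0)
        assert np.allclose(n.scale(np.r_[0.0, 5.0]), 1.0)
        n.s_coeffs[0] = np.log(2.0)
        assert np.allclose(n.scale(np.r_[3.0]), 2.0)

    def test_linear_exponent(self):
        n = lm.GaussianNoise(poly_order=1)
        n.s_coeffs[:] = [0.0, 1.0]
        assert np.isclose(n.scale(np.r_[-1.0])[0], np.exp(-1))


class TestGaussian:
    def test_logpdf_peak_value(self):
        n = lm.GaussianNoise(poly_order=0)
        assert np.isclose(n.logpdf(np.r_[1.2], np.r_[1.2])[0], -0.5 * np.log(2 * np.pi))

    def test_median_is_prediction(self):
        n = lm.GaussianNoise(poly_order=0)
        assert np.isclose(n.quantile(0.5, np.r_[0.7])[0], 0.7)

    def test_quantile_inverts_cdf(self):
        n = lm.GaussianNoise(poly_order=0)
        n.s_coeffs[0] = np.log(1.7)
        y = np.linspace(-3, 3, 21)
        yhat = np.zeros_like(y)
        assert np.allclose(n.quantile(n.cdf(y, yhat), yhat), y, atol=1e-9)


class TestCauchy:
    def test_quantiles(self):
        n = lm.CauchyNoise(poly_order=0)
        n.s_coeffs[0] = np.log(2.0)
        assert np.isclose(n.quantile(0.5, np.r_[1.0])[0], 1.0)
        assert np.isclose(n.quantile(0.75, np.r_[1.0])[0], 3.0)  # yhat + s

    def test_pdf_at_mode(self):
        n = lm.CauchyNoise(poly_order=0)
        n.s_coeffs[0] = np.log(0.5)
        assert np.isclose(np.exp(n.logpdf(np.r_[0.0], np.r_[0.0]))[0], 1 / (np.pi * 0.5))

    def test_quantile_inverts_cdf(self):
        n = lm.CauchyNoise(poly_order=0)
        y = np.linspace(-5, 5, 21)
        yhat = np.zeros_like(y)
        assert np.allclose(n.quantile(n.cdf(y, yhat), yhat), y, atol=1e-9)


class TestSkewT:
    def _noise(self, s=0.8, a=2.0, b=3.0):
        n = lm.SkewTNoise(poly_order=0)
        n.s_coeffs[:] = np.log(s)
        n.a_coeffs[:] = np.log(a)
        n.b_coeffs[:] = np.log(b)
        return n

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (1.0, 1.0), (5.0, 0.7)])
    def test_density_normalizes(self, a, b):
        n = self._noise(a=a, b=b)
        val, _ = quad(
            lambda y: np.exp(n.logpdf(np.r_[y], np.r_[0.3])[0]),
            -np.inf, np.inf, limit=800,
        )
        assert abs(val - 1.0) < 1e-6

    def test_mode_at_prediction(self):
        n = self._noise(a=2.0, b=5.0)
        grid = np.linspace(-4, 4, 100001) + 0.7
        pdf = np.exp(n.logpdf(grid, np.full_like(grid, 0.7)))
        assert abs(grid[pdf.argmax()] - 0.7) < 1e-3

    def test_symmetric_when_a_equals_b(self):
        n = self._noise(a=3.0, b=3.0)
        yhat = np.r_[0.0]
        assert np.isclose(n.quantile(0.5, yhat)[0], 0.0, atol=1e-12)
        d = np.r_[0.9]
        assert np.isclose(n.logpdf(d, yhat)[0], n.logpdf(-d, yhat)[0])

    def test_quantile_inverts_cdf(self):
        n = self._noise()
        y = np.linspace(-3, 3, 15)
        yhat = np.zeros_like(y)
        assert np.allclose(n.quantile(n.cdf(y, yhat), yhat), y, atol=1e-7)

    def test_approaches_gaussian_for_large_symmetric_shape(self):
        # KL(skew-t || normal fit) shrinks monotonically as a=b grows
        gauss = lm.GaussianNoise(poly_order=0)
        grid = np.linspace(-6, 6, 4001)
        kls = []
        for ab in (2.0, 8.0, 32.0, 128.0):
            n = self._noise(s=1.0, a=ab, b=ab)
            logp = n.logpdf(grid, np.zeros_like(grid))
            p = np.exp(logp)
            p /= np.trapezoid(p, grid)
            # match the implied width: std of the skew-t on the grid
            mu = np.trapezoid(p * grid, grid)
            sd = np.sqrt(np.trapezoid(p * (grid - mu) ** 2, grid))
            gauss.s_coeffs[0] = np.log(sd)
            logq = gauss.logpdf(grid, np.full_like(grid, mu))
            kls.append(np.trapezoid(p * (np.log(p + 1e-300) - logq), grid))
        assert all(k2 < k1 for k1, k2 in zip(kls, kls[1:]))
        assert kls[-1] < 1e-3


class TestEmpirical:
    def test_equals_gaussian_with_given_scale(self):
        emp = lm.EmpiricalNoise()
        gauss = lm.GaussianNoise(poly_order=0)
        gauss.s_coeffs[0] = np.log(0.37)
        y, yhat = np.r_[1.0, -0.4], np.r_[0.8, 0.1]
        se = np.full(2, 0.37)
        assert np.allclose(emp.logpdf(y, yhat, se=se), gauss.logpdf(y, yhat))

    def test_doubling_scale_lowers_peak_by_ln2(self):
        emp = lm.EmpiricalNoise()
        y = np.r_[0.5]
        lp1 = emp.logpdf(y, y, se=np.r_[0.2])
        lp2 = emp.logpdf(y, y, se=np.r_[0.4])
        assert np.isclose(lp1[0] - lp2[0], np.log(2))

    def test_missing_se_rejected(self):
        with pytest.raises(ValueError):
            lm.EmpiricalNoise().logpdf(np.r_[0.0], np.r_[0.0])


class TestPredictionInterval:
    def test_gaussian_interval_centered(self):
        meas = lm.GEMeasurement(_single_tanh(), lm.GaussianNoise(poly_order=0))
        lo, hi = meas.prediction_interval(0.025, 0.975, np.r_[0.0])
        assert np.isclose(lo[0], -hi[0])
        assert np.isclose(hi[0], 1.959964, atol=1e-5)

    def test_bad_order_rejected(self):
        meas = lm.GEMeasurement(_single_tanh(), lm.GaussianNoise(poly_order=0))
        with pytest.raises(ValueError):
            meas.prediction_interval(0.9, 0.1, np.r_[0.0])

    def test_coverage_on_simulated_data(self):
        rng = np.random.default_rng(5)
        meas = lm.GEMeasurement(_single_tanh(), lm.SkewTNoise(poly_order=0))
        meas.noise.s_coeffs[:] = np.log(0.5)
        phi = rng.normal(size=10_000)
        y = meas.sample(phi, rng)
        lo, hi = meas.prediction_interval(0.025, 0.975, phi)
        cover = np.mean((y >= lo) & (y <= hi))
        assert abs(cover - 0.95) < 0.02

    @pytest.mark.parametrize("family", ["gaussian", "cauchy", "skewt"])
    def test_sampling_matches_quantiles(self, family):
        rng = np.random.default_rng(6)
        noise = make_noise_model(family, poly_order=0)
        yhat = np.zeros(20_000)
        draws = noise.sample(yhat, rng)
        q25 = noise.quantile(0.25, np.r_[0.0])[0]
        assert abs(np.mean(draws <= q25) - 0.25) < 0.02
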