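"""kNN/KSG estimators against closed forms; information metrics and bounds."""

import numpy as np
import pytest

import latentmave as lm
from latentmave.info_metrics import discrete_entropy
from tests.conftest import make_ge_truth, simulate_ge


class TestKnnEntropy:
    def test_uniform_zero_bits(self, rng):
        h = lm.knn_entropy(rng.uniform(size=10_000))
        assert abs(h) < 0.05

    def test_standard_normal(self, rng):
        h = lm.knn_entropy(rng.normal(size=10_000))
        assert abs(h - 0.5 * np.log2(2 * np.pi * np.e)) < 0.05

    def test_scaling_adds_one_bit(self, rng):
        x = rng.normal(size=5000)
        assert abs(lm.knn_entropy(2 * x) - lm.knn_entropy(x) - 1.0) < 0.02

    def test_duplicates_handled(self):
        x = np.repeat([0.0, 1.0, 2.0], 50)
        assert np.isfinite(lm.knn_entropy(x))

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            lm.knn_entropy(np.r_[1.0, 2.0], k=5)


class TestKsgMutualInformation:
    def test_independent_near_zero(self, rng):
        mi = lm.ksg_mutual_information(rng.normal(size=10_000), rng.normal(size=10_000))
        assert mi < 0.02

    def test_bivariate_gaussian_closed_form(self, rng):
        rho = 0.9
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=10_000)
        mi = lm.ksg_mutual_information(xy[:, 0], xy[:, 1])
        assert abs(mi - (-0.5 * np.log2(1 - rho**2))) < 0.05

    def test_invariant_under_monotone_transform(self, rng):
        rho = 0.8
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000)
        mi1 = lm.ksg_mutual_information(xy[:, 0], xy[:, 1])
        mi2 = lm.ksg_mutual_information(xy[:, 0], np.exp(xy[:, 1]))
        assert abs(mi1 - mi2) < 0.05

    def test_constant_input_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert lm.ksg_mutual_information(np.ones(100), np.arange(100.0)) == 0.0


class TestSubsampleUncertainty:
    def test_constant_estimator_zero(self, rng):
        d = lm.subsample_uncertainty(lambda x: 42.0, rng.normal(size=100))
        assert d == 0.0

    def test_sample_mean_scales_with_n(self, rng):
        d1 = lm.subsample_uncertainty(np.mean, rng.normal(size=400), R=50)
        d2 = lm.subsample_uncertainty(np.mean, rng.normal(size=6400), R=50)
        ratio = d1 / d2
        assert 2.0 < ratio < 8.0  # ~ sqrt(16) = 4

    def test_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            lm.subsample_uncertainty(np.mean, np.r_[1.0, 2.0])
        with pytest.raises(ValueError):
            lm.subsample_uncertainty(np.mean, rng.normal(size=100), R=1)


class TestVariationalInformation:
    def test_marginal_model_near_zero(self):
        """A model whose p(y|phi) equals the marginal p(y) carries no information."""
        rng = np.random.default_rng(3)
        gp = lm.LinearGPMap(3, "dna", "additive")
        gp.theta_lc = rng.normal(size=(3, 4)) * 1e-12
        meas = lm.GEMeasurement(lm.LinearNonlinearity(), lm.GaussianNoise(0))
        model = lm.LatentModel(gp, meas)
        seqs = tuple(
            "".join(np.array(list("ACGT"))[i]) for i in rng.integers(4, size=(3000, 3))
        )
        ds = lm.SequenceDataset(seqs, lm.DNA, y=rng.normal(size=3000))
        i_var, d = lm.variational_information(model, ds)
        assert abs(i_var) < 3 * d + 0.05

    def test_gaussian_channel_ivar_matches_mutual_information(self):
        """For the true model of a Gaussian channel y = m*phi + noise, I_var
        equals I[y; phi]; the KSG estimate of the latter is an independent
        route to the same quantity."""
        truth = make_ge_truth(L=8, seed=31, noise="gaussian", s=0.5, sigmoid=False)
        data = simulate_ge(truth, n=5000, seed=32)
        i_var, d_var = lm.variational_information(truth, data)
        i_pre, d_pre = lm.predictive_information(truth, data)
        joint = np.hypot(d_var, d_pre)
        assert abs(i_var - i_pre) < 2 * joint + 0.1
        assert i_var <= i_pre + 2 * joint


class TestPredictiveInformation:
    def test_constant_phi_zero(self):
        gp = lm.LinearGPMap(2, "dna", "additive")
        meas = lm.GEMeasurement(lm.LinearNonlinearity(), lm.GaussianNoise(0))
        model = lm.LatentModel(gp, meas)
        rng = np.random.default_rng(5)
        seqs = tuple(
            "".join(np.array(list("ACGT"))[i]) for i in rng.integers(4, size=(500, 2))
        )
        ds = lm.SequenceDataset(seqs, lm.DNA, y=rng.normal(size=500))
        with pytest.warns(UserWarning):
            i_pre, _ = lm.predictive_information(model, ds)
        assert i_pre == 0.0

    def test_grows_as_noise_shrinks(self):
        vals = []
        for s in (1.0, 0.3, 0.1):
            truth = make_ge_truth(L=6, seed=41, noise="gaussian", s=s, sigmoid=False)
            data = simulate_ge(truth, n=3000, seed=42)
            i_pre, _ = lm.predictive_information(truth, data)
            vals.append(i_pre)
        assert vals[0] < vals[1] < vals[2]

    def test_independent_of_measurement_parameters(self):
        truth = make_ge_truth(L=6, seed=51, noise="gaussian")
        data = simulate_ge(truth, n=2000, seed=52)
        i1, _ = lm.predictive_information(truth, data)
        truth.measurement.noise.s_coeffs[0] += 1.7  # change eta, not the G-P map
        i2, _ = lm.predictive_information(truth, data)
        assert i1 == i2

    def test_discrete_decomposition(self):
        """MPA I_pre via H[phi] - sum_y p(y) H_y[phi] is close to the KSG value
        computed on a continuized copy of the bins."""
        rng = np.random.default_rng(6)
        gp = lm.LinearGPMap(6, "dna", "additive")
        gp.theta_lc = rng.normal(size=(6, 4))
        meas = lm.MPAMeasurement(Y=3, K=3, seed=7)
        meas.b = np.outer(np.linspace(-2, 2, 3), np.ones(3) / 3)
        meas.c = np.ones((3, 3))
        meas.d = np.zeros((3, 3))
        model = lm.LatentModel(gp, meas)
        from latentmave.gauge import fix_diffeomorphic
        from latentmave.simulate_bootstrap import SimulationSpec, simulate_dataset
        from tests.conftest import random_sequences

        seqs = random_sequences(4000, 6, seed=8)
        fix_diffeomorphic(model, model.phi(seqs))
        ds = simulate_dataset(model, SimulationSpec(n=4000, sequences=seqs, seed=9))
        i_pre, d = lm.predictive_information(model, ds)
        assert i_pre > 0.1  # informative model
        assert i_pre <= discrete_entropy(ds.bins) + 1e-9


class TestIntrinsicBounds:
    def test_poisson_error_propagation_values(self):
        # c_in = c_out = 0 -> dy = log2(e) * sqrt(2)
        dy = np.log2(np.e) * np.sqrt(1 / 1 + 1 / 1)
        assert np.isclose(dy, 2.0404, atol=2e-4)
        # dy = 1 -> conditional entropy 0.5*log2(2 pi e)
        assert np.isclose(0.5 * np.log2(2 * np.pi * np.e), 2.0471, atol=1e-4)

    def test_upper_bound_decreases_with_noisier_counts(self, rng):
        y = rng.normal(size=2000)
        hi, d_hi = lm.intrinsic_info_upper(y, np.full(2000, 1000), np.full(2000, 1000))
        lo, d_lo = lm.intrinsic_info_upper(y, np.full(2000, 2), np.full(2000, 2))
        assert hi > lo  # deeper counts -> smaller conditional entropy -> larger bound

    def test_lower_bound_from_replicates(self, rng):
        y = rng.normal(size=3000)
        # identical replicate: bound is the (large) self-MI estimate
        b_same, _ = lm.intrinsic_info_lower(y=y, y_replicate=y.copy())
        b_indep, _ = lm.intrinsic_info_lower(y=y, y_replicate=rng.normal(size=3000))
        assert b_same > 2.0
        assert b_indep < 0.05

    def test_lower_bound_needs_input(self):
        with pytest.raises(ValueError):
            lm.intrinsic_info_lower()

    def test_model_ipre_as_lower_bound(self):
        val, err = lm.intrinsic_info_lower(model_i_pre=1.3, model_i_pre_err=0.1)
        assert val == 1.3 and err == 0.1
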