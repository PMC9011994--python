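"""Likelihood identities, loss behavior, determinism, and dataset constraints."""

import numpy as np
import pytest

import latentmave as lm
from latentmave.training import check_library_constraints
from tests.conftest import make_ge_truth, random_sequences, simulate_ge


class TestLikelihoodClosedForms:
    def test_mpa_uniform_nll(self):
        m = lm.MPAMeasurement(Y=4, K=2)
        m.set_params(np.zeros(m.n_params))
        gp = lm.LinearGPMap(2, "dna", "additive")
        model = lm.LatentModel(gp, m)
        seqs = tuple(random_sequences(10, 2, seed=0))
        ds = lm.SequenceDataset(seqs, lm.DNA, bins=np.zeros(10, dtype=int))
        assert np.isclose(model.nll(ds), 10 * np.log(4))

    def test_ge_gaussian_perfect_prediction(self):
        gp = lm.LinearGPMap(2, "dna", "additive")  # phi = 0 everywhere
        nl = lm.LinearNonlinearity()  # yhat = phi = 0
        meas = lm.GEMeasurement(nl, lm.GaussianNoise(poly_order=0))  # s = 1
        model = lm.LatentModel(gp, meas)
        ds = lm.SequenceDataset(("AA", "CC", "GG"), lm.DNA, y=np.zeros(3))
        assert np.isclose(model.nll(ds), 3 * 0.5 * np.log(2 * np.pi))

    def test_l2_penalty_form(self):
        # lambda_theta * ||theta||^2 with theta = (3, 4) -> 25
        theta = np.r_[3.0, 4.0]
        assert np.isclose(1.0 * theta @ theta, 25.0)
        cfg = lm.LossConfig(lambda_theta=2e-3)
        assert np.isclose(cfg.lambda_theta * (theta @ theta), 2 * 1e-3 * 25)
        with pytest.raises(ValueError):
            lm.LossConfig(lambda_theta=-1.0)


class TestSplits:
    def test_fractions_validated(self):
        with pytest.raises(ValueError):
            lm.SplitSpec(0.5, 0.5, 0.2)
        spec = lm.SplitSpec(0.8, 0.1, 0.1, seed=1)
        ds = lm.SequenceDataset(
            tuple(random_sequences(100, 3, seed=1)), lm.DNA, y=np.zeros(100)
        )
        tr, va, te = lm.split_dataset(ds, spec)
        assert len(tr) == 80 and len(va) == 10 and len(te) == 10
        assert set(tr.sequences + va.sequences + te.sequences) == set(ds.sequences)


class TestFitBehavior:
    def test_loss_decreases_and_determinism(self):
        truth = make_ge_truth(L=6, seed=11, noise="gaussian")
        data = simulate_ge(truth, n=800, seed=12)
        kwargs = dict(
            gpmap="additive",
            noise="gaussian",
            config=lm.LossConfig(seed=5, epochs=60),
            split=lm.SplitSpec(seed=5),
        )
        r1 = lm.fit(data, **kwargs)
        losses = r1.history["train_loss"].to_numpy()
        assert losses[-1] < losses[0]
        kwargs2 = dict(
            gpmap="additive",
            noise="gaussian",
            config=lm.LossConfig(seed=5, epochs=60),
            split=lm.SplitSpec(seed=5),
        )
        r2 = lm.fit(data, **kwargs2)
        assert np.array_equal(
            r1.history["train_loss"].to_numpy(), r2.history["train_loss"].to_numpy()
        )
        assert np.allclose(
            r1.model.gpmap.get_params(), r2.model.gpmap.get_params(), equal_nan=True
        )

    def test_fit_returns_standardized_phi(self, ge_fit):
        truth, data, result = ge_fit
        phi = result.model.phi(result.train.sequences)
        assert abs(np.nanmean(phi)) < 1e-6
        assert abs(np.nanstd(phi) - 1) < 1e-6

    def test_parameter_recovery(self, ge_fit):
        truth, data, result = ge_fit
        p = np.full((truth.gpmap.L, 4), 0.25)
        t = lm.hierarchical_gauge(truth.gpmap, p).theta_lc.ravel()
        f = result.model.gpmap.theta_lc.ravel()
        mask = np.isfinite(f)
        r2 = np.corrcoef(t[mask], f[mask])[0, 1] ** 2
        assert r2 > 0.95

    def test_noise_free_ivar_approaches_hy(self):
        """With nearly noiseless measurements the model should capture almost
        all measurement entropy: I_var approaches H[y] on held-out data."""
        truth = make_ge_truth(L=6, seed=21, noise="gaussian", s=1e-3)
        data = simulate_ge(truth, n=2000, seed=22)
        res = lm.fit(
            data,
            gpmap="additive",
            noise="gaussian",
            config=lm.LossConfig(seed=7, epochs=300),
            split=lm.SplitSpec(seed=7),
        )
        i_var, d_var = lm.variational_information(res.model, res.test)
        h_y = lm.knn_entropy(res.test.y)
        assert i_var > 0.8 * h_y


class TestLibraryConstraints:
    def _single_mutant_dataset(self):
        wt = "ACGTAC"
        seqs = [wt] + [wt[:l] + c + wt[l + 1 :] for l in range(6) for c in "ACGT" if c != wt[l]]
        y = np.arange(len(seqs), dtype=float)
        return lm.SequenceDataset(tuple(seqs), lm.DNA, y=y)

    def test_pairwise_on_singles_rejected(self):
        ds = self._single_mutant_dataset()
        with pytest.raises(ValueError, match="single-mutation"):
            check_library_constraints(ds, "pairwise", "ge", linear_nonlinearity=False)

    def test_nonlinear_g_on_singles_rejected(self):
        ds = self._single_mutant_dataset()
        with pytest.raises(ValueError):
            check_library_constraints(ds, "additive", "ge", linear_nonlinearity=False)

    def test_additive_linear_accepted(self):
        ds = self._single_mutant_dataset()
        assert check_library_constraints(ds, "additive", "ge", linear_nonlinearity=True)

    def test_doubles_lift_restriction(self):
        ds = self._single_mutant_dataset()
        rng = np.random.default_rng(3)
        wt = "ACGTAC"
        doubles = []
        while len(doubles) < 500:
            l1, l2 = sorted(rng.choice(6, 2, replace=False))
            c1 = "ACGT"[rng.integers(4)]
            c2 = "ACGT"[rng.integers(4)]
            if c1 != wt[l1] and c2 != wt[l2]:
                doubles.append(wt[:l1] + c1 + wt[l1 + 1 : l2] + c2 + wt[l2 + 1 :])
        seqs = ds.sequences + tuple(doubles)
        ds2 = lm.SequenceDataset(seqs, lm.DNA, y=np.zeros(len(seqs)))
        assert not check_library_constraints(ds2, "pairwise", "ge", linear_nonlinearity=False)

    def test_fit_enforces_constraint(self):
        ds = self._single_mutant_dataset()
        with pytest.raises(ValueError, match="single-mutation"):
            lm.fit(ds, gpmap="pairwise", config=lm.LossConfig(epochs=1))
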