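"""Gauge fixing: diffeomorphic standardization and the hierarchical gauge."""

import numpy as np
import pytest

import latentmave as lm
from latentmave.gauge import (
    fix_diffeomorphic,
    hierarchical_gauge,
    position_probability_matrix,
)
from tests.conftest import random_sequences


def _random_pairwise(L=4, seed=0):
    rng = np.random.default_rng(seed)
    gp = lm.LinearGPMap(L, "dna", "pairwise")
    gp.theta_0 = rng.normal()
    gp.theta_lc = rng.normal(size=(L, 4))
    gp.theta_pair = rng.normal(size=gp.theta_pair.shape)
    return gp


class TestPositionProbabilityMatrix:
    def test_sources(self):
        p = position_probability_matrix("uniform", 3, "dna")
        assert np.allclose(p, 0.25)
        p = position_probability_matrix("empirical", 2, "dna", sequences=["AC", "AG"])
        assert np.allclose(p[0], [1, 0, 0, 0]) and np.allclose(p[1], [0, 0.5, 0.5, 0])
        p = position_probability_matrix("wildtype", 2, "dna", wildtype="AT")
        assert p[0, 0] == 1 and p[1, 3] == 1


class TestDiffeomorphicFix:
    def test_standardizes_phi_and_preserves_likelihood(self):
        rng = np.random.default_rng(1)
        gp = _random_pairwise(seed=2)
        meas = lm.GEMeasurement(lm.GENonlinearity(K=4, seed=3), lm.GaussianNoise(1))
        meas.noise.s_coeffs[:] = [0.2, 0.05]
        model = lm.LatentModel(gp, meas)
        seqs = random_sequences(1000, 4, seed=4)
        y = rng.normal(size=1000)
        phi_before = model.phi(seqs)
        lp_before = meas.logpdf(y, phi_before)
        a, b = fix_diffeomorphic(model, phi_before)
        phi_after = model.phi(seqs)
        assert abs(phi_after.mean()) < 1e-9 and abs(phi_after.std() - 1) < 1e-9
        lp_after = meas.logpdf(y, phi_after)
        assert np.abs(lp_before - lp_after).max() < 1e-9

    def test_mpa_likelihood_preserved(self):
        gp = _random_pairwise(seed=5)
        meas = lm.MPAMeasurement(Y=3, K=4, seed=6)
        model = lm.LatentModel(gp, meas)
        seqs = random_sequences(500, 4, seed=7)
        phi = model.phi(seqs)
        p_before = meas.probabilities(phi)
        fix_diffeomorphic(model, phi)
        p_after = meas.probabilities(model.phi(seqs))
        assert np.abs(p_before - p_after).max() < 1e-9

    def test_already_standard_is_identity(self):
        gp = _random_pairwise(seed=8)
        seqs = random_sequences(2000, 4, seed=9)
        model = lm.LatentModel(gp, lm.MPAMeasurement(Y=2, K=2))
        fix_diffeomorphic(model, model.phi(seqs))
        theta_before = model.gpmap.get_params().copy()
        a, b = fix_diffeomorphic(model, model.phi(seqs))
        assert abs(a) < 1e-12 and abs(b - 1) < 1e-12
        assert np.allclose(model.gpmap.get_params(), theta_before)

    def test_degenerate_map_rejected(self):
        gp = lm.LinearGPMap(2, "dna", "additive")
        model = lm.LatentModel(gp, lm.MPAMeasurement(Y=2, K=2))
        with pytest.raises(ValueError, match="zero variance"):
            fix_diffeomorphic(model, np.zeros(10))


class TestHierarchicalGauge:
    def test_hand_case_two_characters(self):
        gp = lm.LinearGPMap(1, "AB", "additive")
        gp.theta_lc = np.array([[2.0, 4.0]])
        fixed = hierarchical_gauge(gp, np.array([[0.5, 0.5]]))
        assert np.isclose(fixed.theta_0, 3.0)
        assert np.allclose(fixed.theta_lc, [[-1.0, 1.0]])
        assert np.isclose(fixed.phi(["A"])[0], gp.phi(["A"])[0])

    @pytest.mark.parametrize("source", ["uniform", "empirical"])
    def test_phi_preserved_on_random_sequences(self, source):
        gp = _random_pairwise(seed=10)
        seqs = random_sequences(1000, 4, seed=11)
        p = position_probability_matrix(source, 4, "dna", sequences=seqs)
        fixed = hierarchical_gauge(gp, p)
        assert np.abs(fixed.phi(seqs) - gp.phi(seqs)).max() < 1e-9

    def test_idempotence(self):
        gp = _random_pairwise(seed=12)
        p = position_probability_matrix("uniform", 4, "dna")
        once = hierarchical_gauge(gp, p)
        twice = hierarchical_gauge(once, p)
        assert np.allclose(once.get_params(), twice.get_params(), atol=1e-12)

    def test_zero_marginal_postconditions(self):
        gp = _random_pairwise(seed=13)
        rng = np.random.default_rng(14)
        p = rng.dirichlet(np.ones(4), size=4)  # random factorized distribution
        fixed = hierarchical_gauge(gp, p)
        assert np.abs((fixed.theta_lc * p).sum(axis=1)).max() < 1e-12
        for idx, (l, lp) in enumerate(fixed.pairs):
            block = fixed.theta_pair[idx]
            assert np.abs(p[l] @ block).max() < 1e-12
            assert np.abs(block @ p[lp]).max() < 1e-12

    def test_wildtype_gauge_zeroes_wildtype_effects(self):
        gp = _random_pairwise(seed=15)
        wt = "ACGT"
        p = position_probability_matrix("wildtype", 4, "dna", wildtype=wt)
        fixed = hierarchical_gauge(gp, p)
        for l, ch in enumerate(wt):
            assert abs(fixed.theta_lc[l, lm.DNA.index(ch)]) < 1e-12
        assert np.isclose(fixed.phi([wt])[0], fixed.theta_0)

    def test_nan_effect_with_positive_probability_rejected(self):
        gp = lm.LinearGPMap(2, "dna", "additive")
        gp.theta_lc[0, 1] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            hierarchical_gauge(gp, position_probability_matrix("uniform", 2, "dna"))

    def test_lower_order_terms_absorb_maximal_variance(self):
        """Among gauge-equivalent parameterizations (phi identical for all x),
        the hierarchical gauge minimizes the variance of the interaction part
        under the factorized sequence distribution, i.e. the constant+additive
        terms account for the largest possible share of var(phi)."""
        L, C = 2, 2
        gp = lm.LinearGPMap(L, "AB", "pairwise")
        rng = np.random.default_rng(16)
        gp.theta_lc = rng.normal(size=(L, C))
        gp.theta_pair = rng.normal(size=gp.theta_pair.shape)
        p = np.array([[0.3, 0.7], [0.6, 0.4]])
        fixed = hierarchical_gauge(gp, p)
        seqs = ["AA", "AB", "BA", "BB"]
        weights = np.array([p[0, 0] * p[1, 0], p[0, 0] * p[1, 1],
                            p[0, 1] * p[1, 0], p[0, 1] * p[1, 1]])

        def pair_variance(g):
            add = lm.LinearGPMap(L, "AB", "additive")
            add.theta_0, add.theta_lc = g.theta_0, g.theta_lc
            part = g.phi(seqs) - add.phi(seqs)
            mean = weights @ part
            return weights @ (part - mean) ** 2

        v_fixed = pair_variance(fixed)
        for trial in range(40):
            # random gauge move: T[c, c'] += u_c + v_c' with additive compensation
            moved = fixed.copy()
            u = rng.normal(size=C)
            v = rng.normal(size=C)
            moved.theta_pair[0] += u[:, None] + v[None, :]
            moved.theta_lc = moved.theta_lc.copy()
            moved.theta_lc[0] -= u
            moved.theta_lc[1] -= v
            assert np.abs(moved.phi(seqs) - fixed.phi(seqs)).max() < 1e-9
            assert pair_variance(moved) >= v_fixed - 1e-12
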