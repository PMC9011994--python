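import numpy as np
import pytest

import latentmave as lm
from latentmave.gauge import fix_diffeomorphic
from latentmave.simulate_bootstrap import SimulationSpec, draw_sequences, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_sequences(n, L, alphabet="ACGT", seed=0):
    rng = np.random.default_rng(seed)
    chars = np.array(list(alphabet))
    return ["".join(chars[i]) for i in rng.integers(len(chars), size=(n, L))]


def make_ge_truth(L=10, seed=1, noise="skewt", s=0.15, sigmoid=True):
    """Ground-truth additive model with a sigmoidal nonlinearity, phi standardized."""
    rng = np.random.default_rng(seed)
    gp = lm.LinearGPMap(L, "dna", "additive")
    gp.theta_lc = rng.normal(0, 1, size=(L, 4))
    if sigmoid:
        nl = lm.GENonlinearity(K=1, seed=0)
        nl.a, nl.b, nl.c, nl.d = 1.0, np.array([2.0]), np.array([1.0]), np.array([0.0])
    else:
        nl = lm.LinearNonlinearity()
    if noise == "skewt":
        nz = lm.SkewTNoise(poly_order=0)
        nz.s_coeffs[:] = np.log(s)
        nz.a_coeffs[:] = np.log(6.0)
        nz.b_coeffs[:] = np.log(3.0)
    else:
        nz = lm.GaussianNoise(poly_order=0)
        nz.s_coeffs[:] = np.log(s)
    model = lm.LatentModel(gp, lm.GEMeasurement(nl, nz))
    seqs = random_sequences(2000, L, seed=seed + 100)
    fix_diffeomorphic(model, model.phi(seqs))
    return model


def simulate_ge(model, n=5000, seed=2):
    seqs = random_sequences(n, model.gpmap.L, seed=seed)
    return simulate_dataset(model, SimulationSpec(n=n, sequences=seqs, seed=seed + 1))


@pytest.fixture(scope="session")
def ge_truth_and_data():
    model = make_ge_truth()
    return model, simulate_ge(model, n=5000, seed=2)


@pytest.fixture(scope="session")
def ge_fit(ge_truth_and_data):
    """One shared additive+GE skew-t fit used by several tests."""
    truth, data = ge_truth_and_data
    result = lm.fit(
        data,
        gpmap="additive",
        noise="skewt",
        config=lm.LossConfig(seed=3, epochs=400),
        split=lm.SplitSpec(seed=3),
    )
    return truth, data, result
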