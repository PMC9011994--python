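"""Self-contained benchmark experiments on simulated data.

These reproduce, at desk scale, the validation experiments that motivate the
package: closed-form checks of the information estimators, gauge-invariance
checks, ground-truth parameter recovery for a global-epistasis model with a
skewed-t noise model, the double-mutant-subsampling experiment (how many
double mutants does it take to deconvolve the measurement nonlinearity), and
the model-performance inequality I_var <= I_pre <= I_int on held-out data.

Every function simulates its own inputs from a stated ground truth, runs the
package, and returns plain numbers; they are used by both the test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .gauge import fix_diffeomorphic, hierarchical_gauge, position_probability_matrix
from .gpmaps import LinearGPMap
from .info_metrics import (
    knn_entropy,
    ksg_mutual_information,
    predictive_information,
    subsample_uncertainty,
    variational_information,
)
from .measurement_ge import (
    GaussianNoise,
    GEMeasurement,
    GENonlinearity,
    SkewTNoise,
)
from .measurement_mpa import MPAMeasurement
from .model import LatentModel
from .simulate_bootstrap import SimulationSpec, draw_sequences, simulate_dataset
from .training import LossConfig, SplitSpec, fit

__all__ = [
    "estimator_closed_form_checks",
    "gauge_invariance_checks",
    "ge_ground_truth",
    "parameter_recovery",
    "double_mutant_deconvolution",
    "information_inequality",
]


def estimator_closed_form_checks(n: int = 10_000, seed: int = 0) -> dict:
    """kNN entropy and KSG MI against closed forms (values in bits)."""
    rng = np.random.default_rng(seed)
    rho = 0.9
    xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    return {
        "knn_entropy_uniform_bits": knn_entropy(rng.uniform(size=n)),
        "knn_entropy_normal_bits": knn_entropy(rng.normal(size=n)),
        "ksg_mi_gaussian_rho09_bits": ksg_mutual_information(xy[:, 0], xy[:, 1]),
    }


def gauge_invariance_checks(seed: int = 0, n_seq: int = 1000, L: int = 5) -> dict:
    """Hierarchical gauge: phi preservation and the two-character hand case."""
    rng = np.random.default_rng(seed)
    gp = LinearGPMap(L, "dna", "pairwise")
    gp.theta_0 = rng.normal()
    gp.theta_lc = rng.normal(size=(L, 4))
    gp.theta_pair = rng.normal(size=gp.theta_pair.shape)
    chars = np.array(list("ACGT"))
    seqs = ["".join(chars[i]) for i in rng.integers(4, size=(n_seq, L))]
    p = position_probability_matrix("uniform", L, "dna")
    fixed = hierarchical_gauge(gp, p)
    twice = hierarchical_gauge(fixed, p)
    hand = LinearGPMap(1, "AB", "additive")
    hand.theta_lc = np.array([[2.0, 4.0]])
    hand_fixed = hierarchical_gauge(hand, np.array([[0.5, 0.5]]))
    return {
        "gauge_phi_max_abs_change": float(np.abs(fixed.phi(seqs) - gp.phi(seqs)).max()),
        "gauge_idempotence_max_param_change": float(
            np.abs(fixed.get_params() - twice.get_params()).max()
        ),
        "gauge_hand_case_theta0": float(hand_fixed.theta_0),
        "gauge_hand_case_theta_max_err": float(
            np.abs(hand_fixed.theta_lc - np.array([[-1.0, 1.0]])).max()
        ),
    }


def ge_ground_truth(
    L: int = 10,
    seed: int = 1,
    noise_scale: float = 0.15,
    standardize_on=None,
) -> LatentModel:
    """Additive DNA map + sigmoidal nonlinearity + skewed-t noise.

    phi is standardized (mean 0, std 1) over ``standardize_on`` sequences, or
    over random sequences by default, so the sigmoid spans the relevant phi
    range the way an assay's dynamic range spans its library.
    """
    rng = np.random.default_rng(seed)
    gp = LinearGPMap(L, "dna", "additive")
    gp.theta_lc = rng.normal(0, 1, size=(L, 4))
    nl = GENonlinearity(K=1, seed=0)
    nl.a, nl.b, nl.c, nl.d = 1.0, np.array([2.0]), np.array([1.0]), np.array([0.0])
    nz = SkewTNoise(poly_order=0)
    nz.s_coeffs[:] = np.log(noise_scale)
    nz.a_coeffs[:] = np.log(6.0)
    nz.b_coeffs[:] = np.log(3.0)
    model = LatentModel(gp, GEMeasurement(nl, nz))
    if standardize_on is None:
        standardize_on = draw_sequences(
            SimulationSpec(n=2000, seed=seed + 100, random_length=L), "dna"
        )
    fix_diffeomorphic(model, model.phi(standardize_on))
    return model


def parameter_recovery(n: int = 5000, seed: int = 1, epochs: int = 400) -> dict:
    """Simulate from a known GE model, refit, and compare gauge-fixed parameters.

    Returns the R^2 between true and recovered additive effects (both in the
    uniform hierarchical gauge) and the maximum deviation of the recovered
    nonlinearity from the truth, as a fraction of the measurement range, over
    the phi range covered by held-out data.
    """
    truth = ge_ground_truth(seed=seed)
    L = truth.gpmap.L
    seqs = draw_sequences(SimulationSpec(n=n, seed=seed + 200, random_length=L), "dna")
    data = simulate_dataset(truth, SimulationSpec(n=n, sequences=seqs, seed=seed + 300))
    res = fit(
        data,
        gpmap="additive",
        noise="skewt",
        config=LossConfig(seed=seed, epochs=epochs),
        split=SplitSpec(seed=seed),
    )
    p = position_probability_matrix("uniform", L, "dna")
    t = hierarchical_gauge(truth.gpmap, p).theta_lc.ravel()
    f = res.model.gpmap.theta_lc.ravel()
    mask = np.isfinite(f)
    r2 = float(np.corrcoef(t[mask], f[mask])[0, 1] ** 2)
    test_seqs = res.test.sequences
    yhat_true = truth.measurement.yhat(truth.phi(test_seqs))
    yhat_fit = res.model.measurement.yhat(res.model.phi(test_seqs))
    y_range = float(data.y.max() - data.y.min())
    g_dev = float(
        _max_dev_on_covered_range(truth.phi(test_seqs), yhat_true, yhat_fit) / y_range
    )
    return {
        "recovery_theta_r2": r2,
        "recovery_g_max_dev_frac": g_dev,
        "n": n,
    }


def double_mutant_deconvolution(
    seed: int = 1,
    n_doubles_full: int = 1500,
    n_doubles_small: int = 500,
    L: int = 20,
    epochs: int = 400,
) -> dict:
    """How many double mutants are needed to deconvolve the nonlinearity?

    Simulates a library of the wildtype, all single mutants, and sampled
    double mutants through a sigmoidal nonlinearity, then fits using all
    singles plus either a full or a small complement of doubles. Returns the
    maximum deviation between the two recovered measurement functions (and
    each vs truth), as fractions of the y-range, on shared evaluation
    sequences.
    """
    wt = "A" * L
    # standardize the truth over the mutant-library distribution so the
    # sigmoid's dynamic range covers the library, as in a real DMS assay
    lib_sample = draw_sequences(
        SimulationSpec(n=1, seed=seed + 900, wildtype=wt, n_doubles=1500), "dna"
    )
    truth = ge_ground_truth(L=L, seed=seed, standardize_on=lib_sample)

    def library(n_doubles, sim_seed):
        spec = SimulationSpec(n=1, seed=sim_seed, wildtype=wt, n_doubles=n_doubles)
        seqs = draw_sequences(spec, "dna")
        return simulate_dataset(
            truth, SimulationSpec(n=len(seqs), sequences=seqs, seed=sim_seed + 1)
        )

    data_full = library(n_doubles_full, seed + 400)
    data_small = library(n_doubles_small, seed + 500)
    fits = {}
    for name, data in (("full", data_full), ("small", data_small)):
        fits[name] = fit(
            data,
            gpmap="additive",
            noise="skewt",
            config=LossConfig(seed=seed, epochs=epochs),
            split=SplitSpec(0.8, 0.1, 0.1, seed=seed),
        ).model
    eval_seqs = data_small.sequences  # phi range covered by the small library
    y_range = float(data_full.y.max() - data_full.y.min())

    def curve(model):
        # the measurement function as a curve over the data-covered phi band,
        # quantile-matched so fits with different phi scales are comparable
        phi = model.phi(eval_seqs)
        qs = np.percentile(phi[np.isfinite(phi)], np.linspace(1, 99, 99))
        return model.measurement.yhat(qs)

    c_true = curve(truth)
    c_full = curve(fits["full"])
    c_small = curve(fits["small"])
    dev = lambda a, b: float(np.abs(a - b).max() / y_range)
    return {
        "deconv_small_vs_full_max_dev_frac": dev(c_small, c_full),
        "deconv_full_vs_truth_max_dev_frac": dev(c_full, c_true),
        "deconv_small_vs_truth_max_dev_frac": dev(c_small, c_true),
        "n_doubles_small": n_doubles_small,
        "n_doubles_full": n_doubles_full,
    }


def _max_dev_on_covered_range(phi, a, b):
    """Max |a - b| over the phi band populated by data (1st-99th percentile).

    The extreme tail of a mutant library holds isolated sequences (often just
    the wildtype) that cannot constrain the measurement function there; the
    band comparison mirrors how overlaid nonlinearities are read off a plot.
    """
    lo, hi = np.nanpercentile(phi, [1, 99])
    m = (phi >= lo) & (phi <= hi)
    return np.nanmax(np.abs(np.asarray(a)[m] - np.asarray(b)[m]))


def information_inequality(
    n_draws: int = 10, n: int = 2000, seed: int = 0, R: int = 15
) -> dict:
    """I_var <= I_pre <= I_int-upper across GE and MPA modes on held-out data.

    Each draw generates a dataset from a random ground truth and evaluates an
    *imperfect* model, as in practice. GE draws: the truth is a pairwise map
    read out through a sigmoid with Gaussian noise, and an additive model is
    fitted to the data — its latent phenotype discards the interaction
    information, so I_var < I_pre < I_int, each gap genuine. The
    intrinsic-information upper bound uses the exact conditional entropy of
    the simulated channel. MPA draws evaluate the true model against the
    (loose) discrete bound I_int <= H[y]. Returns the fraction of draws in
    which each inequality holds within two joint standard errors.
    """
    rng = np.random.default_rng(seed)
    ok_var_pre, ok_pre_int = [], []
    slack_var_pre, slack_pre_int = [], []
    for d in range(n_draws):
        mode = "ge" if d % 2 == 0 else "mpa"
        sub = int(rng.integers(2**31 - 1))
        r = np.random.default_rng(sub)
        # L = 10 keeps phi values distinct at n = 2000 (4^10 sequences);
        # heavy phi duplication biases the per-bin kNN entropies
        L = 10
        if mode == "ge":
            gp = LinearGPMap(L, "dna", "pairwise")
            gp.theta_lc = r.normal(size=(L, 4))
            gp.theta_pair = r.normal(0, 0.35, size=gp.theta_pair.shape)
            nl = GENonlinearity(K=1, seed=0)
            nl.a, nl.b, nl.c, nl.d = (
                r.normal(),
                np.array([1.0 + r.uniform()]),
                np.array([0.5 + r.uniform()]),
                np.array([r.normal() * 0.3]),
            )
            s = 0.2 + 0.3 * r.uniform()
            nz = GaussianNoise(poly_order=0)
            nz.s_coeffs[0] = np.log(s)
            model = LatentModel(gp, GEMeasurement(nl, nz))
        else:
            gp = LinearGPMap(L, "dna", "additive")
            gp.theta_lc = r.normal(size=(L, 4))
            meas = MPAMeasurement(Y=4, K=3, seed=sub % 1000)
            meas.b = np.outer(np.linspace(-2, 2, 4), np.ones(3) / 3)
            meas.c = np.ones((4, 3)) * (0.5 + r.uniform())
            meas.d = np.zeros((4, 3))
            model = LatentModel(gp, meas)
        seqs = draw_sequences(SimulationSpec(n=n, seed=sub, random_length=L), "dna")
        fix_diffeomorphic(model, model.phi(seqs))
        data = simulate_dataset(model, SimulationSpec(n=n, sequences=seqs, seed=sub + 1))
        if mode == "ge":
            res = fit(
                data,
                gpmap="additive",
                noise="gaussian",
                config=LossConfig(seed=sub % 100000, epochs=150),
                split=SplitSpec(0.7, 0.15, 0.15, seed=sub % 100000),
            )
            eval_model, eval_data = res.model, res.test
        else:
            eval_model, eval_data = model, data
        i_var, d_var = variational_information(eval_model, eval_data, R=R, seed=sub)
        i_pre, d_pre = predictive_information(eval_model, eval_data, R=R, seed=sub)
        if mode == "ge":
            h_y = knn_entropy(eval_data.y, seed=sub)
            dh = subsample_uncertainty(
                lambda v: knn_entropy(v, seed=sub), eval_data.y, R=R, seed=sub
            )
            s = float(np.exp(model.measurement.noise.s_coeffs[0]))
            h_cond = 0.5 * np.log2(2 * np.pi * np.e * s**2)
            i_int_up, d_int = h_y - h_cond, dh
        else:
            from .info_metrics import discrete_entropy

            i_int_up = discrete_entropy(eval_data.bins)
            d_int = subsample_uncertainty(
                discrete_entropy, eval_data.bins, R=R, seed=sub
            )
        j1 = float(np.hypot(d_var, d_pre))
        j2 = float(np.hypot(d_pre, d_int))
        ok_var_pre.append(i_var <= i_pre + 2 * j1)
        ok_pre_int.append(i_pre <= i_int_up + 2 * j2)
        slack_var_pre.append(i_pre - i_var)
        slack_pre_int.append(i_int_up - i_pre)
    return {
        "ineq_frac_ivar_le_ipre": float(np.mean(ok_var_pre)),
        "ineq_frac_ipre_le_iint": float(np.mean(ok_pre_int)),
        "ineq_mean_ipre_minus_ivar_bits": float(np.mean(slack_var_pre)),
        "ineq_mean_iint_minus_ipre_bits": float(np.mean(slack_pre_int)),
        "n_draws": n_draws,
        "n": n,
    }
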