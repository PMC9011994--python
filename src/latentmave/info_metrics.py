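"""Information-theoretic model assessment in bits.

Three nested quantities, all evaluated on held-out data:

* **Variational information** ``I_var = H[y] - (log2 e / N) * L_like`` — an
  affine transform of the log likelihood; a lower bound on I_pre that is
  tight when the measurement process matches the true p(y | phi).
* **Predictive information** ``I_pre = I[y; phi]`` — mutual information
  between measurements and the latent phenotype; independent of the
  measurement-process parameters.
* **Intrinsic information** ``I_int = I[x; y]`` — bounded above via
  Poisson-propagated read-count noise and below by replicate MI or by any
  model's I_pre (data-processing inequality), so that
  I_var <= I_pre <= I_int on test data up to estimator error.

Continuous entropies use the Kozachenko-Leonenko kNN estimator; mutual
information between continuous pairs uses the Kraskov-Stögbauer-Grassberger
(KSG) estimator. Uncertainties come from repeated half-sample subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .data import SequenceDataset
from .model import LatentModel

__all__ = [
    "knn_entropy",
    "ksg_mutual_information",
    "discrete_entropy",
    "predictive_information",
    "variational_information",
    "intrinsic_info_upper",
    "intrinsic_info_lower",
    "subsample_uncertainty",
    "InfoReport",
    "evaluate_model",
]

_LN2 = np.log(2.0)
_JITTER = 1e-10  # relative tie-break jitter for kNN estimators


def _jitter(x: np.ndarray, rng) -> np.ndarray:
    """Break ties with tiny uniform jitter; kNN estimators need distinct distances."""
    x = np.asarray(x, float)
    span = np.ptp(x)
    scale = _JITTER * (span if span > 0 else 1.0)
    return x + rng.uniform(-scale, scale, size=x.shape)


def knn_entropy(samples, k: int = 5, seed: int = 0) -> float:
    """Kozachenko-Leonenko differential entropy estimate, in bits.

    1-D continuous samples; ``n > k >= 1``. Duplicate-heavy samples are
    de-tied with seeded jitter of 1e-10 x data range.
    """
    x = np.asarray(samples, float).reshape(-1, 1)
    n = x.shape[0]
    if not n > k >= 1:
        raise ValueError("need n > k >= 1")
    x = _jitter(x, np.random.default_rng(seed))
    r = cKDTree(x).query(x, k=k + 1, p=np.inf)[0][:, k]
    # max-norm ball of radius r has length 2r in 1-D
    return float((digamma(n) - digamma(k) + np.mean(np.log(2 * r))) / _LN2)


def ksg_mutual_information(y, phi, k: int = 5, seed: int = 0) -> float:
    """KSG (algorithm 1) mutual information between paired 1-D samples, in bits.

    Chebyshev (max-norm) balls in the joint space. Small negative estimates
    are floored at 0 with a warning. A constant input gives 0 with a warning.
    """
    y = np.asarray(y, float)
    phi = np.asarray(phi, float)
    n = len(y)
    if len(phi) != n:
        raise ValueError("paired samples must have equal length")
    if not n > k:
        raise ValueError("need n > k")
    if np.ptp(y) == 0 or np.ptp(phi) == 0:
        warnings.warn("constant input to MI estimator; returning 0 bits")
        return 0.0
    rng = np.random.default_rng(seed)
    y = _jitter(y, rng)
    phi = _jitter(phi, rng)
    z = np.column_stack([y, phi])
    eps = cKDTree(z).query(z, k=k + 1, p=np.inf)[0][:, k]
    ys, ps = np.sort(y), np.sort(phi)
    # counts of points strictly inside the eps-ball in each marginal (incl. self)
    ny = np.searchsorted(ys, y + eps, "left") - np.searchsorted(ys, y - eps, "right")
    np_ = np.searchsorted(ps, phi + eps, "left") - np.searchsorted(
        ps, phi - eps, "right"
    )
    mi = (digamma(k) + digamma(n) - np.mean(digamma(ny) + digamma(np_))) / _LN2
    if mi < 0:
        warnings.warn(f"negative MI estimate ({mi:.4f} bits) floored at 0")
        return 0.0
    return float(mi)


def discrete_entropy(labels) -> float:
    """Plug-in entropy of a discrete sample, in bits."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def subsample_uncertainty(estimator, data, R: int = 25, seed: int = 0) -> float:
    """Half-sample uncertainty of an estimator: std of R half-sample values / sqrt 2.

    ``data`` is an array or tuple of equal-length arrays; ``estimator`` is
    called on the subsampled arrays.
    """
    if R < 2:
        raise ValueError("need R >= 2 subsamples")
    arrays = data if isinstance(data, tuple) else (data,)
    n = len(arrays[0])
    if n < 4:
        raise ValueError("data too small to halve")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(R):
        idx = rng.choice(n, size=n // 2, replace=False)
        vals.append(estimator(*(a[idx] for a in arrays)))
    return float(np.std(vals) / np.sqrt(2.0))


# -- model-level metrics -----------------------------------------------------


def variational_information(
    model: LatentModel, dataset: SequenceDataset, k: int = 5, R: int = 25, seed: int = 0
):
    """I_var = H[y] - mean(Q_n) in bits, with Q_n = -log2 p(y_n | phi_n).

    Uncertainty combines the half-sample error of H[y] with the standard
    error of mean(Q_n). Zero-probability data are clipped to a large finite
    penalty.
    """
    q = -np.clip(model.per_datum_log2p(dataset), -1010.0, None)
    N = len(q)
    if model.mode == "ge":
        h_y = knn_entropy(dataset.y, k=k, seed=seed)
        dh = subsample_uncertainty(
            lambda y: knn_entropy(y, k=k, seed=seed), dataset.y, R=R, seed=seed
        )
    else:
        labels = dataset.bins
        if labels is None:
            raise ValueError("I_var for MPA needs per-read (bin) data")
        h_y = discrete_entropy(labels)
        dh = subsample_uncertainty(discrete_entropy, labels, R=R, seed=seed)
    i_var = h_y - float(np.mean(q))
    delta = float(np.sqrt(dh**2 + np.var(q) / N))
    return i_var, delta


def predictive_information(
    model: LatentModel, dataset: SequenceDataset, k: int = 5, R: int = 25, seed: int = 0
):
    """I_pre = I[y; phi] on held-out data, in bits, with half-sample uncertainty.

    Continuous y: KSG estimator on (y, phi). Discrete y: entropy decomposition
    H[phi] - sum_y p(y) H_y[phi] with per-bin kNN entropies.
    """
    phi = model.phi(dataset.sequences)
    if len(dataset) <= k + 1:
        raise ValueError("test set too small for the kNN estimator")
    if model.mode == "ge":
        est = lambda y, f: ksg_mutual_information(y, f, k=k, seed=seed)
        val = est(dataset.y, phi)
        delta = subsample_uncertainty(est, (dataset.y, phi), R=R, seed=seed)
        return val, delta
    labels = dataset.bins
    if labels is None:
        raise ValueError("I_pre for MPA needs per-read (bin) data")

    def mi_disc(f, lab):
        h = knn_entropy(f, k=k, seed=seed)
        out = h
        for b, cnt in zip(*np.unique(lab, return_counts=True)):
            if cnt > k + 1:
                out -= (cnt / len(lab)) * knn_entropy(f[lab == b], k=k, seed=seed)
        return max(out, 0.0)

    val = mi_disc(phi, labels)
    delta = subsample_uncertainty(mi_disc, (phi, labels), R=R, seed=seed)
    return val, delta


def intrinsic_info_upper(
    y, c_in, c_out, k: int = 5, R: int = 25, seed: int = 0
):
    """Upper bound on I[x; y] from Poisson read-count noise, in bits.

    Per-variant measurement noise is propagated as
    ``dy_n = log2(e) * sqrt(1/(c_in+1) + 1/(c_out+1))`` and p(y|x) is taken
    Gaussian, giving conditional entropy ``0.5 * log2(2 pi e dy_n^2)``; the
    bound is H[y] - mean of these. Counts so deep that the conditional
    entropy diverges to -inf make the bound approach H[y]'s maximum; inputs
    are validated instead of guarded. Over-dispersed counts (beyond Poisson)
    make this bound unreliable (too high).
    """
    y = np.asarray(y, float)
    c_in = np.asarray(c_in, float)
    c_out = np.asarray(c_out, float)
    if len(c_in) != len(y) or len(c_out) != len(y):
        raise ValueError("counts must be given per variant")
    dy = np.log2(np.e) * np.sqrt(1.0 / (c_in + 1) + 1.0 / (c_out + 1))
    h_cond = 0.5 * np.log2(2 * np.pi * np.e * dy**2)
    h_y = knn_entropy(y, k=k, seed=seed)
    dh = subsample_uncertainty(
        lambda v: knn_entropy(v, k=k, seed=seed), y, R=R, seed=seed
    )
    d_cond = float(np.std(h_cond) / np.sqrt(len(y)))
    return h_y - float(np.mean(h_cond)), float(np.sqrt(dh**2 + d_cond**2))


def intrinsic_info_lower(
    y=None, y_replicate=None, model_i_pre: float | None = None,
    model_i_pre_err: float = 0.0, k: int = 5, R: int = 25, seed: int = 0,
):
    """Lower bound on I[x; y]: the best of replicate MI and a model's I_pre.

    ``I[x; y] >= I[y; y']`` for replicate measurements y' (Markov chain
    y <- x -> y'), and ``I[x; y] >= I_pre`` for any model on test data.
    """
    candidates = []
    if y is not None and y_replicate is not None:
        est = lambda a, b: ksg_mutual_information(a, b, k=k, seed=seed)
        val = est(np.asarray(y, float), np.asarray(y_replicate, float))
        err = subsample_uncertainty(
            est, (np.asarray(y, float), np.asarray(y_replicate, float)), R=R, seed=seed
        )
        candidates.append((val, err))
    if model_i_pre is not None:
        candidates.append((float(model_i_pre), float(model_i_pre_err)))
    if not candidates:
        raise ValueError("need replicate measurements or a model's I_pre")
    return max(candidates, key=lambda t: t[0])


@dataclass
class InfoReport:
    """Model-performance metrics in bits with standard errors."""

    i_var: float
    d_i_var: float
    i_pre: float
    d_i_pre: float
    n: int
    k: int
    i_int_lower: float | None = None
    d_i_int_lower: float | None = None
    i_int_upper: float | None = None
    d_i_int_upper: float | None = None

    def to_frame(self):
        import pandas as pd

        rows = [
            ("I_var", self.i_var, self.d_i_var),
            ("I_pre", self.i_pre, self.d_i_pre),
        ]
        if self.i_int_lower is not None:
            rows.append(("I_int_lower", self.i_int_lower, self.d_i_int_lower))
        if self.i_int_upper is not None:
            rows.append(("I_int_upper", self.i_int_upper, self.d_i_int_upper))
        return pd.DataFrame(rows, columns=["metric", "bits", "stderr"])


def evaluate_model(
    model: LatentModel, dataset: SequenceDataset, k: int = 5, R: int = 25, seed: int = 0
) -> InfoReport:
    """I_var and I_pre (with uncertainties) of a model on held-out data."""
    i_var, d_var = variational_information(model, dataset, k=k, R=R, seed=seed)
    i_pre, d_pre = predictive_information(model, dataset, k=k, R=R, seed=seed)
    return InfoReport(i_var, d_var, i_pre, d_pre, n=len(dataset), k=k)
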