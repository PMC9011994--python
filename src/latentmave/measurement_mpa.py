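"""Measurement-process-agnostic (MPA) measurement process.

For discrete/binned readouts (e.g. sort-seq), the distribution over bins is a
softmax over per-bin weights, each a one-hidden-layer tanh network of the
latent phenotype:

    p(y | phi) = w_y(phi) / sum_y' w_y'(phi),
    w_y(phi)   = exp[a_y + sum_k b_yk tanh(c_yk phi + d_yk)].

Bins must be contiguous integers starting at 0 (see
:func:`latentmave.data.relabel_bins`). The likelihood of per-read
(sequence, bin) pairs equals that of the collapsed per-sequence count matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MPAMeasurement"]


class MPAMeasurement:
    """Softmax measurement process over ``Y >= 2`` bins with ``K`` hidden nodes per bin."""

    mode = "mpa"

    def __init__(self, Y: int, K: int = 10, seed: int = 0):
        if Y < 2:
            raise ValueError("need Y >= 2 bins")
        if K < 1:
            raise ValueError("need K >= 1 hidden nodes per bin")
        self.Y, self.K = int(Y), int(K)
        rng = np.random.default_rng(seed)
        self.a = np.zeros(Y)
        self.b = 0.1 * rng.normal(size=(Y, K))
        self.c = 1.0 + 0.1 * rng.normal(size=(Y, K))
        self.d = np.linspace(-1, 1, K) * np.ones((Y, 1))

    # flat parameters --------------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.Y * (1 + 3 * self.K)

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [self.a, self.b.ravel(), self.c.ravel(), self.d.ravel()]
        )

    def set_params(self, vec) -> None:
        vec = np.asarray(vec, float)
        Y, K = self.Y, self.K
        self.a = vec[:Y].copy()
        self.b = vec[Y : Y + Y * K].reshape(Y, K).copy()
        self.c = vec[Y + Y * K : Y + 2 * Y * K].reshape(Y, K).copy()
        self.d = vec[Y + 2 * Y * K :].reshape(Y, K).copy()

    # forward ------------------------------------------------------------------
    def log_weights(self, phi) -> np.ndarray:
        """(N, Y) array of log w_y(phi)."""
        phi = np.atleast_1d(np.asarray(phi, float))
        z = phi[:, None, None] * self.c[None] + self.d[None]  # (N, Y, K)
        return self.a[None] + np.einsum("nyk,yk->ny", np.tanh(z), self.b)

    def probabilities(self, phi) -> np.ndarray:
        """p(y | phi) for each bin; rows are positive and sum to 1."""
        lw = self.log_weights(phi)
        lw -= lw.max(axis=1, keepdims=True)
        w = np.exp(lw)
        return w / w.sum(axis=1, keepdims=True)

    def log_probabilities(self, phi) -> np.ndarray:
        lw = self.log_weights(phi)
        m = lw.max(axis=1, keepdims=True)
        return lw - m - np.log(np.exp(lw - m).sum(axis=1, keepdims=True))

    # likelihood ----------------------------------------------------------------
    def nll_counts(self, counts: np.ndarray, phi) -> float:
        """-sum_m sum_y c_my log p(y | phi_m), in nats."""
        logp = self.log_probabilities(phi)
        return float(-np.sum(counts * logp))

    def nll_backprop(self, counts: np.ndarray, phi):
        """Return (nll, dnll/dphi, dnll/dparams) for a count matrix."""
        phi = np.asarray(phi, float)
        z = phi[:, None, None] * self.c[None] + self.d[None]  # (N,Y,K)
        t = np.tanh(z)
        lw = self.a[None] + np.einsum("nyk,yk->ny", t, self.b)
        m = lw.max(axis=1, keepdims=True)
        p = np.exp(lw - m)
        p /= p.sum(axis=1, keepdims=True)
        logp = np.log(p)
        nll = float(-np.sum(counts * logp))
        n_tot = counts.sum(axis=1)  # reads per sequence
        # d nll / d lw_{ny} = n_tot_n * p_{ny} - c_{ny}
        dlw = n_tot[:, None] * p - counts
        sech2 = 1.0 - t**2
        g_a = dlw.sum(axis=0)
        g_b = np.einsum("ny,nyk->yk", dlw, t)
        g_c = np.einsum("ny,nyk,n->yk", dlw, sech2 * self.b[None], phi)
        g_d = np.einsum("ny,nyk->yk", dlw, sech2 * self.b[None])
        dphi = np.einsum("ny,nyk,yk->n", dlw, sech2, self.b * self.c)
        grads = np.concatenate([g_a, g_b.ravel(), g_c.ravel(), g_d.ravel()])
        return nll, dphi, grads

    # misc ------------------------------------------------------------------------
    def sample(self, phi, rng) -> np.ndarray:
        """Draw one bin per phi value from p(y | phi)."""
        p = self.probabilities(phi)
        cum = np.cumsum(p, axis=1)
        u = rng.uniform(size=(p.shape[0], 1))
        return (u > cum).sum(axis=1).astype(np.int64)

    def shift_scale_phi(self, a0: float, b0: float) -> None:
        """Reparameterize so new p(y|phi) equals old p(y | a0 + b0*phi)."""
        self.d = self.d + self.c * a0
        self.c = self.c * b0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "Y": self.Y,
            "K": self.K,
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "d": self.d.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MPAMeasurement":
        out = cls(Y=d["Y"], K=d["K"])
        out.a = np.asarray(d["a"], float)
        out.b = np.asarray(d["b"], float)
        out.c = np.asarray(d["c"], float)
        out.d = np.asarray(d["d"], float)
        return out
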