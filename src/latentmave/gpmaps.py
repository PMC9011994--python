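"""Genotype-phenotype maps: deterministic latent-phenotype functions phi(x; theta).

Four built-in families are provided. The three parametric maps are linear in
their parameters:

* additive:  phi = theta_0 + sum_l theta[l, c(l)]
* neighbor:  additive + interactions between adjacent positions
* pairwise:  additive + interactions between all position pairs (l' > l)

and the black-box map is a densely connected multilayer perceptron over
sequence features with a single linear output. Custom maps (e.g. thermodynamic
models, :mod:`latentmave.biophysics`) subclass :class:`CustomGPMap`.

All maps expose the same training interface: a cached ``design`` of the input
sequences, ``phi_from_design``, and ``backprop`` returning the gradient of a
scalar loss with respect to the flat parameter vector.
"""

from __future__ import annotations

import numpy as np

from .alphabets import Alphabet, get_alphabet
from .data import one_hot_matrix

__all__ = [
    "GPMap",
    "LinearGPMap",
    "AdditiveGPMap",
    "NeighborGPMap",
    "PairwiseGPMap",
    "BlackBoxGPMap",
    "CustomGPMap",
    "make_gpmap",
]


class GPMap:
    """Base interface shared by all genotype-phenotype maps."""

    L: int
    alphabet: Alphabet
    kind: str

    # -- flat parameter vector ---------------------------------------------
    @property
    def n_params(self) -> int:
        raise NotImplementedError

    def get_params(self) -> np.ndarray:
        raise NotImplementedError

    def set_params(self, vec: np.ndarray) -> None:
        raise NotImplementedError

    # -- evaluation ----------------------------------------------------------
    def design(self, sequences) -> np.ndarray:
        """Precompute the per-sequence input representation used in training."""
        raise NotImplementedError

    def phi_from_design(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backprop(self, X: np.ndarray, dphi: np.ndarray) -> np.ndarray:
        """Gradient of the loss w.r.t. the flat parameter vector, given dL/dphi."""
        raise NotImplementedError

    def phi(self, sequences) -> np.ndarray:
        """Latent phenotype for a list of sequences."""
        return self.phi_from_design(self.design(sequences))


def _pair_list(L: int, kind: str) -> list[tuple[int, int]]:
    if kind == "neighbor":
        return [(l, l + 1) for l in range(L - 1)]
    if kind == "pairwise":
        return [(l, lp) for l in range(L) for lp in range(l + 1, L)]
    return []


class LinearGPMap(GPMap):
    """Parametric map, linear in theta; covers additive/neighbor/pairwise.

    Parameters for characters never observed at a position in the training
    data are stored as NaN ("could not be assigned"); evaluating phi on a
    sequence that uses such a character yields NaN rather than a silently
    wrong number.

    Feature order is fixed and documented: the constant, then theta[l, c]
    row-major by (l, then alphabet order), then interaction blocks row-major
    by (l, l') with l' > l, each block row-major by (c, c').
    """

    def __init__(self, L: int, alphabet, kind: str = "additive"):
        if kind not in ("additive", "neighbor", "pairwise"):
            raise ValueError(f"unknown linear G-P map kind {kind!r}")
        self.L = int(L)
        self.alphabet = get_alphabet(alphabet)
        self.C = len(self.alphabet)
        self.kind = kind
        self.pairs = _pair_list(self.L, kind)
        self.theta_0 = 0.0
        self.theta_lc = np.zeros((self.L, self.C))
        # (P, C, C) interaction tensor; empty for additive
        self.theta_pair = np.zeros((len(self.pairs), self.C, self.C))

    # -- parameter vector ----------------------------------------------------
    @property
    def n_params(self) -> int:
        return 1 + self.theta_lc.size + self.theta_pair.size

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [[self.theta_0], self.theta_lc.ravel(), self.theta_pair.ravel()]
        )

    def set_params(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, float)
        if vec.shape != (self.n_params,):
            raise ValueError("parameter vector has wrong length")
        self.theta_0 = float(vec[0])
        na = self.theta_lc.size
        self.theta_lc = vec[1 : 1 + na].reshape(self.L, self.C).copy()
        self.theta_pair = (
            vec[1 + na :].reshape(len(self.pairs), self.C, self.C).copy()
        )

    def theta_lclc(self) -> np.ndarray:
        """Interactions as a dense (L, C, L, C) tensor, zero where l' <= l."""
        t = np.zeros((self.L, self.C, self.L, self.C))
        for p, (l, lp) in enumerate(self.pairs):
            t[l, :, lp, :] = self.theta_pair[p]
        return t

    def set_theta_lclc(self, t: np.ndarray) -> None:
        for p, (l, lp) in enumerate(self.pairs):
            self.theta_pair[p] = t[l, :, lp, :]

    # -- features ------------------------------------------------------------
    def design(self, sequences) -> np.ndarray:
        X = one_hot_matrix(sequences, self.alphabet)  # (N, L, C)
        N = X.shape[0]
        blocks = [np.ones((N, 1)), X.reshape(N, -1)]
        if self.pairs:
            P = len(self.pairs)
            pair_feats = np.zeros((N, P, self.C, self.C))
            for p, (l, lp) in enumerate(self.pairs):
                pair_feats[:, p] = X[:, l, :, None] * X[:, lp, None, :]
            blocks.append(pair_feats.reshape(N, -1))
        return np.concatenate(blocks, axis=1)

    def phi_from_design(self, X: np.ndarray) -> np.ndarray:
        w = self.get_params()
        nan_mask = ~np.isfinite(w)
        phi = X @ np.where(nan_mask, 0.0, w)
        if nan_mask.any():
            undefined = (X[:, nan_mask] != 0).any(axis=1)
            phi = np.where(undefined, np.nan, phi)
        return phi

    def backprop(self, X: np.ndarray, dphi: np.ndarray) -> np.ndarray:
        return X.T @ dphi

    def copy(self) -> "LinearGPMap":
        out = LinearGPMap(self.L, self.alphabet, self.kind)
        out.theta_0 = self.theta_0
        out.theta_lc = self.theta_lc.copy()
        out.theta_pair = self.theta_pair.copy()
        return out


class AdditiveGPMap(LinearGPMap):
    def __init__(self, L, alphabet):
        super().__init__(L, alphabet, "additive")


class NeighborGPMap(LinearGPMap):
    def __init__(self, L, alphabet):
        super().__init__(L, alphabet, "neighbor")


class PairwiseGPMap(LinearGPMap):
    def __init__(self, L, alphabet):
        super().__init__(L, alphabet, "pairwise")


class BlackBoxGPMap(GPMap):
    """Multilayer perceptron over sequence features, single linear output.

    ``input_features`` selects the feature expansion fed to the network
    (additive = one-hot, neighbor/pairwise add interaction products).
    Hidden layers use tanh activations by default.
    """

    kind = "blackbox"

    def __init__(
        self,
        L: int,
        alphabet,
        hidden_layer_sizes=(10, 10, 10, 10, 10),
        input_features: str = "additive",
        activation: str = "tanh",
        seed: int = 0,
    ):
        if len(hidden_layer_sizes) < 1 or any(h < 1 for h in hidden_layer_sizes):
            raise ValueError("need >= 1 hidden layer with positive sizes")
        if activation not in ("tanh", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.L = int(L)
        self.alphabet = get_alphabet(alphabet)
        self.C = len(self.alphabet)
        self.input_features = input_features
        self.activation = activation
        self._feature_map = LinearGPMap(L, alphabet, kind=input_features)
        n_in = self._feature_map.n_params - 1  # features exclude the constant
        sizes = [n_in, *hidden_layer_sizes, 1]
        rng = np.random.default_rng(seed)
        self.weights = [
            rng.normal(0.0, 1.0 / np.sqrt(sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    # -- flat parameters -----------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    def set_params(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, float)
        pos = 0
        for i, w in enumerate(self.weights):
            self.weights[i] = vec[pos : pos + w.size].reshape(w.shape).copy()
            pos += w.size
        for i, b in enumerate(self.biases):
            self.biases[i] = vec[pos : pos + b.size].copy()
            pos += b.size
        if pos != vec.size:
            raise ValueError("parameter vector has wrong length")

    # -- forward/backward ----------------------------------------------------
    def design(self, sequences) -> np.ndarray:
        return self._feature_map.design(sequences)[:, 1:]  # drop constant

    def _act(self, z):
        return np.tanh(z) if self.activation == "tanh" else np.maximum(z, 0.0)

    def _act_grad(self, a, z):
        return 1.0 - a**2 if self.activation == "tanh" else (z > 0).astype(float)

    def phi_from_design(self, X: np.ndarray) -> np.ndarray:
        a = X
        self._cache = [(None, a)]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            z = a @ w + b
            a = self._act(z)
            self._cache.append((z, a))
        out = a @ self.weights[-1] + self.biases[-1]
        return out[:, 0]

    def backprop(self, X: np.ndarray, dphi: np.ndarray) -> np.ndarray:
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = dphi[:, None]  # (N, 1)
        _, a_last = self._cache[-1]
        grads_w[-1] = a_last.T @ delta
        grads_b[-1] = delta.sum(axis=0)
        da = delta @ self.weights[-1].T
        for i in range(len(self.weights) - 2, -1, -1):
            z, a = self._cache[i + 1]
            dz = da * self._act_grad(a, z)
            _, a_prev = self._cache[i]
            grads_w[i] = a_prev.T @ dz
            grads_b[i] = dz.sum(axis=0)
            if i > 0:
                da = dz @ self.weights[i].T
        return np.concatenate(
            [g.ravel() for g in grads_w] + [g.ravel() for g in grads_b]
        )


class CustomGPMap(GPMap):
    """Contract for user-defined G-P maps (e.g. biophysical models).

    Subclasses implement :meth:`phi_from_onehot` mapping an (N, L, C) one-hot
    array and the current parameters to phi, and may override
    :meth:`backprop` with an analytic gradient; the default is a seeded
    central-difference gradient, adequate for small parameter counts.

    Custom maps are deliberately *not* auto-gauge-fixed: their gauge freedoms
    depend on the model structure and are the author's responsibility.
    """

    kind = "custom"

    def __init__(self, L: int, alphabet, n_params: int):
        self.L = int(L)
        self.alphabet = get_alphabet(alphabet)
        self.C = len(self.alphabet)
        self._params = np.zeros(int(n_params))

    @property
    def n_params(self) -> int:
        return self._params.size

    def get_params(self) -> np.ndarray:
        return self._params.copy()

    def set_params(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, float)
        if vec.shape != self._params.shape:
            raise ValueError("parameter vector has wrong length")
        self._params = vec.copy()

    def design(self, sequences) -> np.ndarray:
        return one_hot_matrix(sequences, self.alphabet)

    def phi_from_onehot(self, X: np.ndarray, params: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def phi_from_design(self, X: np.ndarray) -> np.ndarray:
        phi = self.phi_from_onehot(X, self._params)
        return np.asarray(phi, float)

    def backprop(self, X: np.ndarray, dphi: np.ndarray) -> np.ndarray:
        # central differences over parameters; O(n_params) forward passes
        g = np.zeros(self.n_params)
        h = 1e-6
        p = self._params
        for j in range(p.size):
            step = h * max(1.0, abs(p[j]))
            pp, pm = p.copy(), p.copy()
            pp[j] += step
            pm[j] -= step
            g[j] = dphi @ (
                (self.phi_from_onehot(X, pp) - self.phi_from_onehot(X, pm))
                / (2 * step)
            )
        return g


class FunctionGPMap(CustomGPMap):
    """Wrap a plain callable ``phi(X_onehot, params) -> phi`` as a custom map."""

    def __init__(self, L, alphabet, n_params, func):
        super().__init__(L, alphabet, n_params)
        self._func = func

    def phi_from_onehot(self, X, params):
        return self._func(X, params)


def make_gpmap(kind: str, L: int, alphabet, **kwargs) -> GPMap:
    """Factory for the built-in G-P map families."""
    if kind in ("additive", "neighbor", "pairwise"):
        return LinearGPMap(L, alphabet, kind)
    if kind == "blackbox":
        return BlackBoxGPMap(L, alphabet, **kwargs)
    raise ValueError(f"unknown G-P map kind {kind!r}")
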