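"""Thermodynamic (biophysical) G-P maps built on energy matrices.

These custom maps encode explicit hypotheses about molecular mechanism:
sequence determines Gibbs free energies of molecular states through additive
*energy matrices* (in kcal/mol), and the latent phenotype is the equilibrium
(Boltzmann) occupancy of a readout subset of states,

    phi = sum_{s in readout} exp(-beta * G_s) / sum_{s} exp(-beta * G_s),

so phi is a fraction in (0, 1). Two classic architectures are provided:

* :class:`GB1ThreeStateGPMap` — protein folding/binding with states
  {unfolded: 0, folded: dG_F, folded-bound: dG_F + dG_B}; readout is the
  folded-bound fraction.
* :class:`LacFourStateGPMap` — promoter activation with states
  {empty: 0, CRP: dG_C, RNAP: dG_R, CRP+RNAP: dG_C + dG_R + dG_I}; readout is
  the RNAP-bound fraction (RNAP and CRP+RNAP states), with the scalar
  CRP-RNAP interaction energy dG_I providing cooperative recruitment.

Both are :class:`~latentmave.gpmaps.CustomGPMap` subclasses with analytic
gradients, so they plug into GE/MPA training, simulation, and the bootstrap.
Energy scale: beta defaults to 1/0.593 (kcal/mol)^-1, i.e. ~300 K. Ligand and
protein concentration terms are absorbed into the binding offsets. Each
energy matrix includes a sequence-independent scalar offset.
"""

from __future__ import annotations

import numpy as np

from .alphabets import get_alphabet
from .gauge import hierarchical_gauge
from .gpmaps import CustomGPMap, LinearGPMap

__all__ = [
    "BETA_300K",
    "boltzmann_occupancy",
    "GB1ThreeStateGPMap",
    "LacFourStateGPMap",
]

BETA_300K = 1.0 / 0.593  # inverse temperature in 1/(kcal/mol) at ~300 K


def boltzmann_occupancy(state_energies, readout, beta: float = BETA_300K):
    """Occupancy of a readout subset of states, log-sum-exp guarded.

    ``state_energies`` is (N, S) in kcal/mol (one state per column; include a
    reference state at 0); ``readout`` is an index list. Occupancies of all
    states sum to 1, and phi is invariant to adding a constant to all
    energies.
    """
    G = np.atleast_2d(np.asarray(state_energies, float))
    if not np.all(np.isfinite(G)):
        raise ValueError("state energies must be finite")
    w = -beta * G
    w = w - w.max(axis=1, keepdims=True)
    e = np.exp(w)
    p = e / e.sum(axis=1, keepdims=True)
    return p[:, list(readout)].sum(axis=1)


def _state_probs(G, beta):
    w = -beta * G
    w = w - w.max(axis=1, keepdims=True)
    e = np.exp(w)
    return e / e.sum(axis=1, keepdims=True)


class GB1ThreeStateGPMap(CustomGPMap):
    """Three-state folding/binding map: phi = folded-bound fraction.

    Parameters (flat vector): folding offset, folding energy matrix (L*C),
    binding offset, binding energy matrix (L*C); all in kcal/mol. The
    optional scalar binding offset absorbs any chemical-potential term.
    """

    kind = "custom"
    name = "gb1_three_state"

    def __init__(self, L: int, alphabet, beta: float = BETA_300K):
        self.beta = float(beta)
        n = 2 * (1 + L * len(get_alphabet(alphabet).characters))
        super().__init__(L, alphabet, n)

    def _split(self, params):
        LC = self.L * self.C
        off_f = params[0]
        mat_f = params[1 : 1 + LC].reshape(self.L, self.C)
        off_b = params[1 + LC]
        mat_b = params[2 + LC :].reshape(self.L, self.C)
        return off_f, mat_f, off_b, mat_b

    def energies(self, X, params=None):
        """Per-sequence (dG_F, dG_B) from the one-hot array X."""
        params = self._params if params is None else params
        off_f, mat_f, off_b, mat_b = self._split(params)
        dg_f = off_f + np.einsum("nlc,lc->n", X, mat_f)
        dg_b = off_b + np.einsum("nlc,lc->n", X, mat_b)
        return dg_f, dg_b

    def phi_from_onehot(self, X, params):
        dg_f, dg_b = self.energies(X, params)
        G = np.column_stack([np.zeros_like(dg_f), dg_f, dg_f + dg_b])
        return boltzmann_occupancy(G, readout=[2], beta=self.beta)

    def backprop(self, X, dphi):
        dg_f, dg_b = self.energies(X)
        G = np.column_stack([np.zeros_like(dg_f), dg_f, dg_f + dg_b])
        p = _state_probs(G, self.beta)
        phi = p[:, 2]
        # dphi/dG_state for readout {2}: -beta * p_t * (1[t==2] - phi)
        dG = -self.beta * p * (np.array([0.0, 0.0, 1.0])[None, :] - phi[:, None])
        d_dgf = dG[:, 1] + dG[:, 2]  # dG_F enters states 1 and 2
        d_dgb = dG[:, 2]
        wf = dphi * d_dgf
        wb = dphi * d_dgb
        g = np.concatenate(
            [
                [wf.sum()],
                np.einsum("n,nlc->lc", wf, X).ravel(),
                [wb.sum()],
                np.einsum("n,nlc->lc", wb, X).ravel(),
            ]
        )
        return g

    def energy_matrices(self) -> tuple[LinearGPMap, LinearGPMap]:
        """The folding and binding energy matrices as additive maps (for export)."""
        off_f, mat_f, off_b, mat_b = self._split(self._params)
        out = []
        for off, mat in ((off_f, mat_f), (off_b, mat_b)):
            m = LinearGPMap(self.L, self.alphabet, "additive")
            m.theta_0 = float(off)
            m.theta_lc = mat.copy()
            out.append(m)
        return tuple(out)

    def display_gauge(self) -> tuple[LinearGPMap, LinearGPMap]:
        """Energy matrices in the uniform hierarchical gauge, for logos/heatmaps."""
        p = np.full((self.L, self.C), 1.0 / self.C)
        return tuple(hierarchical_gauge(m, p) for m in self.energy_matrices())


class LacFourStateGPMap(CustomGPMap):
    """Four-state promoter-activation map: phi = RNAP-bound fraction.

    CRP and RNAP bind within footprints (position slices) of the assayed
    region; their binding energies come from energy matrices over those
    footprints, and a scalar interaction energy dG_I couples co-occupancy.
    """

    kind = "custom"
    name = "lac_four_state"

    def __init__(
        self,
        L: int,
        alphabet,
        crp_footprint: tuple[int, int],
        rnap_footprint: tuple[int, int],
        beta: float = BETA_300K,
    ):
        for name, (a, b) in (("crp", crp_footprint), ("rnap", rnap_footprint)):
            if not (0 <= a < b <= L):
                raise ValueError(f"{name} footprint {a, b} falls outside sequence of length {L}")
        self.beta = float(beta)
        self.crp_footprint = tuple(crp_footprint)
        self.rnap_footprint = tuple(rnap_footprint)
        C = len(get_alphabet(alphabet).characters)
        lc_c = (crp_footprint[1] - crp_footprint[0]) * C
        lc_r = (rnap_footprint[1] - rnap_footprint[0]) * C
        n = (1 + lc_c) + (1 + lc_r) + 1  # offsets + matrices + dG_I
        super().__init__(L, alphabet, n)
        self._lc_c, self._lc_r = lc_c, lc_r

    def _split(self, params):
        lc_c, lc_r = self._lc_c, self._lc_r
        wc = self.crp_footprint[1] - self.crp_footprint[0]
        wr = self.rnap_footprint[1] - self.rnap_footprint[0]
        off_c = params[0]
        mat_c = params[1 : 1 + lc_c].reshape(wc, self.C)
        off_r = params[1 + lc_c]
        mat_r = params[2 + lc_c : 2 + lc_c + lc_r].reshape(wr, self.C)
        dg_i = params[-1]
        return off_c, mat_c, off_r, mat_r, dg_i

    @property
    def dG_I(self) -> float:
        return float(self._params[-1])

    def energies(self, X, params=None):
        params = self._params if params is None else params
        off_c, mat_c, off_r, mat_r, dg_i = self._split(params)
        a, b = self.crp_footprint
        dg_c = off_c + np.einsum("nlc,lc->n", X[:, a:b], mat_c)
        a, b = self.rnap_footprint
        dg_r = off_r + np.einsum("nlc,lc->n", X[:, a:b], mat_r)
        return dg_c, dg_r, dg_i

    def phi_from_onehot(self, X, params):
        dg_c, dg_r, dg_i = self.energies(X, params)
        zero = np.zeros_like(dg_c)
        G = np.column_stack([zero, dg_c, dg_r, dg_c + dg_r + dg_i])
        return boltzmann_occupancy(G, readout=[2, 3], beta=self.beta)

    def backprop(self, X, dphi):
        dg_c, dg_r, dg_i = self.energies(X)
        zero = np.zeros_like(dg_c)
        G = np.column_stack([zero, dg_c, dg_r, dg_c + dg_r + dg_i])
        p = _state_probs(G, self.beta)
        phi = p[:, 2] + p[:, 3]
        readout = np.array([0.0, 0.0, 1.0, 1.0])
        dG = -self.beta * p * (readout[None, :] - phi[:, None])
        d_c = dG[:, 1] + dG[:, 3]  # dG_C enters CRP-only and co-occupied states
        d_r = dG[:, 2] + dG[:, 3]
        d_i = dG[:, 3]
        wc = dphi * d_c
        wr = dphi * d_r
        a, b = self.crp_footprint
        g_mat_c = np.einsum("n,nlc->lc", wc, X[:, a:b]).ravel()
        a, b = self.rnap_footprint
        g_mat_r = np.einsum("n,nlc->lc", wr, X[:, a:b]).ravel()
        return np.concatenate(
            [[wc.sum()], g_mat_c, [wr.sum()], g_mat_r, [(dphi * d_i).sum()]]
        )
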