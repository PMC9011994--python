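"""Gauge fixing for latent-phenotype models.

Two kinds of non-identifiable degrees of freedom are removed after training:

* **Diffeomorphic modes** — affine changes of phi that a compensating change
  of the measurement process undoes. These are fixed by centering and scaling
  phi to mean 0 / std 1 on the training data while transforming the
  measurement process so that p(y | x) is unchanged for every sequence.

* **Gauge modes** — parameter directions that leave phi itself unchanged.
  For the parametric maps these are fixed in the *hierarchical gauge*: given
  a position-factorized sequence distribution p[l, c], parameters are shifted
  so the lower-order terms absorb the largest possible share of the variance
  of phi. Afterward the additive terms average to zero at each position under
  p, and every interaction block has zero marginals under p.

Built-in sequence distributions: uniform, empirical (per-position character
frequencies of a dataset), and wildtype (a one-hot distribution; additive
parameters then vanish on the wildtype characters and theta_0 = phi(WT)).
"""

from __future__ import annotations

import numpy as np

from .data import one_hot_matrix
from .gpmaps import LinearGPMap

__all__ = [
    "position_probability_matrix",
    "fix_diffeomorphic",
    "hierarchical_gauge",
]


def position_probability_matrix(
    source: str,
    L: int,
    alphabet,
    sequences=None,
    wildtype: str | None = None,
) -> np.ndarray:
    """Build the (L, C) probability matrix p[l, c] for gauge fixing.

    source = 'uniform' | 'empirical' (needs ``sequences``) | 'wildtype'
    (needs ``wildtype``). Rows sum to 1.
    """
    from .alphabets import get_alphabet

    alphabet = get_alphabet(alphabet)
    C = len(alphabet)
    if source == "uniform":
        return np.full((L, C), 1.0 / C)
    if source == "empirical":
        if sequences is None:
            raise ValueError("empirical distribution needs sequences")
        return one_hot_matrix(sequences, alphabet).mean(axis=0)
    if source == "wildtype":
        if wildtype is None:
            raise ValueError("wildtype distribution needs a wildtype sequence")
        return one_hot_matrix([wildtype], alphabet)[0]
    raise ValueError(f"unknown sequence-distribution source {source!r}")


def fix_diffeomorphic(model, training_phi: np.ndarray):
    """Standardize phi on training data, compensating in the measurement process.

    Transforms the model in place so that post-fix training phi has mean 0 and
    std 1 while p(y | x) is unchanged for every sequence. Returns ``(a, b)``,
    the removed center and scale. Rejects degenerate maps with constant phi.
    """
    phi = np.asarray(training_phi, float)
    a = float(np.mean(phi))
    b = float(np.std(phi))
    if not np.isfinite(b) or b <= 0:
        raise ValueError("phi has zero variance on training data; degenerate G-P map")
    gpmap = model.gpmap
    if isinstance(gpmap, LinearGPMap):
        gpmap.theta_0 = (gpmap.theta_0 - a) / b
        gpmap.theta_lc = gpmap.theta_lc / b
        gpmap.theta_pair = gpmap.theta_pair / b
    elif gpmap.kind == "blackbox":
        gpmap.weights[-1] = gpmap.weights[-1] / b
        gpmap.biases[-1] = (gpmap.biases[-1] - a) / b
    else:
        raise ValueError(
            "diffeomorphic fixing of custom G-P maps is the user's responsibility"
        )
    model.measurement.shift_scale_phi(a, b)
    return a, b


def hierarchical_gauge(gpmap: LinearGPMap, p: np.ndarray) -> LinearGPMap:
    """Return a gauge-fixed copy of a parametric G-P map (phi unchanged).

    ``p`` is an (L, C) position-factorized sequence distribution. The returned
    parameters satisfy, for every position l and pair (l, l'):

        sum_c p[l, c] * theta[l, c] == 0
        sum_c p[l, c] * theta[l, c, l', c'] == 0   for each c'
        sum_c' p[l', c'] * theta[l, c, l', c'] == 0  for each c

    The transformation is idempotent and leaves phi(x) identical for all x.
    Positions with undefined (NaN) parameters at characters of positive
    probability are rejected.
    """
    if not isinstance(gpmap, LinearGPMap):
        raise TypeError("hierarchical gauge applies to additive/neighbor/pairwise maps")
    p = np.asarray(p, float)
    if p.shape != (gpmap.L, gpmap.C):
        raise ValueError("probability matrix shape must be (L, C)")
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0):
        raise ValueError("probability matrix rows must be nonnegative and sum to 1")
    bad = (~np.isfinite(gpmap.theta_lc)) & (p > 0)
    if bad.any():
        l, c = np.argwhere(bad)[0]
        raise ValueError(
            f"theta[{l}, {gpmap.alphabet.characters[c]!r}] is undefined (NaN) but has "
            "positive probability under the gauge distribution; use a distribution "
            "supported on observed characters (e.g. empirical or wildtype)"
        )

    out = gpmap.copy()
    theta0 = gpmap.theta_0
    nan_mask = ~np.isfinite(gpmap.theta_lc)  # only where p == 0, checked above
    th = np.where(nan_mask, 0.0, gpmap.theta_lc)  # (L, C)
    new_th = th - (th * p).sum(axis=1, keepdims=True)
    new_theta0 = theta0 + float((th * p).sum())

    new_pair = out.theta_pair
    for idx, (l, lp) in enumerate(gpmap.pairs):
        T = gpmap.theta_pair[idx]  # (C, C), rows = c at l, cols = c' at lp
        pl, plp = p[l], p[lp]
        row_mean = pl @ T  # (C,) over c'
        col_mean = T @ plp  # (C,) over c
        total = float(pl @ T @ plp)
        new_theta0 += total
        new_th[l] += col_mean - total
        new_th[lp] += row_mean - total
        new_pair[idx] = T - row_mean[None, :] - col_mean[:, None] + total

    out.theta_0 = new_theta0
    out.theta_lc = np.where(nan_mask, np.nan, new_th)
    out.theta_pair = new_pair
    return out
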