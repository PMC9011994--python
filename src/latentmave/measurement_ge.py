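"""Global-epistasis measurement process.

A GE measurement process maps the latent phenotype phi through a monotonic
nonlinearity ``g(phi; alpha)`` (a sum of tanh sigmoids) to the prediction
``y_hat`` — the mode of ``p(y | phi)`` — and describes scatter about the
prediction with a parametric noise model. Noise scale (and, for the skewed-t,
shape) parameters are exponentiated polynomials in ``y_hat``, so all noise
models can be heteroscedastic; polynomial order 0 makes them homoscedastic.

The skewed-t family is the Jones-Faddy distribution: it has Gaussian-like and
Cauchy-like limits but accommodates asymmetric experimental noise, with its
mode pinned at ``y_hat``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betainc, betaincinv, gammaln, erf, erfinv

__all__ = [
    "GENonlinearity",
    "LinearNonlinearity",
    "GaussianNoise",
    "CauchyNoise",
    "SkewTNoise",
    "EmpiricalNoise",
    "GEMeasurement",
    "make_noise_model",
]

_EXP_CLIP = 50.0  # bound on poly exponents; keeps exp() finite (documented)


def softplus(x):
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    y = np.asarray(y, float)
    if np.any(y <= 0):
        raise ValueError("softplus inverse requires positive input")
    # log(e^y - 1), stable for large y
    return y + np.log1p(-np.exp(-np.minimum(y, _EXP_CLIP)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_EXP_CLIP, _EXP_CLIP)))


class GENonlinearity:
    """Sum-of-sigmoids nonlinearity ``g(phi) = a + sum_k b_k tanh(c_k phi + d_k)``.

    With ``monotonic=True`` (default) the constraint ``b_k >= 0, c_k >= 0`` is
    enforced by storing unconstrained surrogates mapped through a softplus;
    g is then non-decreasing in phi.
    """

    def __init__(self, K: int = 20, monotonic: bool = True, seed: int = 0):
        if K < 1:
            raise ValueError("need K >= 1 hidden nodes")
        self.K = int(K)
        self.monotonic = bool(monotonic)
        rng = np.random.default_rng(seed)
        self.a = 0.0
        self._rb = np.full(K, softplus_inv(0.1)) + 0.01 * rng.normal(size=K)
        self._rc = np.full(K, softplus_inv(0.5)) + 0.01 * rng.normal(size=K)
        self.d = np.linspace(-1.0, 1.0, K)

    # constrained views ------------------------------------------------------
    @property
    def b(self) -> np.ndarray:
        return softplus(self._rb) if self.monotonic else self._rb.copy()

    @b.setter
    def b(self, val):
        val = np.asarray(val, float)
        self._rb = softplus_inv(val) if self.monotonic else val.copy()

    @property
    def c(self) -> np.ndarray:
        return softplus(self._rc) if self.monotonic else self._rc.copy()

    @c.setter
    def c(self, val):
        val = np.asarray(val, float)
        self._rc = softplus_inv(val) if self.monotonic else val.copy()

    # flat parameters ----------------------------------------------------------
    @property
    def n_params(self) -> int:
        return 1 + 3 * self.K

    def get_params(self) -> np.ndarray:
        return np.concatenate([[self.a], self._rb, self._rc, self.d])

    def set_params(self, vec: np.ndarray) -> None:
        vec = np.asarray(vec, float)
        K = self.K
        self.a = float(vec[0])
        self._rb = vec[1 : 1 + K].copy()
        self._rc = vec[1 + K : 1 + 2 * K].copy()
        self.d = vec[1 + 2 * K :].copy()

    # evaluation ----------------------------------------------------------------
    def g(self, phi) -> np.ndarray:
        phi = np.asarray(phi, float)
        t = np.tanh(np.multiply.outer(phi, self.c) + self.d)
        return self.a + t @ self.b

    __call__ = g

    def g_prime(self, phi) -> np.ndarray:
        phi = np.asarray(phi, float)
        t = np.tanh(np.multiply.outer(phi, self.c) + self.d)
        return (1.0 - t**2) @ (self.b * self.c)

    def backprop(self, phi: np.ndarray, dyhat: np.ndarray):
        """Given dL/dyhat, return (dL/dphi, dL/d params)."""
        b, c = self.b, self.c
        z = np.multiply.outer(phi, c) + self.d
        t = np.tanh(z)
        sech2 = 1.0 - t**2
        dphi = dyhat * (sech2 @ (b * c))
        g_a = dyhat.sum()
        g_b = dyhat @ t  # (K,)
        g_c = ((dyhat[:, None] * sech2 * phi[:, None]) * b).sum(axis=0)
        g_d = ((dyhat[:, None] * sech2) * b).sum(axis=0)
        if self.monotonic:
            g_b = g_b * _sigmoid(self._rb)
            g_c = g_c * _sigmoid(self._rc)
        return dphi, np.concatenate([[g_a], g_b, g_c, g_d])

    def shift_scale_phi(self, a0: float, b0: float) -> None:
        """Reparameterize so new g(phi) equals old g(a0 + b0*phi)."""
        c_old = self.c
        self.d = self.d + c_old * a0
        self.c = c_old * b0

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "monotonic": self.monotonic,
            "a": self.a,
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "d": self.d.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GENonlinearity":
        out = cls(K=d["K"], monotonic=d["monotonic"])
        out.a = float(d["a"])
        out.b = np.asarray(d["b"], float)
        out.c = np.asarray(d["c"], float)
        out.d = np.asarray(d["d"], float)
        return out


class LinearNonlinearity:
    """Identity-affine 'nonlinearity' ``g(phi) = a + m * phi``.

    Used when a dataset contains only single-mutation variants: the shape of a
    genuine nonlinearity is then unidentifiable, so g is constrained to be
    affine and only the noise model absorbs measurement structure.
    """

    def __init__(self):
        self.a = 0.0
        self.m = 1.0

    n_params = 2

    def get_params(self) -> np.ndarray:
        return np.array([self.a, self.m])

    def set_params(self, vec) -> None:
        self.a, self.m = float(vec[0]), float(vec[1])

    def g(self, phi) -> np.ndarray:
        return self.a + self.m * np.asarray(phi, float)

    __call__ = g

    def g_prime(self, phi) -> np.ndarray:
        return np.full(np.shape(phi), self.m)

    def backprop(self, phi, dyhat):
        dphi = dyhat * self.m
        return dphi, np.array([dyhat.sum(), dyhat @ phi])

    def shift_scale_phi(self, a0: float, b0: float) -> None:
        self.a = self.a + self.m * a0
        self.m = self.m * b0

    def to_dict(self) -> dict:
        return {"linear": True, "a": self.a, "m": self.m}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearNonlinearity":
        out = cls()
        out.a, out.m = float(d["a"]), float(d["m"])
        return out


# -- polynomial helpers ------------------------------------------------------


def _poly(coeffs: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    # coeffs[k] multiplies yhat**k
    return np.polynomial.polynomial.polyval(yhat, coeffs)


def _poly_deriv(coeffs: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    if len(coeffs) == 1:
        return np.zeros_like(yhat)
    dcoef = coeffs[1:] * np.arange(1, len(coeffs))
    return np.polynomial.polynomial.polyval(yhat, dcoef)


def _exp_poly(coeffs, yhat):
    return np.exp(np.clip(_poly(coeffs, yhat), -_EXP_CLIP, _EXP_CLIP))


class NoiseModel:
    """Base class: p(y | y_hat) families with quantiles, sampling, gradients."""

    family: str
    n_params: int = 0

    def get_params(self) -> np.ndarray:
        return np.zeros(0)

    def set_params(self, vec) -> None:
        pass

    def logpdf(self, y, yhat, se=None) -> np.ndarray:
        raise NotImplementedError

    def backprop(self, y, yhat, se=None):
        """Return (d sum-logpdf/d yhat per datum, d sum-logpdf/d params)."""
        raise NotImplementedError

    def quantile(self, q, yhat, se=None) -> np.ndarray:
        raise NotImplementedError

    def sample(self, yhat, rng, se=None) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


class GaussianNoise(NoiseModel):
    """Gaussian noise with scale ``s(y_hat) = exp(poly(y_hat))``."""

    family = "gaussian"

    def __init__(self, poly_order: int = 2):
        if poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        self.s_coeffs = np.zeros(poly_order + 1)

    @property
    def n_params(self) -> int:
        return self.s_coeffs.size

    def get_params(self) -> np.ndarray:
        return self.s_coeffs.copy()

    def set_params(self, vec) -> None:
        self.s_coeffs = np.asarray(vec, float).copy()

    def scale(self, yhat) -> np.ndarray:
        return _exp_poly(self.s_coeffs, np.asarray(yhat, float))

    def logpdf(self, y, yhat, se=None) -> np.ndarray:
        s = self.scale(yhat)
        z = (y - yhat) / s
        return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * z**2

    def backprop(self, y, yhat, se=None):
        s = self.scale(yhat)
        z = (y - yhat) / s
        dl_dyhat_direct = z / s
        dl_dlogs = z**2 - 1.0
        dlogs_dyhat = _poly_deriv(self.s_coeffs, yhat)
        dyhat = dl_dyhat_direct + dl_dlogs * dlogs_dyhat
        powers = np.vander(yhat, self.s_coeffs.size, increasing=True)
        gcoef = powers.T @ dl_dlogs
        return dyhat, gcoef

    def quantile(self, q, yhat, se=None) -> np.ndarray:
        q = np.asarray(q, float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile level must be in (0, 1)")
        return yhat + self.scale(yhat) * np.sqrt(2.0) * erfinv(2 * q - 1)

    def cdf(self, y, yhat) -> np.ndarray:
        s = self.scale(yhat)
        return 0.5 * (1 + erf((y - yhat) / (s * np.sqrt(2.0))))

    def sample(self, yhat, rng, se=None) -> np.ndarray:
        return yhat + self.scale(yhat) * rng.standard_normal(np.shape(yhat))

    def to_dict(self) -> dict:
        return {"family": self.family, "s_coeffs": self.s_coeffs.tolist()}


class CauchyNoise(NoiseModel):
    """Cauchy noise with scale ``s(y_hat) = exp(poly(y_hat))``; heavy-tailed."""

    family = "cauchy"

    def __init__(self, poly_order: int = 2):
        self.s_coeffs = np.zeros(poly_order + 1)

    n_params = property(lambda self: self.s_coeffs.size)

    def get_params(self):
        return self.s_coeffs.copy()

    def set_params(self, vec):
        self.s_coeffs = np.asarray(vec, float).copy()

    def scale(self, yhat):
        return _exp_poly(self.s_coeffs, np.asarray(yhat, float))

    def logpdf(self, y, yhat, se=None):
        s = self.scale(yhat)
        z = (y - yhat) / s
        return -np.log(np.pi) - np.log(s) - np.log1p(z**2)

    def backprop(self, y, yhat, se=None):
        s = self.scale(yhat)
        z = (y - yhat) / s
        dl_dyhat_direct = 2 * z / (s * (1 + z**2))
        dl_dlogs = 2 * z**2 / (1 + z**2) - 1.0
        dyhat = dl_dyhat_direct + dl_dlogs * _poly_deriv(self.s_coeffs, yhat)
        powers = np.vander(yhat, self.s_coeffs.size, increasing=True)
        return dyhat, powers.T @ dl_dlogs

    def quantile(self, q, yhat, se=None):
        q = np.asarray(q, float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile level must be in (0, 1)")
        return yhat + self.scale(yhat) * np.tan(np.pi * (q - 0.5))

    def cdf(self, y, yhat):
        s = self.scale(yhat)
        return 0.5 + np.arctan((y - yhat) / s) / np.pi

    def sample(self, yhat, rng, se=None):
        u = rng.uniform(size=np.shape(yhat))
        return self.quantile(np.clip(u, 1e-12, 1 - 1e-12), yhat)

    def to_dict(self):
        return {"family": self.family, "s_coeffs": self.s_coeffs.tolist()}


def _jf_logpdf(y, yhat, s, a, b):
    """Jones-Faddy skewed-t log density of y with mode at yhat."""
    tstar = (a - b) * np.sqrt(a + b) / (np.sqrt(2 * a + 1) * np.sqrt(2 * b + 1))
    t = tstar + (y - yhat) / s
    w = np.sqrt(a + b + t**2)
    u = t / w
    logf = (
        (1 - a - b) * np.log(2.0)
        - 0.5 * np.log(a + b)
        + gammaln(a + b)
        - gammaln(a)
        - gammaln(b)
        + (a + 0.5) * np.log1p(u)
        + (b + 0.5) * np.log1p(-u)
    )
    return logf - np.log(s)


class SkewTNoise(NoiseModel):
    """Jones-Faddy skewed-t noise; ``s``, ``a``, ``b`` are exponentiated
    polynomials in ``y_hat`` (so a, b > 0 automatically). ``a = b`` gives a
    symmetric density; ``a = b -> inf`` approaches a Gaussian."""

    family = "skewt"

    def __init__(self, poly_order: int = 2):
        k = poly_order + 1
        self.s_coeffs = np.zeros(k)
        self.a_coeffs = np.zeros(k)
        self.b_coeffs = np.zeros(k)
        self.a_coeffs[0] = np.log(4.0)  # start symmetric, moderately heavy tails
        self.b_coeffs[0] = np.log(4.0)

    n_params = property(
        lambda self: self.s_coeffs.size + self.a_coeffs.size + self.b_coeffs.size
    )

    def get_params(self):
        return np.concatenate([self.s_coeffs, self.a_coeffs, self.b_coeffs])

    def set_params(self, vec):
        vec = np.asarray(vec, float)
        k = self.s_coeffs.size
        self.s_coeffs = vec[:k].copy()
        self.a_coeffs = vec[k : 2 * k].copy()
        self.b_coeffs = vec[2 * k :].copy()

    def _sab(self, yhat):
        yhat = np.asarray(yhat, float)
        return (
            _exp_poly(self.s_coeffs, yhat),
            _exp_poly(self.a_coeffs, yhat),
            _exp_poly(self.b_coeffs, yhat),
        )

    def logpdf(self, y, yhat, se=None):
        s, a, b = self._sab(yhat)
        return _jf_logpdf(y, yhat, s, a, b)

    def backprop(self, y, yhat, se=None):
        s, a, b = self._sab(yhat)
        tstar = (a - b) * np.sqrt(a + b) / (np.sqrt(2 * a + 1) * np.sqrt(2 * b + 1))
        t = tstar + (y - yhat) / s
        w = np.sqrt(a + b + t**2)
        u = t / w
        dl_dt = ((a + 0.5) / (1 + u) - (b + 0.5) / (1 - u)) * (a + b) / w**3
        dl_dyhat_direct = dl_dt * (-1.0 / s)
        dl_dlogs = dl_dt * (-(y - yhat) / s) - 1.0
        # shape-parameter sensitivities by central differences in log space;
        # exact elsewhere, this keeps the code simple and is accurate to ~1e-9
        h = 1e-5
        dl_dloga = (
            _jf_logpdf(y, yhat, s, a * np.exp(h), b)
            - _jf_logpdf(y, yhat, s, a * np.exp(-h), b)
        ) / (2 * h)
        dl_dlogb = (
            _jf_logpdf(y, yhat, s, a, b * np.exp(h))
            - _jf_logpdf(y, yhat, s, a, b * np.exp(-h))
        ) / (2 * h)
        dyhat = (
            dl_dyhat_direct
            + dl_dlogs * _poly_deriv(self.s_coeffs, yhat)
            + dl_dloga * _poly_deriv(self.a_coeffs, yhat)
            + dl_dlogb * _poly_deriv(self.b_coeffs, yhat)
        )
        powers = np.vander(yhat, self.s_coeffs.size, increasing=True)
        gcoef = np.concatenate(
            [powers.T @ dl_dlogs, powers.T @ dl_dloga, powers.T @ dl_dlogb]
        )
        return dyhat, gcoef

    def quantile(self, q, yhat, se=None):
        q = np.asarray(q, float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile level must be in (0, 1)")
        s, a, b = self._sab(yhat)
        tstar = (a - b) * np.sqrt(a + b) / (np.sqrt(2 * a + 1) * np.sqrt(2 * b + 1))
        xq = betaincinv(a, b, q)
        v = 2 * xq - 1
        tq = v * np.sqrt(a + b) / np.sqrt(np.maximum(1 - v**2, 1e-300))
        return yhat + (tq - tstar) * s

    def cdf(self, y, yhat):
        s, a, b = self._sab(yhat)
        tstar = (a - b) * np.sqrt(a + b) / (np.sqrt(2 * a + 1) * np.sqrt(2 * b + 1))
        t = tstar + (y - yhat) / s
        u = t / np.sqrt(a + b + t**2)
        return betainc(a, b, (1 + u) / 2)

    def sample(self, yhat, rng, se=None):
        u = rng.uniform(size=np.shape(yhat))
        return self.quantile(np.clip(u, 1e-12, 1 - 1e-12), yhat)

    def to_dict(self):
        return {
            "family": self.family,
            "s_coeffs": self.s_coeffs.tolist(),
            "a_coeffs": self.a_coeffs.tolist(),
            "b_coeffs": self.b_coeffs.tolist(),
        }


class EmpiricalNoise(NoiseModel):
    """Gaussian noise with user-supplied per-measurement standard errors.

    No free parameters; requires the dataset to carry ``se``.
    """

    family = "empirical"

    def _check(self, se):
        if se is None:
            raise ValueError("empirical noise model requires per-datum standard errors")
        return np.asarray(se, float)

    def logpdf(self, y, yhat, se=None):
        s = self._check(se)
        z = (y - yhat) / s
        return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * z**2

    def backprop(self, y, yhat, se=None):
        s = self._check(se)
        return (y - yhat) / s**2, np.zeros(0)

    def quantile(self, q, yhat, se=None):
        s = self._check(se)
        return yhat + s * np.sqrt(2.0) * erfinv(2 * np.asarray(q, float) - 1)

    def sample(self, yhat, rng, se=None):
        s = self._check(se)
        return yhat + s * rng.standard_normal(np.shape(yhat))

    def to_dict(self):
        return {"family": self.family}


def make_noise_model(family: str, poly_order: int = 2) -> NoiseModel:
    families = {
        "gaussian": GaussianNoise,
        "cauchy": CauchyNoise,
        "skewt": SkewTNoise,
    }
    if family == "empirical":
        return EmpiricalNoise()
    if family not in families:
        raise ValueError(f"unknown noise family {family!r}")
    return families[family](poly_order=poly_order)


class GEMeasurement:
    """Nonlinearity + noise model; the full GE measurement process p(y | phi)."""

    mode = "ge"

    def __init__(self, nonlinearity: GENonlinearity, noise: NoiseModel):
        self.nonlinearity = nonlinearity
        self.noise = noise

    @property
    def n_params(self) -> int:
        return self.nonlinearity.n_params + self.noise.n_params

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.nonlinearity.get_params(), self.noise.get_params()])

    def set_params(self, vec) -> None:
        k = self.nonlinearity.n_params
        self.nonlinearity.set_params(vec[:k])
        self.noise.set_params(vec[k:])

    def yhat(self, phi) -> np.ndarray:
        return self.nonlinearity.g(phi)

    def logpdf(self, y, phi, se=None) -> np.ndarray:
        return self.noise.logpdf(y, self.yhat(phi), se=se)

    def nll(self, y, phi, se=None) -> float:
        """Negative log likelihood in nats (sum over data)."""
        return float(-np.sum(self.logpdf(y, phi, se=se)))

    def nll_backprop(self, y, phi, se=None):
        """Return (nll, dnll/dphi, dnll/dparams)."""
        yhat = self.nonlinearity.g(phi)
        ll = self.noise.logpdf(y, yhat, se=se)
        dl_dyhat, g_noise = self.noise.backprop(y, yhat, se=se)
        dphi, g_nonlin = self.nonlinearity.backprop(phi, -dl_dyhat)
        return float(-np.sum(ll)), dphi, np.concatenate([g_nonlin, -g_noise])

    def prediction_interval(self, q_lo: float, q_hi: float, phi, se=None):
        """Noise-model quantile interval at y_hat = g(phi)."""
        if not q_lo < q_hi:
            raise ValueError("require q_lo < q_hi")
        yhat = self.yhat(phi)
        return self.noise.quantile(q_lo, yhat, se=se), self.noise.quantile(
            q_hi, yhat, se=se
        )

    def sample(self, phi, rng, se=None) -> np.ndarray:
        return self.noise.sample(self.yhat(phi), rng, se=se)

    def shift_scale_phi(self, a0: float, b0: float) -> None:
        self.nonlinearity.shift_scale_phi(a0, b0)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "nonlinearity": self.nonlinearity.to_dict(),
            "noise": self.noise.to_dict(),
        }
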