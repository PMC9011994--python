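"""Joint likelihood-based fitting of G-P maps and measurement processes.

The loss is the negative log likelihood plus an L2 penalty,

    L = L_like + lambda_theta * ||theta||^2 + lambda_eta * ||eta||^2,

minimized by minibatch Adam with early stopping on a validation split.
Gradients are computed analytically by backpropagation through the G-P map,
the GE nonlinearity and noise model (or the MPA softmax). Training is
deterministic given the seed. After optimization the returned model is
diffeomorphically fixed (training phi standardized to mean 0 / std 1, with a
compensating change of the measurement process) and, for the parametric maps,
hierarchically gauge-fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SequenceDataset
from .gauge import fix_diffeomorphic, hierarchical_gauge, position_probability_matrix
from .gpmaps import GPMap, LinearGPMap, make_gpmap
from .measurement_ge import (
    GEMeasurement,
    GENonlinearity,
    LinearNonlinearity,
    make_noise_model,
)
from .measurement_mpa import MPAMeasurement
from .model import LatentModel

__all__ = ["LossConfig", "SplitSpec", "split_dataset", "fit", "check_library_constraints"]

_LOGP_FLOOR = -700.0  # clip for zero-probability data (large finite penalty)


@dataclass
class LossConfig:
    """Optimizer and regularization settings.

    ``lambda_theta`` and ``lambda_eta`` are the L2 weights on G-P map and
    measurement-process parameters. All measurement parameters (including
    bias-like ones) are penalized by ``lambda_eta``.
    """

    lambda_theta: float = 1e-3
    lambda_eta: float = 1e-1
    learning_rate: float = 1e-3
    epochs: int = 600
    batch_size: int = 100
    patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.lambda_theta < 0 or self.lambda_eta < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class SplitSpec:
    """Random train/validation/test fractions (must sum to 1)."""

    train: float = 0.90
    val: float = 0.05
    test: float = 0.05
    seed: int = 0

    def __post_init__(self):
        fr = (self.train, self.val, self.test)
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


def split_dataset(dataset: SequenceDataset, spec: SplitSpec):
    """Shuffle rows and split into (train, val, test) datasets."""
    rng = np.random.default_rng(spec.seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_tr = int(round(spec.train * n))
    n_va = int(round(spec.val * n))
    if min(n_tr, n_va, n - n_tr - n_va) < 1:
        raise ValueError("dataset too small for the requested split")
    return (
        dataset.subset(order[:n_tr]),
        dataset.subset(order[n_tr : n_tr + n_va]),
        dataset.subset(order[n_tr + n_va :]),
    )


# -- dataset-constraint enforcement ------------------------------------------


def _mutation_counts(sequences, reference: str) -> np.ndarray:
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    out = np.empty(len(sequences), dtype=np.int64)
    for i, s in enumerate(sequences):
        out[i] = int((np.frombuffer(s.encode(), dtype=np.uint8) != ref).sum())
    return out


def _mode_first(sequences) -> str:
    """Most frequent sequence (ties broken by first appearance)."""
    best, best_n, seen = None, 0, {}
    for s in sequences:
        seen[s] = seen.get(s, 0) + 1
        if seen[s] > best_n:
            best, best_n = s, seen[s]
    return best


def check_library_constraints(
    dataset: SequenceDataset,
    gpmap_kind: str,
    process: str,
    linear_nonlinearity: bool,
    reference: str | None = None,
) -> bool:
    """Enforce the single-mutant restriction.

    When every non-reference sequence differs from the reference by at most
    one position, experimental nonlinearities cannot be deconvolved from the
    G-P map; only an additive map with an affine nonlinearity under GE
    regression is then permitted (heteroscedastic noise is still allowed).
    Returns True if the library is single-mutant-only.
    """
    ref = reference if reference is not None else _mode_first(dataset.sequences)
    nmut = _mutation_counts(dataset.sequences, ref)
    single_only = bool(nmut.max() <= 1)
    if single_only:
        if process != "ge" or gpmap_kind != "additive" or not linear_nonlinearity:
            raise ValueError(
                "dataset contains only single-mutation variants relative to "
                f"reference {ref!r}; experimental nonlinearities are not "
                "identifiable from such data, so only an additive G-P map with "
                "a linear nonlinearity under GE regression is permitted "
                "(pass linear_nonlinearity=True, gpmap='additive')"
            )
    return single_only


# -- Adam --------------------------------------------------------------------


class _Adam:
    def __init__(self, n, lr):
        self.lr = lr
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, w, g):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.m = b1 * self.m + (1 - b1) * g
        self.v = b2 * self.v + (1 - b2) * g * g
        mhat = self.m / (1 - b1**self.t)
        vhat = self.v / (1 - b2**self.t)
        return w - self.lr * mhat / (np.sqrt(vhat) + eps)


# -- initialization helpers --------------------------------------------------


def _ridge_init(X, target, lam=1e-3):
    XtX = X.T @ X + lam * np.eye(X.shape[1])
    return np.linalg.solve(XtX, X.T @ target)


def _init_ge(gpmap, measurement, X, y):
    if isinstance(gpmap, LinearGPMap):
        gpmap.set_params(_ridge_init(X, y))
    phi0 = gpmap.phi_from_design(X)
    mu, sd = float(np.mean(phi0)), float(np.std(phi0))
    sd = sd if sd > 0 else 1.0
    slope = float(np.cov(phi0, y)[0, 1] / sd**2) if sd > 0 else 1.0
    nonlin = measurement.nonlinearity
    if isinstance(nonlin, LinearNonlinearity):
        nonlin.a = float(np.mean(y)) - slope * mu
        nonlin.m = slope
    else:
        K = nonlin.K
        c0 = 1.0 / (2.0 * sd)
        centers = mu + np.linspace(-2, 2, K) * sd
        nonlin.c = np.full(K, c0)
        nonlin.d = -c0 * centers
        nonlin.b = np.full(K, max(abs(slope), 1e-3) * 2 * sd / K * np.sign(slope or 1.0))
        if np.any(nonlin.b <= 0):  # monotonic surrogate needs positive b
            nonlin.b = np.full(K, 1e-3)
        nonlin.a = float(np.mean(y))
    resid = y - nonlin.g(phi0)
    s0 = max(float(np.std(resid)), 1e-3)
    noise = measurement.noise
    if hasattr(noise, "s_coeffs"):
        noise.s_coeffs[:] = 0.0
        noise.s_coeffs[0] = np.log(s0)


def _init_mpa(gpmap, X, counts):
    mean_bin = counts @ np.arange(counts.shape[1]) / counts.sum(axis=1)
    if isinstance(gpmap, LinearGPMap):
        gpmap.set_params(_ridge_init(X, mean_bin))


# -- fitting -----------------------------------------------------------------


@dataclass
class FitResult:
    model: LatentModel
    history: pd.DataFrame
    train: SequenceDataset
    val: SequenceDataset
    test: SequenceDataset
    diffeo: tuple[float, float] = (0.0, 1.0)


def fit(
    dataset: SequenceDataset,
    gpmap: str | GPMap = "additive",
    process: str | None = None,
    noise: str = "gaussian",
    k_nonlin: int = 20,
    poly_order: int = 2,
    mpa_hidden: int = 10,
    linear_nonlinearity: bool = False,
    monotonic: bool = True,
    config: LossConfig | None = None,
    split: SplitSpec | None = None,
    gauge: str = "uniform",
    wildtype: str | None = None,
    reference: str | None = None,
    enforce_constraints: bool = True,
) -> FitResult:
    """Jointly fit a G-P map and measurement process to a MAVE dataset.

    ``process`` defaults to 'ge' for continuous data and 'mpa' for binned
    data. The returned model is diffeomorphically standardized and (for
    additive/neighbor/pairwise maps) hierarchically gauge-fixed under the
    requested sequence distribution ('uniform', 'empirical', or 'wildtype').
    """
    config = config or LossConfig()
    split = split or SplitSpec(seed=config.seed)
    process = process or ("ge" if dataset.mode == "ge" else "mpa")
    if process == "ge" and dataset.y is None:
        raise ValueError("GE regression needs continuous measurements")
    if process == "mpa" and dataset.y is not None:
        raise ValueError("MPA regression needs binned or count measurements")
    if noise == "empirical" and dataset.se is None:
        raise ValueError("empirical noise model needs per-datum standard errors (dy)")

    gpmap_kind = gpmap if isinstance(gpmap, str) else gpmap.kind
    if enforce_constraints:
        single_only = check_library_constraints(
            dataset, gpmap_kind, process, linear_nonlinearity, reference
        )
    rng = np.random.default_rng(config.seed)

    train, val, test = split_dataset(dataset, split)

    # model components
    if isinstance(gpmap, str):
        gp = make_gpmap(gpmap, dataset.L, dataset.alphabet, **(
            {"seed": config.seed} if gpmap == "blackbox" else {}
        ))
    else:
        gp = gpmap
    if process == "ge":
        if linear_nonlinearity:
            nonlin = LinearNonlinearity()
        else:
            nonlin = GENonlinearity(K=k_nonlin, monotonic=monotonic, seed=config.seed)
        meas = GEMeasurement(nonlin, make_noise_model(noise, poly_order))
    else:
        if train.counts is None:
            seqs, counts = _as_counts(train)
            train = SequenceDataset(tuple(seqs), dataset.alphabet, counts=counts)
        meas = MPAMeasurement(Y=dataset.n_bins, K=mpa_hidden, seed=config.seed)

    model = LatentModel(gp, meas)

    # cached designs and targets
    X_tr = gp.design(train.sequences)
    X_va = gp.design(val.sequences)
    if process == "ge":
        _init_ge(gp, meas, X_tr, train.y)
        target_tr, target_va = train.y, val.y
        se_tr, se_va = train.se, val.se
    else:
        _init_mpa(gp, X_tr, train.counts)
        target_tr = train.counts
        target_va = _counts_for(val, meas.Y)
        se_tr = se_va = None

    n_gp = gp.n_params
    w = np.concatenate([gp.get_params(), meas.get_params()])
    lam = np.concatenate(
        [
            np.full(n_gp, config.lambda_theta),
            np.full(meas.n_params, config.lambda_eta),
        ]
    )

    def set_all(wvec):
        gp.set_params(wvec[:n_gp])
        meas.set_params(wvec[n_gp:])

    def batch_loss_grad(wvec, idx):
        set_all(wvec)
        Xb = X_tr[idx]
        phi = gp.phi_from_design(Xb)
        if process == "ge":
            nll, dphi, g_meas = meas.nll_backprop(
                target_tr[idx], phi, se=None if se_tr is None else se_tr[idx]
            )
        else:
            nll, dphi, g_meas = meas.nll_backprop(target_tr[idx], phi)
        g_gp = gp.backprop(Xb, dphi)
        grad = np.concatenate([g_gp, g_meas])
        # scale penalty to the batch so the expected gradient matches full-batch
        frac = len(idx) / X_tr.shape[0]
        loss = nll + frac * float(lam @ (wvec**2))
        grad = grad + 2 * frac * lam * wvec
        if not np.isfinite(loss):
            raise FloatingPointError(
                "loss became non-finite during training; try a smaller learning "
                "rate or check the dataset for pathological values"
            )
        return loss, grad

    def val_nll(wvec) -> float:
        set_all(wvec)
        phi = gp.phi_from_design(X_va)
        if process == "ge":
            lp = meas.logpdf(target_va, phi, se=se_va)
            return float(-np.clip(lp, _LOGP_FLOOR, None).sum())
        return meas.nll_counts(target_va, phi)

    n_train = X_tr.shape[0]
    n_obs_train = float(target_tr.sum()) if process == "mpa" else float(n_train)
    opt = _Adam(w.size, config.learning_rate)
    best_w, best_val, best_epoch = w.copy(), np.inf, -1
    hist_rows = []
    bs = min(config.batch_size, n_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, bs):
            idx = order[start : start + bs]
            loss, grad = batch_loss_grad(w, idx)
            epoch_loss += loss
            w = opt.step(w, grad)
        v = val_nll(w)
        hist_rows.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss,
                "train_loss_per_obs": epoch_loss / n_obs_train,
                "val_nll": v,
            }
        )
        if v < best_val - 1e-10:
            best_val, best_w, best_epoch = v, w.copy(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    set_all(best_w)

    # gauge fixing: diffeomorphic always (built-in maps), hierarchical for parametric
    phi_train = gp.phi_from_design(X_tr)
    diffeo = (0.0, 1.0)
    if gp.kind in ("additive", "neighbor", "pairwise", "blackbox"):
        diffeo = fix_diffeomorphic(model, phi_train)
    if isinstance(gp, LinearGPMap):
        _mask_unobserved(gp, X_tr)
        gauge_used = gauge
        if np.isnan(gp.theta_lc).any() and gauge == "uniform":
            gauge_used = "empirical"  # uniform gauge undefined with missing effects
        p = position_probability_matrix(
            gauge_used,
            gp.L,
            gp.alphabet,
            sequences=train.sequences,
            wildtype=wildtype,
        )
        fixed = hierarchical_gauge(gp, p)
        gp.theta_0 = fixed.theta_0
        gp.theta_lc = fixed.theta_lc
        gp.theta_pair = fixed.theta_pair
        model.meta["gauge"] = gauge_used
    model.meta.update(
        {
            "seed": config.seed,
            "process": process,
            "gpmap_kind": gp.kind,
            "diffeo_a": diffeo[0],
            "diffeo_b": diffeo[1],
            "best_epoch": best_epoch,
        }
    )
    history = pd.DataFrame(hist_rows)
    return FitResult(model, history, train, val, test, diffeo)


def _as_counts(ds: SequenceDataset):
    from .data import bins_to_counts

    if ds.counts is not None:
        return list(ds.sequences), ds.counts
    return bins_to_counts(ds.sequences, ds.bins, n_bins=ds.n_bins)


def _counts_for(ds: SequenceDataset, Y: int) -> np.ndarray:
    if ds.counts is not None:
        return ds.counts
    out = np.zeros((len(ds), Y), dtype=np.int64)
    out[np.arange(len(ds)), ds.bins] = 1
    return out


def _mask_unobserved(gp: LinearGPMap, X_tr: np.ndarray) -> None:
    """NaN-out additive effects for (position, character) pairs never seen in training."""
    na = gp.theta_lc.size
    observed = (X_tr[:, 1 : 1 + na] != 0).any(axis=0).reshape(gp.L, gp.C)
    gp.theta_lc = np.where(observed, gp.theta_lc, np.nan)
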