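"""Model-based dataset simulation and parametric-bootstrap uncertainties.

Any latent-phenotype model is also a MAVE simulator: sequences are drawn (or
supplied), phi is computed by the G-P map, and measurements are sampled from
the measurement process. The parametric bootstrap keeps the assayed sequences
fixed, treats only the measurements as stochastic, refits a fresh model to
each of R simulated datasets (same hyperparameters as the ground-truth fit by
default), gauge-fixes each refit, and reports per-parameter standard
deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SequenceDataset
from .gpmaps import LinearGPMap
from .model import LatentModel

__all__ = ["SimulationSpec", "simulate_dataset", "parametric_bootstrap", "BootstrapResult"]


@dataclass
class SimulationSpec:
    """Where simulated sequences come from and how many.

    Exactly one source: ``sequences`` (explicit list), ``random`` over the
    alphabet, ``mutagenize`` a wildtype at a per-position rate, or
    ``singles_and_doubles`` of a wildtype (all singles plus ``n_doubles``
    sampled doubles).
    """

    n: int = 1000
    seed: int = 0
    sequences: list[str] | None = None
    random_length: int | None = None
    wildtype: str | None = None
    mutation_rate: float | None = None
    n_doubles: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need n >= 1 sequences")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation rate must be in [0, 1]")


def draw_sequences(spec: SimulationSpec, alphabet) -> list[str]:
    """Realize the sequence source of a simulation spec."""
    from .alphabets import get_alphabet

    alphabet = get_alphabet(alphabet)
    chars = np.array(list(alphabet.characters))
    rng = np.random.default_rng(spec.seed)
    if spec.sequences is not None:
        return [s.upper() for s in spec.sequences]
    if spec.wildtype is not None and spec.n_doubles is not None:
        return _singles_and_doubles(spec.wildtype.upper(), alphabet, spec.n_doubles, rng)
    if spec.wildtype is not None:
        wt = spec.wildtype.upper()
        L = len(wt)
        rate = spec.mutation_rate if spec.mutation_rate is not None else 0.1
        out = []
        wt_arr = np.array(list(wt))
        for _ in range(spec.n):
            s = wt_arr.copy()
            mut = rng.uniform(size=L) < rate
            s[mut] = chars[rng.integers(len(chars), size=int(mut.sum()))]
            out.append("".join(s))
        return out
    if spec.random_length is not None:
        idx = rng.integers(len(chars), size=(spec.n, spec.random_length))
        return ["".join(chars[i]) for i in idx]
    raise ValueError("simulation spec names no sequence source")


def _singles_and_doubles(wt: str, alphabet, n_doubles: int, rng) -> list[str]:
    chars = alphabet.characters
    L = len(wt)
    C = len(chars)
    n_possible = L * (L - 1) // 2 * (C - 1) ** 2
    if n_doubles > n_possible:
        raise ValueError(
            f"requested {n_doubles} double mutants but only {n_possible} exist "
            f"for L={L}, C={C}"
        )
    singles = [
        wt[:l] + c + wt[l + 1 :]
        for l in range(L)
        for c in chars
        if c != wt[l]
    ]
    doubles = []
    seen = set()
    while len(doubles) < n_doubles:
        l1, l2 = sorted(rng.choice(L, size=2, replace=False))
        c1 = chars[rng.integers(len(chars))]
        c2 = chars[rng.integers(len(chars))]
        if c1 == wt[l1] or c2 == wt[l2]:
            continue
        s = wt[:l1] + c1 + wt[l1 + 1 : l2] + c2 + wt[l2 + 1 :]
        if s not in seen:
            seen.add(s)
            doubles.append(s)
    return [wt] + singles + doubles


def simulate_dataset(
    model: LatentModel,
    spec: SimulationSpec,
    reads_per_sequence: int = 1,
) -> SequenceDataset:
    """Simulate a MAVE dataset from a model (deterministic given spec.seed).

    GE mode: y is drawn from the noise model at y_hat = g(phi(x)). MPA mode:
    bins are drawn from p(y | phi); with ``reads_per_sequence > 1`` a count
    matrix is produced instead of per-read pairs.
    """
    alphabet = model.gpmap.alphabet
    seqs = draw_sequences(spec, alphabet)
    if any(len(s) != model.gpmap.L for s in seqs):
        raise ValueError("simulated sequences do not match the model's length L")
    rng = np.random.default_rng(spec.seed + 1)
    phi = model.phi(seqs)
    if model.mode == "ge":
        y = model.measurement.sample(phi, rng)
        return SequenceDataset(tuple(seqs), alphabet, y=y)
    if reads_per_sequence == 1:
        bins = model.measurement.sample(phi, rng)
        return SequenceDataset(tuple(seqs), alphabet, bins=bins)
    p = model.measurement.probabilities(phi)
    counts = rng.multinomial(reads_per_sequence, p)
    return SequenceDataset(tuple(seqs), alphabet, counts=counts)


@dataclass
class BootstrapResult:
    """Per-parameter standard errors from R simulate-and-refit cycles."""

    param_std: np.ndarray
    replicates: np.ndarray  # (R, n_params), gauge-fixed parameter vectors
    param_mean: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.param_mean is None:
            self.param_mean = self.replicates.mean(axis=0)


def parametric_bootstrap(
    model: LatentModel,
    sequences,
    R: int = 25,
    fit_kwargs: dict | None = None,
    seed: int = 0,
) -> BootstrapResult:
    """Parameter uncertainties via the parametric bootstrap.

    The trained model acts as ground truth: R datasets are simulated with the
    given sequences held fixed, a fresh model is fit to each (same
    hyperparameters by default), each refit is gauge-fixed the same way as
    the input model, and per-parameter standard deviations are returned.

    Black-box maps are rejected: individual parameter uncertainties are not
    meaningful for heavily overparameterized models. Custom maps are accepted
    but the caller is responsible for gauge-fixing them consistently.
    """
    from .training import LossConfig, SplitSpec, fit

    if model.gpmap.kind == "blackbox":
        raise ValueError(
            "parametric bootstrap of black-box G-P maps is not supported: "
            "individual parameter uncertainties are not meaningful for "
            "overparameterized models"
        )
    if model.gpmap.kind == "custom":
        import warnings

        warnings.warn(
            "bootstrapping a custom G-P map: gauge freedoms are not fixed "
            "automatically; ensure replicate fits share a gauge"
        )
    fit_kwargs = dict(fit_kwargs or {})
    if model.gpmap.kind == "custom" and "gpmap" not in fit_kwargs:
        raise ValueError(
            "bootstrapping a custom G-P map requires fit_kwargs['gpmap'] to "
            "supply a fresh map instance for the refits"
        )
    fit_kwargs.setdefault("gpmap", model.gpmap.kind)
    if model.mode == "ge":
        fit_kwargs.setdefault("noise", model.measurement.noise.family)
    gauge = model.meta.get("gauge", "uniform")
    fit_kwargs.setdefault("gauge", gauge)
    master = np.random.default_rng(seed)
    reps = []
    for r in range(R):
        rep_seed = int(master.integers(2**31 - 1))
        sim = simulate_dataset(
            model, SimulationSpec(n=len(sequences), sequences=list(sequences), seed=rep_seed)
        )
        kw = dict(fit_kwargs)
        kw["config"] = kw.get("config") or LossConfig(seed=rep_seed)
        kw.setdefault("split", SplitSpec(seed=rep_seed))
        kw["enforce_constraints"] = False
        result = fit(sim, **kw)
        reps.append(result.model.gpmap.get_params())
    reps = np.asarray(reps)
    return BootstrapResult(param_std=np.nanstd(reps, axis=0), replicates=reps)
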