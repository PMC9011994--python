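"""Latent-phenotype model container and serialized model bundle.

A :class:`LatentModel` pairs a G-P map with a measurement process and is the
object returned by training, consumed by evaluation, simulation, and the
parametric bootstrap. Bundles are single JSON files holding all parameters,
the alphabet, the gauge choice, and reproducibility metadata.
"""

from __future__ import annotations

import json

import numpy as np

from .alphabets import Alphabet, get_alphabet
from .data import SequenceDataset
from .gpmaps import BlackBoxGPMap, LinearGPMap
from .measurement_ge import (
    GEMeasurement,
    GENonlinearity,
    LinearNonlinearity,
    make_noise_model,
)
from .measurement_mpa import MPAMeasurement

__all__ = ["LatentModel", "save_model", "load_model"]


class LatentModel:
    """A G-P map plus a measurement process: the full model p(y | x)."""

    def __init__(self, gpmap, measurement, meta: dict | None = None):
        self.gpmap = gpmap
        self.measurement = measurement
        self.meta = dict(meta or {})

    @property
    def mode(self) -> str:
        return self.measurement.mode

    # -- evaluation ----------------------------------------------------------
    def phi(self, sequences) -> np.ndarray:
        return self.gpmap.phi(sequences)

    def yhat(self, sequences) -> np.ndarray:
        if self.mode != "ge":
            raise ValueError("yhat is defined for GE models only")
        return self.measurement.yhat(self.phi(sequences))

    def nll(self, dataset: SequenceDataset) -> float:
        """Negative log likelihood (nats) of a dataset under this model."""
        phi = self.phi(dataset.sequences)
        if self.mode == "ge":
            if dataset.y is None:
                raise ValueError("GE model requires a continuous-measurement dataset")
            return self.measurement.nll(dataset.y, phi, se=dataset.se)
        if dataset.counts is not None:
            return self.measurement.nll_counts(dataset.counts, phi)
        if dataset.bins is not None:
            logp = self.measurement.log_probabilities(phi)
            return float(-logp[np.arange(len(dataset)), dataset.bins].sum())
        raise ValueError("MPA model requires a binned or count dataset")

    def per_datum_log2p(self, dataset: SequenceDataset) -> np.ndarray:
        """log2 p(y_n | phi_n) per observation (reads for MPA pair data)."""
        phi = self.phi(dataset.sequences)
        if self.mode == "ge":
            return self.measurement.logpdf(dataset.y, phi, se=dataset.se) / np.log(2)
        logp = self.measurement.log_probabilities(phi)
        if dataset.bins is not None:
            return logp[np.arange(len(dataset)), dataset.bins] / np.log(2)
        raise ValueError("per-datum likelihoods need per-read (bin) data")


# -- serialization -----------------------------------------------------------


def _gpmap_to_dict(gpmap) -> dict:
    if isinstance(gpmap, LinearGPMap):
        return {
            "kind": gpmap.kind,
            "L": gpmap.L,
            "alphabet": list(gpmap.alphabet.characters),
            "alphabet_name": gpmap.alphabet.name,
            "theta_0": gpmap.theta_0,
            "theta_lc": np.where(
                np.isfinite(gpmap.theta_lc), gpmap.theta_lc, None
            ).tolist(),
            "theta_pair": gpmap.theta_pair.tolist(),
        }
    if isinstance(gpmap, BlackBoxGPMap):
        return {
            "kind": "blackbox",
            "L": gpmap.L,
            "alphabet": list(gpmap.alphabet.characters),
            "alphabet_name": gpmap.alphabet.name,
            "input_features": gpmap.input_features,
            "activation": gpmap.activation,
            "hidden_layer_sizes": [w.shape[1] for w in gpmap.weights[:-1]],
            "weights": [w.tolist() for w in gpmap.weights],
            "biases": [b.tolist() for b in gpmap.biases],
        }
    raise ValueError(
        f"custom G-P map {type(gpmap).__name__} has no generic serialization; "
        "save its parameter vector yourself"
    )


def _gpmap_from_dict(d: dict):
    alphabet = Alphabet(d.get("alphabet_name", "custom"), tuple(d["alphabet"]))
    if d["kind"] in ("additive", "neighbor", "pairwise"):
        out = LinearGPMap(d["L"], alphabet, d["kind"])
        out.theta_0 = float(d["theta_0"])
        th = np.array(
            [[np.nan if v is None else v for v in row] for row in d["theta_lc"]],
            dtype=float,
        )
        out.theta_lc = th
        out.theta_pair = np.asarray(d["theta_pair"], float).reshape(
            out.theta_pair.shape
        )
        return out
    if d["kind"] == "blackbox":
        out = BlackBoxGPMap(
            d["L"],
            alphabet,
            hidden_layer_sizes=tuple(d["hidden_layer_sizes"]),
            input_features=d["input_features"],
            activation=d["activation"],
        )
        out.weights = [np.asarray(w, float) for w in d["weights"]]
        out.biases = [np.asarray(b, float) for b in d["biases"]]
        return out
    raise ValueError(f"cannot deserialize G-P map kind {d['kind']!r}")


def _measurement_from_dict(d: dict):
    if d["mode"] == "ge":
        nl = d["nonlinearity"]
        if nl.get("linear", False):
            nonlin = LinearNonlinearity.from_dict(nl)
        else:
            nonlin = GENonlinearity.from_dict(nl)
        noise_d = d["noise"]
        noise = make_noise_model(
            noise_d["family"],
            poly_order=len(noise_d.get("s_coeffs", [1])) - 1,
        )
        if noise_d["family"] in ("gaussian", "cauchy"):
            noise.s_coeffs = np.asarray(noise_d["s_coeffs"], float)
        elif noise_d["family"] == "skewt":
            noise.s_coeffs = np.asarray(noise_d["s_coeffs"], float)
            noise.a_coeffs = np.asarray(noise_d["a_coeffs"], float)
            noise.b_coeffs = np.asarray(noise_d["b_coeffs"], float)
        return GEMeasurement(nonlin, noise)
    if d["mode"] == "mpa":
        return MPAMeasurement.from_dict(d)
    raise ValueError(f"cannot deserialize measurement mode {d['mode']!r}")


def save_model(model: LatentModel, path) -> None:
    """Write a model bundle as a single JSON file."""
    bundle = {
        "format": "latentmave-model-v1",
        "gpmap": _gpmap_to_dict(model.gpmap),
        "measurement": model.measurement.to_dict(),
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=1)


def load_model(path) -> LatentModel:
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("format") != "latentmave-model-v1":
        raise ValueError("not a latentmave model bundle")
    return LatentModel(
        _gpmap_from_dict(bundle["gpmap"]),
        _measurement_from_dict(bundle["measurement"]),
        meta=bundle.get("meta", {}),
    )


def export_parameters_tsv(gpmap: LinearGPMap, path) -> None:
    """Tidy TSV export (columns l, c, value; then l, c, l2, c2, value blocks)."""
    import pandas as pd

    rows = [
        {"l": l, "c": gpmap.alphabet.characters[c], "value": gpmap.theta_lc[l, c]}
        for l in range(gpmap.L)
        for c in range(gpmap.C)
    ]
    df = pd.DataFrame(rows)
    df.attrs["theta_0"] = gpmap.theta_0
    pair_rows = [
        {
            "l": l,
            "c": gpmap.alphabet.characters[c],
            "l2": lp,
            "c2": gpmap.alphabet.characters[cp],
            "value": gpmap.theta_pair[p, c, cp],
        }
        for p, (l, lp) in enumerate(gpmap.pairs)
        for c in range(gpmap.C)
        for cp in range(gpmap.C)
    ]
    out = pd.concat([df, pd.DataFrame(pair_rows)]) if pair_rows else df
    out.to_csv(path, sep="\t", index=False)
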