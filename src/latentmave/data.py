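"""Dataset containers, one-hot encoding, read-count scores, and TSV/CSV I/O.

The universal input is a table of fixed-length sequences paired with either a
continuous measurement ``y`` (global-epistasis regression), a bin label
(measurement-process-agnostic regression on reads), or a per-bin count vector
(the sort-seq layout). Raw read counts from enrichment or splicing assays are
converted to measurement scores with :func:`log2_enrichment` /
:func:`log10_psi` before modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabets import Alphabet, get_alphabet

__all__ = [
    "SequenceDataset",
    "one_hot_encode",
    "one_hot_matrix",
    "pairwise_features",
    "log2_enrichment",
    "log10_psi",
    "filter_by_min_count",
    "bins_to_counts",
    "counts_to_bins",
    "read_dataset",
    "write_dataset",
]


def _validate_sequences(sequences: list[str], alphabet: Alphabet) -> int:
    if len(sequences) == 0:
        raise ValueError("dataset has no sequences")
    L = len(sequences[0])
    if L < 1:
        raise ValueError("sequences must have length >= 1")
    for i, s in enumerate(sequences):
        if len(s) != L:
            raise ValueError(
                f"ragged sequence lengths: row 0 has length {L} but row {i} "
                f"({s!r}) has length {len(s)}"
            )
        alphabet.indices(s)  # raises on unknown characters
    return L


@dataclass(frozen=True)
class SequenceDataset:
    """Fixed-length sequences with measurements.

    Exactly one of ``y`` (continuous), ``bins`` (integer bin per read), or
    ``counts`` (per-sequence bin-count matrix) is populated. ``se`` optionally
    carries per-measurement standard errors for the empirical noise model.
    Sequences are case-normalized to upper case at construction; an alphabet
    mismatch (e.g. 'U' in a DNA dataset) is an error, never silently converted.
    """

    sequences: tuple[str, ...]
    alphabet: Alphabet
    y: np.ndarray | None = None
    bins: np.ndarray | None = None
    counts: np.ndarray | None = None
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        _validate_sequences(list(seqs), self.alphabet)
        n = len(seqs)
        modes = [m for m in (self.y, self.bins, self.counts) if m is not None]
        if len(modes) != 1:
            raise ValueError("exactly one of {y, bins, counts} must be populated")
        if self.y is not None:
            y = np.asarray(self.y, dtype=float)
            if y.shape != (n,):
                raise ValueError("y must be one value per sequence")
            if not np.all(np.isfinite(y)):
                raise ValueError("y must be finite")
            object.__setattr__(self, "y", y)
        if self.bins is not None:
            b = np.asarray(self.bins)
            if b.shape != (n,) or not np.issubdtype(b.dtype, np.integer):
                raise ValueError("bins must be one integer per read")
            if b.min() < 0:
                raise ValueError("bins must be nonnegative")
            object.__setattr__(self, "bins", b.astype(np.int64))
        if self.counts is not None:
            c = np.asarray(self.counts)
            if c.ndim != 2 or c.shape[0] != n:
                raise ValueError("counts must be an M x Y matrix")
            if not np.issubdtype(c.dtype, np.integer):
                if not np.allclose(c, np.round(c)):
                    raise ValueError("counts must be integers")
                c = np.round(c).astype(np.int64)
            if c.min() < 0:
                raise ValueError("counts must be nonnegative")
            if np.any(c.sum(axis=1) < 1):
                raise ValueError("each counts row must sum to >= 1")
            object.__setattr__(self, "counts", c.astype(np.int64))
        if self.se is not None:
            s = np.asarray(self.se, dtype=float)
            if s.shape != (n,):
                raise ValueError("se must be one value per sequence")
            if np.any(s <= 0):
                raise ValueError("se must be positive")
            object.__setattr__(self, "se", s)

    # -- basic properties ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    @property
    def C(self) -> int:
        return len(self.alphabet)

    @property
    def n_bins(self) -> int:
        if self.counts is not None:
            return self.counts.shape[1]
        if self.bins is not None:
            return int(self.bins.max()) + 1
        raise ValueError("dataset has no bin structure")

    @property
    def mode(self) -> str:
        if self.y is not None:
            return "ge"
        return "mpa"

    def subset(self, idx) -> "SequenceDataset":
        """Row subset (order preserved for slices/index arrays)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        take = lambda a: None if a is None else a[idx]
        return SequenceDataset(
            sequences=tuple(self.sequences[i] for i in idx),
            alphabet=self.alphabet,
            y=take(self.y),
            bins=take(self.bins),
            counts=take(self.counts),
            se=take(self.se),
        )


# -- one-hot encoding -------------------------------------------------------


def one_hot_encode(sequence: str, alphabet: str | Alphabet) -> np.ndarray:
    """One-hot encode one sequence as an (L, C) binary matrix.

    Entry ``[l, c]`` is 1 iff character ``c`` occurs at position ``l``
    (0-based positions, alphabet order for ``c``). Each row has exactly one 1.
    """
    alphabet = get_alphabet(alphabet)
    idx = alphabet.indices(sequence.upper())
    L, C = len(idx), len(alphabet)
    x = np.zeros((L, C), dtype=np.float64)
    x[np.arange(L), idx] = 1.0
    return x


def one_hot_matrix(sequences, alphabet: str | Alphabet) -> np.ndarray:
    """One-hot encode many sequences as an (N, L, C) array."""
    alphabet = get_alphabet(alphabet)
    seqs = [s.upper() for s in sequences]
    _validate_sequences(seqs, alphabet)
    N, L, C = len(seqs), len(seqs[0]), len(alphabet)
    x = np.zeros((N, L, C), dtype=np.float64)
    for n, s in enumerate(seqs):
        x[n, np.arange(L), alphabet.indices(s)] = 1.0
    return x


def pairwise_features(x: np.ndarray) -> np.ndarray:
    """Products ``x[l, c] * x[l', c']`` for position pairs with ``l' > l``.

    Input is an (L, C) one-hot matrix (or an (N, L, C) batch); output has
    shape (P, C, C) (or (N, P, C, C)) where P = L(L-1)/2 pairs are ordered
    row-major by (l, l'), l' > l. For L < 2 the pair axis is empty.
    """
    x = np.asarray(x, dtype=float)
    batched = x.ndim == 3
    if not batched:
        x = x[None]
    N, L, C = x.shape
    pairs = [(l, lp) for l in range(L) for lp in range(l + 1, L)]
    out = np.zeros((N, len(pairs), C, C), dtype=np.float64)
    for p, (l, lp) in enumerate(pairs):
        out[:, p] = x[:, l, :, None] * x[:, lp, None, :]
    return out if batched else out[0]


# -- read-count preprocessing ----------------------------------------------


def log2_enrichment(c_out, c_in, c_wt_out, c_wt_in) -> np.ndarray:
    """Log2 enrichment of a variant relative to wildtype, with +1 pseudocounts.

    ``y = log2[((c_out+1)/(c_wt_out+1)) / ((c_in+1)/(c_wt_in+1))]``
    where ``c_in``/``c_out`` are pre-/post-selection read counts. The +1
    pseudocount guards zero counts, so the score is defined for all inputs.
    """
    c_out, c_in = np.asarray(c_out, float), np.asarray(c_in, float)
    _check_counts(c_out, "c_out")
    _check_counts(c_in, "c_in")
    _check_counts(np.asarray(c_wt_out, float), "c_wt_out")
    _check_counts(np.asarray(c_wt_in, float), "c_wt_in")
    return np.log2(((c_out + 1) / (c_wt_out + 1)) / ((c_in + 1) / (c_wt_in + 1)))


def log10_psi(c_inc, c_tot, c_cons_inc, c_cons_tot):
    """Log10-scale percent-spliced-in relative to the consensus splice site.

    ``y = log10[100 * ((c_inc+1)/(c_cons_inc+1)) / ((c_tot+1)/(c_cons_tot+1))]``
    with ``PSI = 10**y`` returned alongside. ``c_inc``/``c_tot`` are barcode
    reads from inclusion isoforms and total mRNA; the consensus site itself
    scores y = 2, PSI = 100.
    """
    c_inc, c_tot = np.asarray(c_inc, float), np.asarray(c_tot, float)
    _check_counts(c_inc, "c_inc")
    _check_counts(c_tot, "c_tot")
    _check_counts(np.asarray(c_cons_inc, float), "c_cons_inc")
    _check_counts(np.asarray(c_cons_tot, float), "c_cons_tot")
    y = np.log10(
        100.0 * ((c_inc + 1) / (c_cons_inc + 1)) / ((c_tot + 1) / (c_cons_tot + 1))
    )
    return y, 10.0**y


def _check_counts(c: np.ndarray, name: str) -> None:
    if np.any(c < 0):
        raise ValueError(f"{name} must be nonnegative")
    if not np.allclose(c, np.round(c)):
        raise ValueError(f"{name} must be integer counts")


def filter_by_min_count(df: pd.DataFrame, column: str, threshold: int):
    """Retain rows whose ``column`` count is >= threshold (order preserved).

    Returns ``(filtered_df, n_retained, n_total)``. Idempotent. Used e.g. to
    keep only variants with at least 10 input reads before score computation.
    """
    if column not in df.columns:
        raise KeyError(f"count column {column!r} not present in dataframe")
    keep = df[column] >= threshold
    out = df[keep]
    return out, int(keep.sum()), len(df)


# -- bins <-> counts --------------------------------------------------------


def bins_to_counts(sequences, bins, n_bins: int | None = None):
    """Collapse per-read (sequence, bin) pairs into a per-unique-sequence count matrix.

    Returns ``(unique_sequences, counts)`` with counts[m, y] the number of
    reads of sequence m in bin y. Unique sequences keep first-appearance order.
    """
    bins = np.asarray(bins)
    if len(bins) != len(sequences):
        raise ValueError("sequences and bins must have equal length")
    if len(bins) and bins.min() < 0:
        raise ValueError("bins must be nonnegative")
    Y = int(n_bins if n_bins is not None else (bins.max() + 1 if len(bins) else 0))
    order: dict[str, int] = {}
    for s in sequences:
        if s not in order:
            order[s] = len(order)
    counts = np.zeros((len(order), Y), dtype=np.int64)
    for s, b in zip(sequences, bins):
        counts[order[s], b] += 1
    return list(order), counts


def counts_to_bins(sequences, counts):
    """Expand a count matrix back into per-read (sequence, bin) pairs."""
    counts = np.asarray(counts)
    seqs, bins = [], []
    for s, row in zip(sequences, counts):
        for b, c in enumerate(row):
            seqs.extend([s] * int(c))
            bins.extend([b] * int(c))
    return seqs, np.asarray(bins, dtype=np.int64)


def relabel_bins(bins) -> np.ndarray:
    """Map arbitrary sorted-unique bin labels onto contiguous integers from 0."""
    bins = np.asarray(bins)
    uniq = np.unique(bins)
    lut = {v: i for i, v in enumerate(uniq)}
    return np.asarray([lut[v] for v in bins], dtype=np.int64)


# -- I/O ---------------------------------------------------------------------


def read_dataset(path, alphabet: str | Alphabet, sep: str = "\t") -> SequenceDataset:
    """Read a dataset table (columns ``seq`` plus ``y``[, ``dy``] / ``bin`` / ``ct_*``)."""
    df = pd.read_csv(path, sep=sep)
    if "seq" not in df.columns:
        raise ValueError("dataset table must have a 'seq' column")
    alphabet = get_alphabet(alphabet)
    seqs = tuple(str(s) for s in df["seq"])
    ct_cols = sorted(
        (c for c in df.columns if c.startswith("ct_")), key=lambda c: int(c[3:])
    )
    if "y" in df.columns:
        se = df["dy"].to_numpy(float) if "dy" in df.columns else None
        return SequenceDataset(seqs, alphabet, y=df["y"].to_numpy(float), se=se)
    if "bin" in df.columns:
        bins = df["bin"].to_numpy()
        if not np.allclose(bins, np.round(bins)):
            raise ValueError("'bin' column must be integer")
        return SequenceDataset(seqs, alphabet, bins=np.round(bins).astype(np.int64))
    if ct_cols:
        counts = df[ct_cols].to_numpy()
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("count columns must be integers")
        counts = np.round(counts).astype(np.int64)
        if counts.min() < 0:
            raise ValueError("count columns must be nonnegative")
        return SequenceDataset(seqs, alphabet, counts=counts)
    raise ValueError("dataset table needs a 'y', 'bin', or 'ct_0..ct_{Y-1}' columns")


def write_dataset(dataset: SequenceDataset, path, sep: str = "\t") -> None:
    """Write a dataset in the layout :func:`read_dataset` accepts (round-trips)."""
    cols: dict[str, object] = {"seq": list(dataset.sequences)}
    if dataset.y is not None:
        cols["y"] = dataset.y
        if dataset.se is not None:
            cols["dy"] = dataset.se
    elif dataset.bins is not None:
        cols["bin"] = dataset.bins
    else:
        for b in range(dataset.counts.shape[1]):
            cols[f"ct_{b}"] = dataset.counts[:, b]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_fasta(path, alphabet: str | Alphabet) -> list[str]:
    """Read sequences (only) from a FASTA file, for feeding the simulator."""
    from Bio import SeqIO

    alphabet = get_alphabet(alphabet)
    seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    _validate_sequences(seqs, alphabet)
    return seqs
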