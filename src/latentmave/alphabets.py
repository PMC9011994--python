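"""Sequence alphabets.

An :class:`Alphabet` is an ordered set of single characters. The ordering
matters: one-hot feature indices, parameter matrices, and serialized model
bundles all use the alphabet's character order, so two models are only
comparable if built over the same alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Alphabet:
    """Ordered alphabet of ``C`` distinct single characters.

    Parameters
    ----------
    name : str
        Identifier recorded in serialized models.
    characters : tuple of str
        Ordered, unique single characters; at least two.
    """

    name: str
    characters: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        chars = tuple(self.characters)
        if len(chars) < 2:
            raise ValueError("alphabet needs at least 2 characters")
        if any(len(c) != 1 for c in chars):
            raise ValueError("alphabet characters must be single characters")
        if len(set(chars)) != len(chars):
            raise ValueError("alphabet characters must be unique")
        object.__setattr__(self, "characters", chars)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(chars)})

    def __len__(self) -> int:
        return len(self.characters)

    def __contains__(self, c: str) -> bool:
        return c in self._index

    def index(self, c: str) -> int:
        """Index of character ``c``; raises KeyError with the character named."""
        try:
            return self._index[c]
        except KeyError:
            raise KeyError(f"character {c!r} not in alphabet {self.name!r}") from None

    def indices(self, sequence: str) -> list[int]:
        """Per-position character indices for ``sequence``.

        Raises ``ValueError`` naming the first offending position/character.
        """
        idx = self._index
        out = []
        for pos, c in enumerate(sequence):
            try:
                out.append(idx[c])
            except KeyError:
                raise ValueError(
                    f"character {c!r} at position {pos} not in alphabet {self.name!r}"
                ) from None
        return out


DNA = Alphabet("dna", tuple("ACGT"))
RNA = Alphabet("rna", tuple("ACGU"))
PROTEIN = Alphabet("protein", tuple("ACDEFGHIKLMNPQRSTVWY"))
PROTEIN_STOP = Alphabet("protein*", tuple("ACDEFGHIKLMNPQRSTVWY*"))

BUILTIN_ALPHABETS: dict[str, Alphabet] = {
    a.name: a for a in (DNA, RNA, PROTEIN, PROTEIN_STOP)
}


def get_alphabet(spec: str | Alphabet) -> Alphabet:
    """Resolve a built-in alphabet name, a custom character string, or pass through.

    A plain string that is not a built-in name is interpreted as the ordered
    characters of a custom alphabet (e.g. ``"ACGT-"`` for gapped DNA).
    """
    if isinstance(spec, Alphabet):
        return spec
    if spec in BUILTIN_ALPHABETS:
        return BUILTIN_ALPHABETS[spec]
    return Alphabet(f"custom:{spec}", tuple(spec))
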