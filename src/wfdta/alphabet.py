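"""Residue alphabet and positional indexing of n-peptides.

Protein sequences are drawn from a 25-letter alphabet: the 20 standard amino
acids plus the extended codes B, O, U, X and Z (the uppercase Latin letters
with J removed), in lexicographic order.  An n-peptide is mapped to a column
index by reading it as a base-25 numeral, first letter most significant, so
the 25**n columns of every feature vector have a fixed, documented layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_LETTERS = "ABCDEFGHIKLMNOPQRSTUVWXYZ"  # A-Z without J


@dataclass(frozen=True)
class PeptideAlphabet:
    """Ordered 25-symbol residue alphabet with a bijective n-peptide index."""

    letters: str = DEFAULT_LETTERS
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        letters = self.letters
        if len(letters) != 25 or len(set(letters)) != 25:
            raise ValueError("alphabet must contain exactly 25 distinct symbols")
        if not letters.isupper():
            raise ValueError("alphabet symbols must be uppercase")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(letters)})

    @property
    def size(self) -> int:
        return len(self.letters)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def letter_index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise ValueError(f"residue {symbol!r} is not in the 25-letter alphabet") from None

    def peptide_index(self, peptide: str) -> int:
        """Base-25 positional index of an n-peptide, in [0, 25**n)."""
        if not peptide:
            raise ValueError("peptide must be non-empty")
        idx = 0
        for symbol in peptide:
            idx = idx * 25 + self.letter_index(symbol)
        return idx

    def index_to_peptide(self, index: int, n: int) -> str:
        """Inverse of :meth:`peptide_index` for peptides of order ``n``."""
        if not 0 <= index < 25**n:
            raise ValueError(f"index {index} out of range for n={n}")
        out = []
        for _ in range(n):
            index, rem = divmod(index, 25)
            out.append(self.letters[rem])
        return "".join(reversed(out))

    def peptide_labels(self, n: int) -> list[str]:
        """All 25**n peptide strings in index order."""
        return [self.index_to_peptide(i, n) for i in range(25**n)]


DEFAULT_ALPHABET = PeptideAlphabet()


def peptide_index(peptide: str, alphabet: PeptideAlphabet = DEFAULT_ALPHABET) -> int:
    return alphabet.peptide_index(peptide)
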