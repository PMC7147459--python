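"""Polypeptide-frequency and word-frequency protein feature vectors.

A protein sequence of length L over the 25-letter alphabet contains
L - n + 1 overlapping n-peptide windows.  The *polypeptide frequency*
vector F has one entry per possible n-peptide,

    v_i = n_i / (L - n + 1),

where n_i counts windows equal to peptide i, so the vector sums to 1.
The *word-frequency* (WF) encoding reweights each within-sequence frequency
by the fraction of corpus sequences that contain the peptide at all:

    wf_i = (w_i / N) * p_i / (L - n + 1),

with w_i the number of corpus sequences containing peptide i and N the
corpus size.  Rare peptides are thereby damped rather than boosted — the
opposite of the IDF weight log10(N / w_i), which is provided for comparison
only.  Word-frequency weights are fitted on a training corpus and reused
unchanged for held-out sequences.

For dipeptides (n = 2) the window count L - n + 1 equals L - 1; a
``strict_denominator`` flag forces the L - 1 denominator at every order for
compatibility, at the price of frequency vectors that no longer sum to 1
when n != 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import DEFAULT_ALPHABET, PeptideAlphabet

UNKNOWN_RESIDUE = "X"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein primary structure: identifier plus residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.residues:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FrequencyVector:
    """Normalized n-peptide counts for one sequence (sums to 1)."""

    n: int
    values: np.ndarray


@dataclass(frozen=True)
class CorpusWeights:
    """Per-peptide document counts over a corpus of N sequences."""

    n: int
    n_sequences: int
    counts: np.ndarray  # integer, 0 <= counts <= n_sequences

    @property
    def word_frequency(self) -> np.ndarray:
        """w_i / N, the fraction of sequences containing each peptide."""
        return self.counts / self.n_sequences


@dataclass(frozen=True)
class WFVector:
    """Word-frequency-weighted peptide frequencies for one sequence."""

    n: int
    values: np.ndarray


def _clean_residues(seq: ProteinSequence, alphabet: PeptideAlphabet, remap_unknown: bool) -> str:
    residues = seq.residues
    bad = [c for c in residues if c not in alphabet]
    if not bad:
        return residues
    if remap_unknown:
        return "".join(c if c in alphabet else UNKNOWN_RESIDUE for c in residues)
    raise ValueError(
        f"protein {seq.id!r} contains residue {bad[0]!r} outside the 25-letter alphabet"
    )


def _window_counts(
    seq: ProteinSequence,
    n: int,
    alphabet: PeptideAlphabet,
    remap_unknown: bool,
) -> np.ndarray:
    if n < 1:
        raise ValueError("peptide order n must be >= 1")
    residues = _clean_residues(seq, alphabet, remap_unknown)
    L = len(residues)
    if L < n:
        raise ValueError(f"protein {seq.id!r} is shorter (L={L}) than the peptide order n={n}")
    counts = np.zeros(25**n, dtype=np.int64)
    letter_codes = np.array([alphabet.letter_index(c) for c in residues], dtype=np.int64)
    idx = letter_codes[: L - n + 1].copy()
    for k in range(1, n):
        idx = idx * 25 + letter_codes[k : L - n + 1 + k]
    np.add.at(counts, idx, 1)
    return counts


def _denominator(L: int, n: int, strict_denominator: bool) -> int:
    return (L - 1) if strict_denominator else (L - n + 1)


def peptide_frequency(
    seq: ProteinSequence,
    n: int,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
    *,
    remap_unknown: bool = False,
    strict_denominator: bool = False,
) -> FrequencyVector:
    """Normalized n-peptide composition of one sequence."""
    counts = _window_counts(seq, n, alphabet, remap_unknown)
    denom = _denominator(len(seq), n, strict_denominator)
    if denom < 1:
        raise ValueError(f"protein {seq.id!r} too short for the requested denominator")
    return FrequencyVector(n=n, values=counts / denom)


def document_counts(
    corpus: list[ProteinSequence],
    n: int,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
    *,
    remap_unknown: bool = False,
) -> CorpusWeights:
    """Count, for each peptide, how many corpus sequences contain it (presence)."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    counts = np.zeros(25**n, dtype=np.int64)
    for seq in corpus:
        counts += _window_counts(seq, n, alphabet, remap_unknown) > 0
    return CorpusWeights(n=n, n_sequences=len(corpus), counts=counts)


def idf(weights: CorpusWeights) -> np.ndarray:
    """Inverse document frequency log10(N / w_i); NaN where w_i = 0.

    Provided for comparison with the word-frequency weight only.
    """
    out = np.full(weights.counts.shape, np.nan)
    seen = weights.counts > 0
    out[seen] = np.log10(weights.n_sequences / weights.counts[seen])
    return out


def wf_encode(
    seq: ProteinSequence,
    weights: CorpusWeights,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
    *,
    remap_unknown: bool = False,
    strict_denominator: bool = False,
) -> WFVector:
    """Word-frequency-weighted peptide frequencies of one sequence.

    ``weights`` must come from the training corpus; held-out sequences are
    encoded with the same weights to avoid leakage.
    """
    freq = peptide_frequency(
        seq,
        weights.n,
        alphabet,
        remap_unknown=remap_unknown,
        strict_denominator=strict_denominator,
    )
    return WFVector(n=weights.n, values=weights.word_frequency * freq.values)


def encode_corpus(
    corpus: list[ProteinSequence],
    weights: CorpusWeights,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
    *,
    remap_unknown: bool = False,
    strict_denominator: bool = False,
) -> pd.DataFrame:
    """Encode sequences into a (sequence x 25**n) matrix of WF features.

    Rows are indexed by sequence id, columns labelled with peptide strings
    (e.g. "PE"); encoding is deterministic.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    rows = []
    for seq in corpus:
        try:
            rows.append(
                wf_encode(
                    seq,
                    weights,
                    alphabet,
                    remap_unknown=remap_unknown,
                    strict_denominator=strict_denominator,
                ).values
            )
        except ValueError as exc:
            raise ValueError(f"failed to encode sequence {seq.id!r}: {exc}") from exc
    return pd.DataFrame(
        np.vstack(rows),
        index=[s.id for s in corpus],
        columns=alphabet.peptide_labels(weights.n),
    )


class WordFrequencyEncoder:
    """Fit word-frequency weights on a training corpus, then encode sequences.

    Mirrors the fit/transform convention of scikit-learn vectorizers: weights
    are learned once from training data and applied unchanged to new
    sequences.
    """

    def __init__(
        self,
        n: int = 2,
        alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
        *,
        remap_unknown: bool = False,
        strict_denominator: bool = False,
    ) -> None:
        self.n = n
        self.alphabet = alphabet
        self.remap_unknown = remap_unknown
        self.strict_denominator = strict_denominator
        self.weights_: CorpusWeights | None = None

    @property
    def dim(self) -> int:
        return 25**self.n

    def fit(self, corpus: list[ProteinSequence]) -> "WordFrequencyEncoder":
        self.weights_ = document_counts(
            corpus, self.n, self.alphabet, remap_unknown=self.remap_unknown
        )
        return self

    def transform(self, corpus: list[ProteinSequence]) -> pd.DataFrame:
        if self.weights_ is None:
            raise RuntimeError("encoder must be fitted before transform")
        return encode_corpus(
            corpus,
            self.weights_,
            self.alphabet,
            remap_unknown=self.remap_unknown,
            strict_denominator=self.strict_denominator,
        )

    def fit_transform(self, corpus: list[ProteinSequence]) -> pd.DataFrame:
        return self.fit(corpus).transform(corpus)


def read_fasta(path) -> list[ProteinSequence]:
    """Load protein sequences from a FASTA file (uppercased)."""
    records = [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def read_sequence_csv(path, id_column: str = "protein_id", seq_column: str = "sequence") -> list[ProteinSequence]:
    """Load protein sequences from a CSV with (protein_id, sequence) columns."""
    table = pd.read_csv(path, dtype=str)
    for col in (id_column, seq_column):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    return [
        ProteinSequence(id=row[id_column], residues=row[seq_column].upper())
        for _, row in table.iterrows()
    ]
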