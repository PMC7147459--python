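"""Peptide indexing, frequency vectors and word-frequency encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wfdta as w
from wfdta.protein_encoding import read_fasta, read_sequence_csv

ALPHABET = w.DEFAULT_ALPHABET
LETTERS = ALPHABET.letters


class TestPeptideIndex:
    @pytest.mark.parametrize(
        "peptide,expected",
        [("A", 0), ("AA", 0), ("ZZ", 624), ("Z", 24), ("AB", 1), ("BA", 25)],
    )
    def test_known_indices(self, peptide, expected):
        assert w.peptide_index(peptide) == expected

    def test_bijective_for_dipeptides(self):
        seen = {ALPHABET.peptide_index(a + b) for a in LETTERS for b in LETTERS}
        assert seen == set(range(625))

    def test_index_roundtrip(self):
        for idx in (0, 1, 333, 624):
            assert ALPHABET.peptide_index(ALPHABET.index_to_peptide(idx, 2)) == idx

    def test_rejects_out_of_alphabet_symbol(self):
        with pytest.raises(ValueError, match="'J'"):
            w.peptide_index("AJ")

    def test_alphabet_has_25_letters_without_j(self):
        assert len(LETTERS) == 25
        assert "J" not in LETTERS
        assert list(LETTERS) == sorted(LETTERS)


class TestPeptideFrequency:
    def test_single_window_is_one(self):
        fv = w.peptide_frequency(w.ProteinSequence("s", "AA"), 2)
        assert fv.values[w.peptide_index("AA")] == 1.0
        assert fv.values.sum() == 1.0

    def test_hand_enumerated_dipeptides(self):
        # windows of "ACAC": AC, CA, AC
        fv = w.peptide_frequency(w.ProteinSequence("s", "ACAC"), 2)
        assert fv.values[w.peptide_index("AC")] == pytest.approx(2 / 3, abs=1e-12)
        assert fv.values[w.peptide_index("CA")] == pytest.approx(1 / 3, abs=1e-12)
        assert np.count_nonzero(fv.values) == 2

    def test_monopeptides_of_distinct_residues(self):
        fv = w.peptide_frequency(w.ProteinSequence("s", "ACDEFG"), 1)
        for c in "ACDEFG":
            assert fv.values[w.peptide_index(c)] == pytest.approx(1 / 6, abs=1e-12)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            w.peptide_frequency(w.ProteinSequence("s", "A"), 2)

    def test_out_of_alphabet_rejected_or_remapped(self):
        seq = w.ProteinSequence("s", "AJC")
        with pytest.raises(ValueError, match="'J'"):
            w.peptide_frequency(seq, 1)
        fv = w.peptide_frequency(seq, 1, remap_unknown=True)
        assert fv.values[w.peptide_index("X")] == pytest.approx(1 / 3)

    def test_strict_denominator_matches_default_at_n2(self):
        seq = w.ProteinSequence("s", "ACDEFGH")
        default = w.peptide_frequency(seq, 2).values
        strict = w.peptide_frequency(seq, 2, strict_denominator=True).values
        np.testing.assert_array_equal(default, strict)
        # at n=3 the strict window count is L-1, so the sum drops below 1
        assert w.peptide_frequency(seq, 3, strict_denominator=True).values.sum() < 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.text(alphabet=LETTERS, min_size=3, max_size=60),
        st.integers(min_value=1, max_value=3),
    )
    def test_frequencies_sum_to_one(self, residues, n):
        fv = w.peptide_frequency(w.ProteinSequence("s", residues), n)
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert fv.values.min() >= 0.0


class TestDocumentCountsAndIdf:
    def test_hand_counts(self):
        wt = w.document_counts([w.ProteinSequence("a", "AC"), w.ProteinSequence("b", "CA")], 2)
        assert wt.counts[w.peptide_index("AC")] == 1
        assert wt.counts[w.peptide_index("CA")] == 1
        assert wt.n_sequences == 2

    def test_presence_not_multiplicity(self):
        wt = w.document_counts([w.ProteinSequence("a", "AAAA")], 2)
        assert wt.counts[w.peptide_index("AA")] == 1

    def test_peptide_in_every_sequence(self):
        wt = w.document_counts([w.ProteinSequence("a", "AA"), w.ProteinSequence("b", "AA")], 2)
        assert wt.counts[w.peptide_index("AA")] == 2

    def test_absent_peptide_is_zero(self):
        wt = w.document_counts([w.ProteinSequence("a", "AC")], 2)
        assert wt.counts[w.peptide_index("CA")] == 0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            w.document_counts([], 2)

    def test_corpus_order_irrelevant(self):
        seqs = [w.ProteinSequence(f"s{i}", s) for i, s in enumerate(["ACDE", "CDEA", "EDCA"])]
        a = w.document_counts(seqs, 2).counts
        b = w.document_counts(seqs[::-1], 2).counts
        np.testing.assert_array_equal(a, b)

    def test_idf_values_and_undefined_marker(self):
        wt = w.CorpusWeights(n=1, n_sequences=100, counts=np.array([100, 1, 0] + [0] * 22))
        vals = w.idf(wt)
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(2.0)
        assert np.isnan(vals[2])


class TestWFEncoding:
    def test_hand_evaluated_wf(self):
        corpus = [w.ProteinSequence("a", "AC"), w.ProteinSequence("b", "CA")]
        wt = w.document_counts(corpus, 2)
        vec = w.wf_encode(w.ProteinSequence("x", "AC"), wt)
        assert vec.values[w.peptide_index("AC")] == pytest.approx(0.5, abs=1e-12)
        assert np.count_nonzero(vec.values) == 1

    def test_full_presence_equals_plain_frequency(self):
        corpus = [w.ProteinSequence("a", "AC"), w.ProteinSequence("b", "ACA")]
        wt = w.document_counts(corpus, 2)
        vec = w.wf_encode(w.ProteinSequence("x", "AC"), wt)
        assert vec.values[w.peptide_index("AC")] == pytest.approx(1.0, abs=1e-12)

    def test_wf_dominated_by_frequency(self):
        rng = np.random.default_rng(3)
        corpus = [
            w.ProteinSequence(f"s{i}", "".join(rng.choice(list(LETTERS), size=40)))
            for i in range(6)
        ]
        wt = w.document_counts(corpus, 2)
        for seq in corpus:
            v = w.peptide_frequency(seq, 2).values
            wf = w.wf_encode(seq, wt).values
            assert np.all(wf <= v + 1e-15)
            assert np.all(wf[v == 0] == 0)

    def test_encode_corpus_shape_and_layout(self):
        corpus = [w.ProteinSequence("a", "ACDE"), w.ProteinSequence("b", "CDEF")]
        wt = w.document_counts(corpus, 2)
        matrix = w.encode_corpus(corpus, wt)
        assert matrix.shape == (2, 625)
        assert list(matrix.index) == ["a", "b"]
        assert matrix.columns[w.peptide_index("PE")] == "PE"

    @pytest.mark.parametrize("n,dim", [(1, 25), (2, 625), (3, 15_625)])
    def test_dimensions_by_order(self, n, dim):
        enc = w.WordFrequencyEncoder(n=n)
        seqs = [w.ProteinSequence("a", "ACDEFGHIKL")]
        assert enc.fit_transform(seqs).shape == (1, dim)

    def test_encoding_deterministic(self):
        rng = np.random.default_rng(5)
        corpus = [
            w.ProteinSequence(f"s{i}", "".join(rng.choice(list(LETTERS), size=30)))
            for i in range(4)
        ]
        a = w.WordFrequencyEncoder(n=2).fit_transform(corpus)
        b = w.WordFrequencyEncoder(n=2).fit_transform(corpus)
        assert a.equals(b)

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            w.WordFrequencyEncoder().transform([w.ProteinSequence("a", "ACDE")])


class TestSequenceIO:
    def test_fasta_roundtrip(self, tmp_path):
        path = tmp_path / "prot.fasta"
        path.write_text(">p1\nACDE\n>p2\nMNPQ\n")
        seqs = read_fasta(path)
        assert [s.id for s in seqs] == ["p1", "p2"]
        assert seqs[0].residues == "ACDE"

    def test_csv_reader(self, tmp_path):
        path = tmp_path / "prot.csv"
        path.write_text("protein_id,sequence\np1,acde\n")
        seqs = read_sequence_csv(path)
        assert seqs[0].residues == "ACDE"
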