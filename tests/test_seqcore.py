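"""Sequence model: reverse complement, translation, frames, ORF enumeration."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from olgkit.seqcore import (
    ALL_FRAMES,
    AlphabetError,
    ConfigError,
    DEFAULT_START_CODONS,
    EmbeddedOrf,
    FrameError,
    GeneAnnotation,
    GenomeRecord,
    enumerate_embedded_orfs,
    relative_frame,
    revcomp,
    translate,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=120)


class TestRevcomp:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("", ""), ("CAA", "TTG"), ("ANC", "GNT")],
    )
    def test_examples(self, seq, expected):
        assert revcomp(seq) == expected

    @given(dna)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_rejects_non_dna(self):
        with pytest.raises(AlphabetError):
            revcomp("ACGU")


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,aa",
        [("ATGTAA", "M*"), ("TCT", "S"), ("ATGNNNTGA", "MX*"), ("", "")],
    )
    def test_examples(self, nt, aa):
        assert translate(nt) == aa

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate("ATGA")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=60).filter(lambda s: len(s) % 3 == 0))
    def test_revcomp_frame_consistency(self, seq):
        # translating the reverse complement equals translating each codon of
        # the complementary strand in reverse order
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        expected = "".join(translate(revcomp(c)) for c in reversed(codons))
        assert translate(revcomp(seq)) == expected


class TestRecordsAndAnnotations:
    def test_record_validates_alphabet_and_length(self):
        with pytest.raises(AlphabetError):
            GenomeRecord("x", "ACGTX")
        with pytest.raises(ValueError):
            GenomeRecord("x", "")

    def test_annotation_invariants(self):
        with pytest.raises(ValueError):
            GeneAnnotation("g", "r", 10, 10, "+")
        with pytest.raises(ValueError):
            GeneAnnotation("g", "r", 0, 10, "+")  # not codon multiple
        with pytest.raises(ValueError):
            GeneAnnotation("g", "r", 0, 9, "*")

    def test_embedded_orf_invariants(self):
        with pytest.raises(ValueError, match="stop"):
            EmbeddedOrf("o", "m", 0, 6, "+", 1, "ATGAAA", "M", 6)
        with pytest.raises(ValueError, match="aa length"):
            EmbeddedOrf("o", "m", 0, 6, "+", 1, "ATGTAA", "MK", 6)


class TestRelativeFrame:
    MOTHER = GeneAnnotation("m", "r", 120, 180, "+")

    def test_mother_own_start_is_plus_one(self):
        assert relative_frame(self.MOTHER, 120, "+") == 1

    def test_six_offsets_partition_all_labels(self):
        labels = {
            relative_frame(self.MOTHER, 120 + off, strand)
            for off in (0, 1, 2)
            for strand in "+-"
        }
        assert labels == set(ALL_FRAMES)

    @pytest.mark.parametrize("shift", [3, 30, 999])
    def test_translation_invariance(self, shift):
        shifted = GeneAnnotation("m", "r", 120 + shift, 180 + shift, "+")
        for off in range(3):
            for strand in "+-":
                assert relative_frame(self.MOTHER, 123 + off, strand) == (
                    relative_frame(shifted, 123 + shift + off, strand)
                )

    def test_non_overlap_is_domain_error(self):
        with pytest.raises(FrameError):
            relative_frame(self.MOTHER, 300, "-", orf_end=330)


def brute_force_orfs(record, mother, min_aa_len, start_codons, frames):
    """Independent scanner: test every position x strand x frame."""
    from olgkit.seqcore import _stop_codons  # oracle shares only constants

    stops = _stop_codons(11)
    found = []
    n = len(record.seq)
    for strand in "+-":
        seq = record.seq if strand == "+" else revcomp(record.seq)
        for pos in range(n - 2):
            if seq[pos : pos + 3] not in start_codons:
                continue
            q = pos + 3
            while q + 3 <= n and seq[q : q + 3] not in stops:
                q += 3
            if q + 3 > n:
                continue
            s_local, e_local = pos, q + 3
            if strand == "+":
                start, end = s_local, e_local
            else:
                start, end = n - e_local, n - s_local
            if min(end, mother.end) - max(start, mother.start) < 1:
                continue
            if relative_frame(mother, start, strand) not in frames:
                continue
            if (end - start) // 3 - 1 < min_aa_len:
                continue
            found.append((start, end, strand))
    return sorted(found)


class TestEnumerateEmbeddedOrfs:
    def test_requires_frames(self, fixture):
        with pytest.raises(ConfigError):
            enumerate_embedded_orfs(fixture.record, fixture.mother, frames=())

    def test_no_candidates_in_tiny_gene(self):
        record = GenomeRecord("r", "ATG" + "GGA" * 10 + "TAA")
        mother = GeneAnnotation("m", "r", 0, len(record), "+")
        assert enumerate_embedded_orfs(record, mother, min_aa_len=5) == []

    def test_fixture_recovers_exactly_planted_orfs(self, fixture, planted_orfs):
        intervals = {(o.start, o.end, o.strand) for o in planted_orfs}
        assert intervals == {
            (*fixture.ledger["orf"], "-"),
            (*fixture.ledger["upstream_orf"], "-"),
        }
        by_len = sorted(o.aa_len for o in planted_orfs)
        assert by_len == [41, 61]

    def test_planted_orf_is_frame_minus_two(self, embedded_orf):
        assert embedded_orf.relative_frame == -2
        assert embedded_orf.overlap_bp == len(embedded_orf)  # fully embedded

    def test_matches_brute_force_oracle_on_fixture(self, fixture):
        got = [
            (o.start, o.end, o.strand)
            for o in enumerate_embedded_orfs(
                fixture.record, fixture.mother, min_aa_len=15
            )
        ]
        expected = brute_force_orfs(
            fixture.record,
            fixture.mother,
            15,
            DEFAULT_START_CODONS,
            (-1, -2, -3),
        )
        assert got == expected

    @given(st.integers(0, 200))
    def test_matches_brute_force_oracle_on_random_sequences(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 900))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        m0 = 3 * int(rng.integers(0, (n - 60) // 3))
        mother = GeneAnnotation("m", "r", m0, m0 + 60, "+")
        record = GenomeRecord("r", seq)
        got = [
            (o.start, o.end, o.strand)
            for o in enumerate_embedded_orfs(
                record, mother, min_aa_len=5, frames=ALL_FRAMES
            )
        ]
        expected = brute_force_orfs(
            record, mother, 5, DEFAULT_START_CODONS, ALL_FRAMES
        )
        assert got == expected

    def test_orfs_well_formed(self, planted_orfs):
        for o in planted_orfs:
            assert o.nt_seq[:3] in DEFAULT_START_CODONS
            assert "*" not in o.aa_seq
            assert len(o.aa_seq) == (o.end - o.start) // 3 - 1
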