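"""Genome and annotation data model, genetic code, and embedded-ORF enumeration.

Antisense overlapping genes (OLGs) are protein-coding ORFs embedded in an
alternative reading frame of an established "mother" gene.  With the mother
gene defined as frame +1, a second gene can run on the same strand in frames
+2/+3 or antiparallel in frames -1/-2/-3.  This module fixes the coordinate
and frame conventions used throughout the package and enumerates candidate
embedded ORFs.

Conventions
-----------
* All genomic coordinates are 0-based, half-open, on the forward strand.
  GFF3 input (1-based, closed) is converted at the reader boundary.
* Relative reading frame of an ORF with respect to a mother gene: let
  ``p = (orf_left - mother_left) mod 3`` where both coordinates are the
  5'-most (leftmost) genomic coordinates on the forward strand.  Same-strand
  ORFs are labelled +1/+2/+3 for p = 0/1/2; antisense ORFs are labelled
  -1/-2/-3 for p = 2/1/0.  The literature does not agree on a single
  antisense numbering rule; this one is a documented, swappable choice
  (see :func:`relative_frame`), calibrated so that the canonical fixture
  geometry produced by :mod:`olgkit.synthdata` is labelled -2.
* Translation uses the bacterial genetic code (NCBI table 11) by default.
  Codons containing ``N`` translate to ``X`` and are never starts or stops.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "AlphabetError",
    "ConfigError",
    "FrameError",
    "GenomeRecord",
    "GeneAnnotation",
    "EmbeddedOrf",
    "revcomp",
    "translate",
    "relative_frame",
    "enumerate_embedded_orfs",
    "DEFAULT_START_CODONS",
    "ANTISENSE_FRAMES",
    "ALL_FRAMES",
]

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_START_CODONS: tuple[str, ...] = ("ATG", "GTG", "TTG")
ANTISENSE_FRAMES: tuple[int, ...] = (-1, -2, -3)
ALL_FRAMES: tuple[int, ...] = (1, 2, 3, -1, -2, -3)


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class ConfigError(ValueError):
    """An operation was configured with invalid parameters."""


class FrameError(ValueError):
    """A frame relation was requested for a non-overlapping gene pair."""


def _check_dna(seq: str) -> str:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"non-DNA characters in sequence: {sorted(bad)!r}")
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T, N}.

    An involution: ``revcomp(revcomp(s)) == s``.  The empty string maps to
    itself.
    """
    _check_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@functools.lru_cache(maxsize=None)
def _codon_map(table_id: int) -> dict[str, str]:
    table = unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@functools.lru_cache(maxsize=None)
def _stop_codons(table_id: int) -> frozenset[str]:
    return frozenset(unambiguous_dna_by_id[table_id].stop_codons)


def translate(nt_seq: str, table: int = 11) -> str:
    """Translate a DNA string, one amino acid per codon, ``*`` for stops.

    Parameters
    ----------
    nt_seq:
        DNA over {A, C, G, T, N}; length must be divisible by 3.
    table:
        NCBI genetic-code table id (default 11, bacterial).

    Codons containing ``N`` translate to ``X``.
    """
    _check_dna(nt_seq)
    if len(nt_seq) % 3:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    mapping = _codon_map(table)
    out = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3]
        out.append("X" if "N" in codon else mapping[codon])
    return "".join(out)


@dataclass(frozen=True)
class GenomeRecord:
    """A replicon: sequence plus identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError("genome record must contain at least one base")
        _check_dna(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneAnnotation:
    """A strand-aware protein-coding feature in 0-based half-open coordinates."""

    gene_id: str
    record_id: str
    start: int
    end: int
    strand: str
    kind: str = "mother"  # mother | overlapping | putative

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if (self.end - self.start) % 3:
            raise ValueError(
                f"{self.gene_id}: length {self.end - self.start} not divisible by 3"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def validate_against(self, record: GenomeRecord) -> None:
        if self.record_id != record.id:
            raise ValueError(
                f"{self.gene_id} annotated on {self.record_id}, not {record.id}"
            )
        if self.end > len(record):
            raise ValueError(f"{self.gene_id} extends past end of {record.id}")

    def sequence(self, record: GenomeRecord) -> str:
        """Coding-strand sequence of the feature."""
        self.validate_against(record)
        sub = record.seq[self.start : self.end]
        return sub if self.strand == "+" else revcomp(sub)


@dataclass(frozen=True)
class EmbeddedOrf:
    """An ORF on either strand with its frame label relative to a mother gene.

    ``nt_seq`` is the coding-strand sequence including the terminal stop
    codon; ``aa_seq`` excludes the stop.  ``overlap_bp`` is the length of the
    genomic intersection with the mother gene interval.
    """

    orf_id: str
    mother_gene_id: str
    start: int
    end: int
    strand: str
    relative_frame: int
    nt_seq: str
    aa_seq: str
    overlap_bp: int
    table: int = field(default=11, compare=False)

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be divisible by 3")
        expected_aa = (self.end - self.start) // 3 - 1
        if len(self.aa_seq) != expected_aa:
            raise ValueError(
                f"aa length {len(self.aa_seq)} != (end-start)/3 - 1 = {expected_aa}"
            )
        if self.nt_seq[-3:] not in _stop_codons(self.table):
            raise ValueError("ORF must end in a stop codon")
        if "*" in self.aa_seq:
            raise ValueError("ORF contains an internal stop codon")
        if self.relative_frame not in ALL_FRAMES:
            raise ValueError(f"invalid frame label {self.relative_frame}")

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)

    def __len__(self) -> int:
        return self.end - self.start


def relative_frame(
    mother: GeneAnnotation,
    orf_start: int,
    orf_strand: str,
    orf_end: int | None = None,
) -> int:
    """Reading-frame label of an ORF relative to a mother gene.

    Parameters
    ----------
    mother:
        The annotated mother gene (defines frame +1 on its own strand).
    orf_start:
        Leftmost (5'-most on the forward strand) genomic coordinate of the
        ORF.
    orf_strand:
        Strand of the ORF.
    orf_end:
        Optional right coordinate; when provided, a non-overlapping pair
        raises :class:`FrameError`.

    Returns one of +1, +2, +3 (same strand) or -1, -2, -3 (antisense).
    Invariant under translation of all coordinates by a constant.
    """
    if orf_strand not in ("+", "-"):
        raise ValueError("orf_strand must be '+' or '-'")
    if orf_end is not None and (orf_end <= mother.start or orf_start >= mother.end):
        raise FrameError(
            f"ORF [{orf_start}, {orf_end}) does not overlap mother "
            f"[{mother.start}, {mother.end})"
        )
    p = (orf_start - mother.start) % 3
    if orf_strand == mother.strand:
        return (1, 2, 3)[p]
    return (-3, -2, -1)[p]


def _scan_strand_orfs(
    seq: str,
    start_codons: Sequence[str],
    table: int,
) -> list[tuple[int, int]]:
    """All (start, end) ORFs on the given sequence, in its own coordinates.

    An ORF begins at an allowed start codon and ends at the first in-frame
    stop (stop codon included in the interval).  Nested ORFs sharing a stop
    are all reported.
    """
    stops = _stop_codons(table)
    starts = set(start_codons)
    orfs: list[tuple[int, int]] = []
    n = len(seq)
    for phase in range(3):
        open_starts: list[int] = []
        for pos in range(phase, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in stops:
                for s in open_starts:
                    orfs.append((s, pos + 3))
                open_starts = []
            elif codon in starts:
                open_starts.append(pos)
        # ORFs without an in-frame stop before the sequence edge are dropped
    return orfs


def enumerate_embedded_orfs(
    record: GenomeRecord,
    mother: GeneAnnotation,
    min_aa_len: int = 20,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    frames: Iterable[int] = ANTISENSE_FRAMES,
    table: int = 11,
) -> list[EmbeddedOrf]:
    """Enumerate ORFs overlapping a mother gene in the requested frames.

    Every returned ORF begins with an allowed start codon, ends at its first
    in-frame stop, overlaps the mother gene by >= 1 bp, encodes at least
    ``min_aa_len`` amino acids (stop excluded), and carries one of the
    requested relative-frame labels.  Results are sorted by genomic start and
    are deterministic.
    """
    frames = tuple(frames)
    if not frames:
        raise ConfigError("frames list must not be empty")
    for f in frames:
        if f not in ALL_FRAMES:
            raise ConfigError(f"unknown frame label {f}")
    if not start_codons:
        raise ConfigError("start_codons must not be empty")
    mother.validate_against(record)

    need_same = any(f > 0 for f in frames)
    need_anti = any(f < 0 for f in frames)
    strands: list[str] = []
    other = "-" if mother.strand == "+" else "+"
    if need_same:
        strands.append(mother.strand)
    if need_anti:
        strands.append(other)

    n = len(record)
    results: list[EmbeddedOrf] = []
    for strand in strands:
        seq = record.seq if strand == "+" else revcomp(record.seq)
        for s_local, e_local in _scan_strand_orfs(seq, start_codons, table):
            if strand == "+":
                start, end = s_local, e_local
            else:
                start, end = n - e_local, n - s_local
            ov = min(end, mother.end) - max(start, mother.start)
            if ov < 1:
                continue
            label = relative_frame(mother, start, strand)
            if label not in frames:
                continue
            aa_len = (end - start) // 3 - 1
            if aa_len < min_aa_len:
                continue
            nt = seq[s_local:e_local]
            results.append(
                EmbeddedOrf(
                    orf_id=f"{record.id}:{start}-{end}({strand})",
                    mother_gene_id=mother.gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    relative_frame=label,
                    nt_seq=nt,
                    aa_seq=translate(nt, table)[:-1],
                    overlap_bp=ov,
                    table=table,
                )
            )
    results.sort(key=lambda o: (o.start, o.end, o.strand))
    return results
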