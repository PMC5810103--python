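"""Quantification of transcription/translation and the translated-ORF classifier.

Strand-specific RNAseq (transcriptome) and RIBOseq (translatome, ribosomal
footprints) alignments are summarized per ORF as RPKM, ORF coverage, and the
ribosomal coverage value (RCV) -- translatome RPKM divided by transcriptome
RPKM, a translatability statistic.  An ORF is called translated when, in
every biological replicate,

(i)   its RIBOseq RPKM is at least 1 (one read per million mapped reads,
      normalized to 1 kbp),
(ii)  at least 50% of its positions are covered by RIBOseq reads, and
(iii) its RCV is at least 0.25.

Criterion (i) is applied to the RIBOseq library by default (it is a
translation-detection filter); a stricter mode requires it of both
libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .seqcore import EmbeddedOrf

__all__ = [
    "Read",
    "AlignmentSet",
    "ExpressionProfile",
    "TranslatabilityThresholds",
    "TranslationCall",
    "rpkm",
    "count_reads",
    "coverage_fraction",
    "rcv",
    "profile_orf",
    "classify_translated",
    "summary_table",
]

CRITERIA = ("ribo_rpkm", "coverage", "rcv")


class Read(NamedTuple):
    """A mapped read interval: 0-based half-open, strand-aware."""

    record_id: str
    start: int
    end: int
    strand: str


@dataclass
class AlignmentSet:
    """Strand-specific mapped reads for one library/replicate/condition.

    ``total_mapped`` is the library's total mapped read count and may exceed
    ``len(reads)`` when only a genomic region of interest was extracted.
    """

    library: str  # "RNA" | "RIBO"
    replicate: int
    condition: str
    reads: list[Read]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.library not in ("RNA", "RIBO"):
            raise ValueError(f"unknown library type {self.library!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.total_mapped < len(self.reads):
            raise ValueError("total_mapped smaller than number of reads")


@dataclass
class ExpressionProfile:
    """Per-ORF, per-replicate expression summary."""

    orf_id: str
    condition: str
    replicate: int
    rpkm_rna: float
    rpkm_ribo: float
    coverage_fraction: float
    rcv: float | None  # None when RNA RPKM is zero (undefined, never +inf)


@dataclass
class TranslatabilityThresholds:
    min_ribo_rpkm: float = 1.0
    min_coverage: float = 0.5
    min_rcv: float = 0.25
    require_all_replicates: bool = True
    rpkm_floor_on_both_libraries: bool = False

    def __post_init__(self) -> None:
        if min(self.min_ribo_rpkm, self.min_coverage, self.min_rcv) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class TranslationCall:
    """Classifier verdict with per-replicate, per-criterion booleans."""

    orf_id: str
    condition: str
    translated: bool
    by_replicate: dict[int, dict[str, bool]] = field(default_factory=dict)

    @property
    def failed_criteria(self) -> list[str]:
        failed = []
        for name in CRITERIA:
            if any(not flags[name] for flags in self.by_replicate.values()):
                failed.append(name)
        return failed


def rpkm(count: int, orf_len_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads.

    RPKM = count * 1e9 / (orf_len_bp * total_mapped).  Scale-invariant:
    doubling both count and total_mapped leaves it unchanged.
    """
    if orf_len_bp <= 0:
        raise ValueError("orf_len_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e9 / (orf_len_bp * total_mapped)


def _read_matches(read: Read, orf: EmbeddedOrf, mode: str) -> bool:
    if read.strand != orf.strand:
        return False
    if mode == "overlap_any":
        return min(read.end, orf.end) - max(read.start, orf.start) >= 1
    if mode == "within":
        return read.start >= orf.start and read.end <= orf.end
    raise ValueError(f"unknown counting mode {mode!r}")


def count_reads(aln: AlignmentSet, orf: EmbeddedOrf, mode: str = "overlap_any") -> int:
    """Strand-specific read count for an ORF.

    ``overlap_any`` counts a read if it overlaps the ORF by >= 1 bp;
    ``within`` requires full containment.  Reads on the opposite strand
    never count.
    """
    if mode not in ("overlap_any", "within"):
        raise ValueError(f"unknown counting mode {mode!r}")
    record_id = orf.orf_id.split(":")[0]
    return sum(
        1
        for r in aln.reads
        if r.record_id == record_id and _read_matches(r, orf, mode)
    )


def coverage_fraction(aln: AlignmentSet, orf: EmbeddedOrf) -> float:
    """Fraction of ORF positions overlapped by >= 1 same-strand read."""
    record_id = orf.orf_id.split(":")[0]
    covered = np.zeros(len(orf), dtype=bool)
    for r in aln.reads:
        if r.record_id != record_id or r.strand != orf.strand:
            continue
        lo = max(r.start, orf.start) - orf.start
        hi = min(r.end, orf.end) - orf.start
        if hi > lo:
            covered[lo:hi] = True
    return float(covered.mean())


def rcv(rpkm_ribo: float, rpkm_rna: float) -> float | None:
    """Ribosomal coverage value: translatome RPKM over transcriptome RPKM.

    Returns ``None`` (undefined) when the transcriptome RPKM is zero; the
    undefined case fails the classifier's RCV criterion by definition.
    """
    if rpkm_ribo < 0 or rpkm_rna < 0:
        raise ValueError("RPKM inputs must be non-negative")
    if rpkm_rna == 0:
        return None
    return rpkm_ribo / rpkm_rna


def profile_orf(
    orf: EmbeddedOrf,
    rna: AlignmentSet,
    ribo: AlignmentSet,
    mode: str = "overlap_any",
) -> ExpressionProfile:
    """Build the per-replicate expression profile of one ORF."""
    if rna.replicate != ribo.replicate or rna.condition != ribo.condition:
        raise ValueError("RNA and RIBO alignment sets must be paired")
    r_rna = rpkm(count_reads(rna, orf, mode), len(orf), rna.total_mapped)
    r_ribo = rpkm(count_reads(ribo, orf, mode), len(orf), ribo.total_mapped)
    return ExpressionProfile(
        orf_id=orf.orf_id,
        condition=rna.condition,
        replicate=rna.replicate,
        rpkm_rna=r_rna,
        rpkm_ribo=r_ribo,
        coverage_fraction=coverage_fraction(ribo, orf),
        rcv=rcv(r_ribo, r_rna),
    )


def classify_translated(
    profiles: Sequence[ExpressionProfile],
    thr: TranslatabilityThresholds | None = None,
) -> TranslationCall:
    """Apply the three-criterion translated-ORF classifier.

    ``profiles`` are the replicates of one ORF under one condition.  The ORF
    is called translated iff every replicate passes all three criteria (when
    ``require_all_replicates``; otherwise one fully passing replicate
    suffices).
    """
    if not profiles:
        raise ValueError("at least one replicate profile is required")
    ids = {(p.orf_id, p.condition) for p in profiles}
    if len(ids) > 1:
        raise ValueError("profiles must belong to a single ORF and condition")
    thr = thr or TranslatabilityThresholds()

    by_rep: dict[int, dict[str, bool]] = {}
    for p in profiles:
        floor_ok = p.rpkm_ribo >= thr.min_ribo_rpkm
        if thr.rpkm_floor_on_both_libraries:
            floor_ok = floor_ok and p.rpkm_rna >= thr.min_ribo_rpkm
        by_rep[p.replicate] = {
            "ribo_rpkm": floor_ok,
            "coverage": p.coverage_fraction >= thr.min_coverage,
            "rcv": p.rcv is not None and p.rcv >= thr.min_rcv,
        }
    rep_pass = [all(flags.values()) for flags in by_rep.values()]
    translated = all(rep_pass) if thr.require_all_replicates else any(rep_pass)
    orf_id, condition = next(iter(ids))
    return TranslationCall(
        orf_id=orf_id,
        condition=condition,
        translated=translated,
        by_replicate=by_rep,
    )


def _round_rpkm(x: float) -> float:
    return round(x, 1)


def summary_table(profiles: Iterable[ExpressionProfile]):
    """Mean-of-replicates expression table, one row per ORF x condition.

    Columns mirror the conventional reporting layout: transcriptome RPKM,
    translatome RPKM, RCV and ORF coverage, as means over biological
    replicates.  The RCV column is the mean of per-replicate RCVs (not the
    ratio of mean RPKMs).  RPKM is rounded to 1 decimal, RCV and coverage to
    2; full precision stays with the per-replicate profiles.
    """
    import pandas as pd

    rows: dict[tuple[str, str], list[ExpressionProfile]] = {}
    for p in profiles:
        rows.setdefault((p.orf_id, p.condition), []).append(p)
    out = []
    for (orf_id, condition), ps in rows.items():
        rcvs = [p.rcv for p in ps if p.rcv is not None]
        out.append(
            {
                "orf_id": orf_id,
                "condition": condition,
                "rpkm_transcriptome": _round_rpkm(
                    float(np.mean([p.rpkm_rna for p in ps]))
                ),
                "rpkm_translatome": _round_rpkm(
                    float(np.mean([p.rpkm_ribo for p in ps]))
                ),
                "rcv": round(float(np.mean(rcvs)), 2) if rcvs else math.nan,
                "orf_coverage": round(
                    float(np.mean([p.coverage_fraction for p in ps])), 2
                ),
                "n_replicates": len(ps),
            }
        )
    return pd.DataFrame(out)
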