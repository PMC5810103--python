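"""Continuity of an overlapping reading frame across homologs, and the origin
stratum of the young gene on a species tree.

For every homolog of the mother gene, the region aligning to the reference
overlapping ORF is extracted from a global pairwise nucleotide alignment and
classified:

``disrupted_frameshift``
    an indel whose length is not a multiple of 3 falls inside the ORF;
``disrupted_stop``
    the frame is intact but contains an internal stop codon;
``divergent``
    frame intact and stop-free, but the encoded peptide is shorter than
    ``min_len`` or less than ``min_ident`` identical to the reference;
``continuous``
    none of the above;
``missing``
    the homolog does not align over (most of) the ORF region.

The precedence frameshift > stop > divergent > continuous is a documented
choice; stop and indel counts are always reported so alternative rules can
be re-derived.  The minimum intact length (41 aa) and identity gate (0.5)
default to the fragment/identity rules used for the archetypal antisense
overlapping gene and are configurable.

The origin stratum is the most recent common ancestor (MRCA) of all tips
carrying a continuous ORF; tips inside that clade whose ORF is disrupted
are flagged as inconsistent with a single origin (loss or homoplasy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
from Bio import Align

from .seqcore import revcomp, translate

__all__ = [
    "HomologSet",
    "ContinuityCall",
    "OriginStratum",
    "make_aligner",
    "align_pair",
    "project_orf",
    "classify_continuity",
    "classify_homolog_set",
    "origin_stratum",
]

STATUSES = (
    "continuous",
    "disrupted_stop",
    "disrupted_frameshift",
    "divergent",
    "missing",
)


@dataclass
class HomologSet:
    """Reference overlap region plus homolog sequences in mother orientation."""

    ref_seq: str
    orf_start: int
    orf_end: int
    orf_strand: str
    homologs: dict[str, str]

    def __post_init__(self) -> None:
        if not (0 <= self.orf_start < self.orf_end <= len(self.ref_seq)):
            raise ValueError("ORF interval outside reference sequence")
        if (self.orf_end - self.orf_start) % 3:
            raise ValueError("ORF length must be divisible by 3")
        if len(set(self.homologs)) != len(self.homologs):
            raise ValueError("homolog taxa must be unique")
        for taxon, seq in self.homologs.items():
            if not seq:
                raise ValueError(f"empty sequence for {taxon}")

    @property
    def ref_orf_nt(self) -> str:
        sub = self.ref_seq[self.orf_start : self.orf_end]
        return revcomp(sub) if self.orf_strand == "-" else sub

    @property
    def ref_peptide(self) -> str:
        return translate(self.ref_orf_nt)[:-1]


@dataclass
class ContinuityCall:
    taxon: str
    status: str
    n_internal_stops: int
    net_indel_mod3: int
    aa_identity_to_reference: float
    aa_len: int

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def make_aligner(
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -24.0,
    gap_extend: float = -0.5,
) -> Align.PairwiseAligner:
    """Global nucleotide aligner with affine gaps (Needle-style scoring).

    The default gap-opening penalty is stiffer than the classic EDNAFULL
    setting: at the ~10% nucleotide divergence typical between related
    genera, cheap gap openings occasionally produce compensating gap pairs
    that mimic frameshifts inside the ORF window, which would corrupt
    continuity classification.  Substitution-only divergence should be
    explained by mismatches, so gaps are reserved for genuine indels.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(
    ref_seq: str,
    homolog_seq: str,
    aligner: Align.PairwiseAligner | None = None,
) -> Align.Alignment:
    """Global pairwise alignment of two nucleotide sequences.

    Deterministic: for equal-scoring alignments the aligner's canonical
    first traceback is used (leftmost gap placement).
    """
    if not ref_seq or not homolog_seq:
        raise ValueError("sequences must be non-empty")
    aligner = aligner or make_aligner()
    return aligner.align(ref_seq, homolog_seq)[0]


def project_orf(
    alignment: Align.Alignment,
    orf_start: int,
    orf_end: int,
) -> tuple[str, list[int]]:
    """Homolog bases aligned to a reference interval, plus an indel ledger.

    Returns the gap-free homolog subsequence aligned to reference positions
    ``[orf_start, orf_end)`` and a list of signed indel lengths inside the
    interval (+k insertion relative to the reference, -k deletion).  Indels
    outside the interval are ignored; insertions at the interval boundaries
    are not counted as inside.
    """
    ref_row = alignment[0]
    hom_row = alignment[1]
    seg: list[str] = []
    ledger: list[int] = []
    ref_pos = 0  # reference coordinate of the next reference base
    run_ins = 0
    run_del = 0
    for rc, hc in zip(ref_row, hom_row):
        inside = orf_start <= ref_pos < orf_end
        if rc == "-":
            # insertion in homolog; attribute to current ref_pos, counted
            # only strictly inside the interval
            if orf_start < ref_pos < orf_end and hc != "-":
                run_ins += 1
                seg.append(hc)
            continue
        if run_ins:
            ledger.append(run_ins)
            run_ins = 0
        if inside:
            if hc == "-":
                run_del += 1
            else:
                if run_del:
                    ledger.append(-run_del)
                    run_del = 0
                seg.append(hc)
        ref_pos += 1
        if ref_pos == orf_end:
            break
    if run_ins:
        ledger.append(run_ins)
    if run_del:
        ledger.append(-run_del)
    return "".join(seg), ledger


def _aa_identity(a: str, b: str) -> float:
    """Fraction of identical residues over a global AA alignment.

    Identities are divided by the longer sequence length, so trailing
    truncation lowers identity.
    """
    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    ident = sum(x == y and x != "-" for x, y in zip(aln[0], aln[1]))
    return ident / max(len(a), len(b))


def classify_continuity(
    segment: str,
    indel_ledger: Sequence[int],
    ref_peptide: str,
    taxon: str = "",
    orf_strand: str = "-",
    min_len: int = 41,
    min_ident: float = 0.5,
    min_segment_fraction: float = 0.5,
) -> ContinuityCall:
    """Classify one homolog's overlapping-frame segment.

    ``segment`` and ``indel_ledger`` come from :func:`project_orf`;
    ``ref_peptide`` is the reference ORF's protein (stop excluded).  The
    reference classified against itself is always continuous with identity
    1.0.
    """
    ref_nt_len = 3 * (len(ref_peptide) + 1)
    net = sum(indel_ledger)
    net_mod3 = net % 3

    if len(segment) < min_segment_fraction * ref_nt_len:
        return ContinuityCall(taxon, "missing", 0, net_mod3, 0.0, 0)

    coding = revcomp(segment) if orf_strand == "-" else segment
    pep_full = translate(coding[: len(coding) - len(coding) % 3])
    aa_seq = pep_full[:-1] if pep_full.endswith("*") else pep_full
    n_internal = pep_full[:-1].count("*")
    ident = _aa_identity(ref_peptide, aa_seq.split("*")[0])
    aa_len = len(aa_seq.split("*")[0])

    if any(l % 3 for l in indel_ledger) or net_mod3:
        status = "disrupted_frameshift"
    elif n_internal > 0:
        status = "disrupted_stop"
    elif aa_len < min_len or ident < min_ident:
        status = "divergent"
    else:
        status = "continuous"
    return ContinuityCall(taxon, status, n_internal, net_mod3, ident, aa_len)


def classify_homolog_set(
    hset: HomologSet,
    aligner: Align.PairwiseAligner | None = None,
    min_len: int = 41,
    min_ident: float = 0.5,
) -> list[ContinuityCall]:
    """Align every homolog to the reference and classify ORF continuity."""
    aligner = aligner or make_aligner()
    ref_pep = hset.ref_peptide
    calls = []
    for taxon in sorted(hset.homologs):
        aln = align_pair(hset.ref_seq, hset.homologs[taxon], aligner)
        segment, ledger = project_orf(aln, hset.orf_start, hset.orf_end)
        calls.append(
            classify_continuity(
                segment,
                ledger,
                ref_pep,
                taxon=taxon,
                orf_strand=hset.orf_strand,
                min_len=min_len,
                min_ident=min_ident,
            )
        )
    return calls


@dataclass
class OriginStratum:
    """MRCA clade of continuous tips, with single-origin consistency flags."""

    clade_taxa: tuple[str, ...]
    continuous_taxa: tuple[str, ...]
    inconsistent_taxa: tuple[str, ...]  # non-continuous tips inside the clade


def origin_stratum(
    tree: dendropy.Tree | str,
    calls: Sequence[ContinuityCall] | Mapping[str, str],
) -> OriginStratum:
    """Place the origin of the overlapping gene on a species tree.

    ``calls`` maps tree tip labels to continuity status (a list of
    :class:`ContinuityCall` is accepted).  Returns the tip set of the MRCA
    of all continuous taxa, plus the tips inside that clade that are not
    continuous (candidate secondary losses).  All call taxa must be on the
    tree; with no continuous taxon the clade is empty.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(
            data=tree, schema="newick", preserve_underscores=True
        )
    if isinstance(calls, Mapping):
        status_by_taxon = dict(calls)
    else:
        status_by_taxon = {c.taxon: c.status for c in calls}

    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(status_by_taxon) - tip_labels
    if unknown:
        raise ValueError(f"call taxa not on tree: {sorted(unknown)}")

    continuous = tuple(
        sorted(t for t, s in status_by_taxon.items() if s == "continuous")
    )
    if not continuous:
        return OriginStratum((), (), ())
    if len(continuous) == 1:
        return OriginStratum(continuous, continuous, ())
    tree.is_rooted = True
    mrca = tree.mrca(taxon_labels=list(continuous))
    clade = tuple(sorted(leaf.taxon.label for leaf in mrca.leaf_iter()))
    inconsistent = tuple(
        t
        for t in clade
        if status_by_taxon.get(t, "missing") != "continuous"
    )
    return OriginStratum(clade, continuous, inconsistent)
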