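"""Design of strand-specific translational-arrest mutants of overlapping genes.

Given a region containing an antisense overlapping ORF, find minimal sets of
point mutations that introduce a premature stop codon early in the target
(overlapping) frame while leaving the partner (mother-gene) protein sequence
unchanged over the whole region.  Plans are additionally annotated with
restriction sites lost or gained, which supports digest-based screening of
mutant clones (the canonical screen uses MnlI site loss).

Search semantics, shared with the brute-force oracle used in the test suite:
mutations are restricted to codons 2..``max_codon`` of the target frame (the
start codon is excluded -- arrest is via a premature stop, not start-codon
loss), and a plan is valid iff the partner translation of the whole region
is unchanged and the first stop-codon index in the window after mutation is
strictly earlier than in the wild type.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field

import yaml
from Bio.Data.IUPACData import ambiguous_dna_values

from .seqcore import EmbeddedOrf, GeneAnnotation, GenomeRecord, revcomp, translate

__all__ = [
    "OverlapPair",
    "Mutation",
    "MutationPlan",
    "RestrictionSite",
    "apply_mutations",
    "design_arrest",
    "find_sites",
    "restriction_diff",
    "default_enzymes",
]

BASES = "ACGT"


class IntegrityError(ValueError):
    """A mutation's reference base does not match the sequence."""


def default_enzymes() -> dict[str, str]:
    """Built-in enzyme catalog: name -> IUPAC recognition sequence."""
    ref = importlib.resources.files("olgkit.data").joinpath("enzymes.yaml")
    return dict(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class Mutation:
    position: int
    ref_base: str
    alt_base: str


@dataclass(frozen=True)
class RestrictionSite:
    enzyme: str
    recognition: str
    position: int
    strand: str


@dataclass
class OverlapPair:
    """An overlap region in mother-gene orientation plus the target ORF.

    ``mother_phase`` is the offset (0-2) within ``region_seq`` at which the
    first complete mother codon begins.  ``target_start``/``target_end`` are
    region-local half-open coordinates of the target (overlapping) ORF,
    whose coding strand is ``target_strand``.
    """

    region_seq: str
    mother_phase: int = 0
    target_start: int = 0
    target_end: int | None = None
    target_strand: str = "-"
    region_start: int = 0  # genomic coordinate of region_seq[0], bookkeeping
    overlap_orf: EmbeddedOrf | None = None

    def __post_init__(self) -> None:
        if self.target_end is None:
            self.target_end = len(self.region_seq)
        if not 0 <= self.mother_phase <= 2:
            raise ValueError("mother_phase must be in 0..2")
        if not (0 <= self.target_start < self.target_end <= len(self.region_seq)):
            raise ValueError("target ORF outside region")
        if (self.target_end - self.target_start) % 3:
            raise ValueError("target ORF length must be divisible by 3")
        if self.target_strand not in ("+", "-"):
            raise ValueError("target_strand must be '+' or '-'")

    @classmethod
    def from_genome(
        cls,
        record: GenomeRecord,
        mother: GeneAnnotation,
        orf: EmbeddedOrf,
        pad: int = 0,
    ) -> "OverlapPair":
        """Cut the ORF's region (plus padding) out of a genome.

        The region is kept in mother-gene orientation; for a forward-strand
        mother this is the forward strand.
        """
        if mother.strand != "+":
            raise NotImplementedError(
                "regions are extracted for forward-strand mother genes; "
                "reverse-complement the record first"
            )
        lo = max(0, orf.start - pad)
        hi = min(len(record), orf.end + pad)
        phase = (3 - (lo - mother.start) % 3) % 3
        return cls(
            region_seq=record.seq[lo:hi],
            mother_phase=phase,
            target_start=orf.start - lo,
            target_end=orf.end - lo,
            target_strand=orf.strand,
            region_start=lo,
            overlap_orf=orf,
        )


@dataclass
class MutationPlan:
    """A verified arrest plan: mutations, consequences, screening sites."""

    mutations: tuple[Mutation, ...]
    target_stop_codon_index: int  # 1-based codon number in the target frame
    partner_codon_changes: tuple[tuple[int, str, str], ...]  # (codon, before, after)
    sites_lost: tuple[RestrictionSite, ...] = field(default_factory=tuple)
    sites_gained: tuple[RestrictionSite, ...] = field(default_factory=tuple)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


def apply_mutations(seq: str, mutations: tuple[Mutation, ...] | list[Mutation]) -> str:
    """Apply point substitutions; reference bases are verified first."""
    out = list(seq)
    seen: set[int] = set()
    for m in mutations:
        if m.position in seen:
            raise ValueError(f"duplicate mutation position {m.position}")
        seen.add(m.position)
        if not 0 <= m.position < len(seq):
            raise ValueError(f"mutation position {m.position} outside sequence")
        if seq[m.position] != m.ref_base:
            raise IntegrityError(
                f"position {m.position}: expected {m.ref_base}, found {seq[m.position]}"
            )
        out[m.position] = m.alt_base
    return "".join(out)


def _target_nt(pair: OverlapPair, region: str) -> str:
    sub = region[pair.target_start : pair.target_end]
    return revcomp(sub) if pair.target_strand == "-" else sub


def _target_pos_to_region(pair: OverlapPair, q: int) -> int:
    """Map an index in the target coding sequence to a region coordinate."""
    if pair.target_strand == "-":
        return pair.target_end - 1 - q
    return pair.target_start + q


def _first_stop_index(target_nt: str, max_codon: int, table: int = 11) -> int | None:
    """1-based index of the first stop among codons 2..max_codon, else None."""
    n_codons = len(target_nt) // 3
    aa = translate(target_nt[: 3 * min(max_codon, n_codons)], table)
    for j in range(1, len(aa)):  # skip codon 1 (start)
        if aa[j] == "*":
            return j + 1
    return None


def _mother_codon_starts(pair: OverlapPair) -> list[int]:
    starts = []
    p = pair.mother_phase
    while p + 3 <= len(pair.region_seq):
        starts.append(p)
        p += 3
    return starts


def _partner_translation(pair: OverlapPair, region: str, table: int = 11) -> str:
    starts = _mother_codon_starts(pair)
    return "".join(translate(region[s : s + 3], table) for s in starts)


def design_arrest(
    pair: OverlapPair,
    max_codon: int = 10,
    max_mutations: int = 3,
    require_contiguous: bool = False,
    enzymes: dict[str, str] | None = None,
    table: int = 11,
) -> list[MutationPlan]:
    """Exhaustively enumerate verified translational-arrest plans.

    Returns every substitution set of size 1..``max_mutations`` within
    codons 2..``max_codon`` of the target frame that creates a premature
    stop while preserving the partner protein over the entire region,
    ranked by (stop codon index, mutation count, positions).  The search is
    exhaustive for ``max_mutations`` <= 4; enumeration is pruned to
    partner-synonymous edits per mother codon, which is equivalent because
    partner preservation decomposes by codon.  Every plan is re-verified by
    translating both frames of the mutated region.
    """
    if max_mutations > 4:
        raise ValueError("exhaustive search supports max_mutations <= 4")
    if max_mutations < 1:
        raise ValueError("max_mutations must be >= 1")
    region = pair.region_seq
    target_wt = _target_nt(pair, region)
    n_codons = len(target_wt) // 3
    if n_codons < 1:
        raise ValueError("overlap shorter than one codon")
    max_codon = min(max_codon, n_codons)
    if max_codon < 2:
        raise ValueError("target frame too short for a premature stop")
    enzymes = enzymes if enzymes is not None else default_enzymes()

    wt_stop = _first_stop_index(target_wt, max_codon, table)
    wt_partner = _partner_translation(pair, region, table)

    # Region positions eligible for mutation: bases of target codons 2..max_codon.
    window = {
        _target_pos_to_region(pair, q) for q in range(3, 3 * max_codon)
    }

    # Group eligible positions by the mother codon containing them; only
    # complete mother codons may be edited (a straddling partial codon cannot
    # be verified for synonymy).
    codon_starts = _mother_codon_starts(pair)
    mutable_by_codon: dict[int, list[int]] = {}
    pos_to_codon: dict[int, int] = {}
    for ci, cs in enumerate(codon_starts):
        for p in (cs, cs + 1, cs + 2):
            pos_to_codon[p] = ci
    for p in sorted(window):
        if p in pos_to_codon:
            mutable_by_codon.setdefault(pos_to_codon[p], []).append(p)

    # Per mother codon: all non-empty substitution combos preserving its AA.
    combos_by_codon: dict[int, list[tuple[Mutation, ...]]] = {}
    for ci, positions in mutable_by_codon.items():
        cs = codon_starts[ci]
        wt_codon = region[cs : cs + 3]
        aa = translate(wt_codon, table)
        combos: list[tuple[Mutation, ...]] = []
        for r in range(1, min(len(positions), max_mutations) + 1):
            for pos_set in itertools.combinations(positions, r):
                for alts in itertools.product(BASES, repeat=r):
                    if any(region[p] == a for p, a in zip(pos_set, alts)):
                        continue
                    codon = list(wt_codon)
                    for p, a in zip(pos_set, alts):
                        codon[p - cs] = a
                    if translate("".join(codon), table) != aa:
                        continue
                    combos.append(
                        tuple(
                            Mutation(p, region[p], a)
                            for p, a in zip(pos_set, alts)
                        )
                    )
        if combos:
            combos_by_codon[ci] = combos

    plans: list[MutationPlan] = []
    codon_ids = sorted(combos_by_codon)
    for n_codons_used in range(1, max_mutations + 1):
        for codon_subset in itertools.combinations(codon_ids, n_codons_used):
            for combo_choice in itertools.product(
                *(combos_by_codon[ci] for ci in codon_subset)
            ):
                muts = tuple(
                    sorted(itertools.chain(*combo_choice), key=lambda m: m.position)
                )
                if len(muts) > max_mutations:
                    continue
                if require_contiguous and len(muts) > 1:
                    span = [m.position for m in muts]
                    if span[-1] - span[0] != len(span) - 1:
                        continue
                mut_region = apply_mutations(region, muts)
                stop_idx = _first_stop_index(
                    _target_nt(pair, mut_region), max_codon, table
                )
                if stop_idx is None or (wt_stop is not None and stop_idx >= wt_stop):
                    continue
                # belt-and-braces: re-translate the partner frame in full
                if _partner_translation(pair, mut_region, table) != wt_partner:
                    continue
                changes = []
                for ci in codon_subset:
                    cs = codon_starts[ci]
                    before = translate(region[cs : cs + 3], table)
                    after = translate(mut_region[cs : cs + 3], table)
                    changes.append((ci, before, after))
                lost, gained = restriction_diff(region, mut_region, enzymes)
                plans.append(
                    MutationPlan(
                        mutations=muts,
                        target_stop_codon_index=stop_idx,
                        partner_codon_changes=tuple(changes),
                        sites_lost=tuple(lost),
                        sites_gained=tuple(gained),
                    )
                )
    plans.sort(
        key=lambda pl: (
            pl.target_stop_codon_index,
            pl.n_mutations,
            tuple(m.position for m in pl.mutations),
            tuple(m.alt_base for m in pl.mutations),
        )
    )
    return plans


# ---------------------------------------------------------------------------
# restriction sites


def _motif_matches(seq: str, pos: int, motif: str) -> bool:
    if pos + len(motif) > len(seq):
        return False
    return all(
        seq[pos + i] in ambiguous_dna_values.get(c, c)
        for i, c in enumerate(motif)
    )


def find_sites(seq: str, enzymes: dict[str, str] | None = None) -> list[RestrictionSite]:
    """All recognition-site matches on both strands.

    Positions refer to the forward strand; a minus-strand site is reported
    at the forward-strand position of the reverse-complemented motif match.
    """
    enzymes = enzymes if enzymes is not None else default_enzymes()
    sites: list[RestrictionSite] = []
    for name, motif in sorted(enzymes.items()):
        rc = revcomp(motif)
        for pos in range(len(seq) - len(motif) + 1):
            if _motif_matches(seq, pos, motif):
                sites.append(RestrictionSite(name, motif, pos, "+"))
            if rc != motif and _motif_matches(seq, pos, rc):
                sites.append(RestrictionSite(name, motif, pos, "-"))
    sites.sort(key=lambda s: (s.position, s.enzyme, s.strand))
    return sites


def restriction_diff(
    wt_seq: str,
    mut_seq: str,
    enzymes: dict[str, str] | None = None,
) -> tuple[list[RestrictionSite], list[RestrictionSite]]:
    """Sites lost and gained between equal-length wild-type/mutant sequences."""
    if len(wt_seq) != len(mut_seq):
        raise ValueError("sequences must have equal length")
    wt = set(find_sites(wt_seq, enzymes))
    mut = set(find_sites(mut_seq, enzymes))
    lost = sorted(wt - mut, key=lambda s: (s.position, s.enzyme, s.strand))
    gained = sorted(mut - wt, key=lambda s: (s.position, s.enzyme, s.strand))
    return lost, gained
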