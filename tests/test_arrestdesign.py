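"""Translational-arrest mutant design and restriction screening."""

import itertools

import numpy as np
import pytest

from olgkit.arrestdesign import (
    IntegrityError,
    Mutation,
    OverlapPair,
    apply_mutations,
    design_arrest,
    find_sites,
    restriction_diff,
)
from olgkit.seqcore import revcomp, translate

BASES = "ACGT"


def oracle_plans(region, max_codon=10, kmax=3):
    """Naive enumeration over every substitution set in the mutation window.

    Independent of the implementation: checks partner preservation by full
    re-translation and finds the first stop index by scanning the mutated
    target frame.  Target = whole region on the minus strand, frame 0;
    mother frame 0 on the plus strand.
    """
    n = len(region)

    def first_stop(tnt):
        aa = translate(tnt[: 3 * min(max_codon, len(tnt) // 3)])
        for j in range(1, len(aa)):
            if aa[j] == "*":
                return j + 1
        return None

    wt_stop = first_stop(revcomp(region))
    wt_partner = translate(region[: (n // 3) * 3])
    window = sorted({n - 1 - q for q in range(3, 3 * min(max_codon, n // 3))})
    found = set()
    for r in range(1, kmax + 1):
        for pos in itertools.combinations(window, r):
            for alts in itertools.product(BASES, repeat=r):
                if any(region[p] == a for p, a in zip(pos, alts)):
                    continue
                chars = list(region)
                for p, a in zip(pos, alts):
                    chars[p] = a
                mut = "".join(chars)
                if translate(mut[: (n // 3) * 3]) != wt_partner:
                    continue
                si = first_stop(revcomp(mut))
                if si is None or (wt_stop is not None and si >= wt_stop):
                    continue
                found.add(frozenset(zip(pos, alts)))
    return found


def plan_keys(plans):
    return {frozenset((m.position, m.alt_base) for m in p.mutations) for p in plans}


class TestApplyMutations:
    def test_empty_plan_is_identity(self):
        assert apply_mutations("ACGT", []) == "ACGT"

    def test_round_trip_with_inverse(self):
        m = Mutation(2, "G", "T")
        inv = Mutation(2, "T", "G")
        assert apply_mutations(apply_mutations("ACGT", [m]), [inv]) == "ACGT"

    def test_three_adjacent_substitutions(self):
        muts = [Mutation(3, "T", "A"), Mutation(4, "A", "C"), Mutation(5, "G", "T")]
        assert apply_mutations("ACGTAG", muts) == "ACGACT"

    def test_reference_mismatch_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            apply_mutations("ACGT", [Mutation(0, "C", "T")])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            apply_mutations("ACGT", [Mutation(0, "A", "C"), Mutation(0, "A", "G")])


class TestDesignArrest:
    def test_single_synonymous_substitution_creates_stop(self):
        # the target frame reads each mother codon in reverse complement;
        # a serine partner codon TCT edited to TCA (synonymous) flips the
        # target codon AGA -> TGA, a premature stop at codon 2
        region = "GGC" * 8 + "TCT" + "GGC"
        pair = OverlapPair(region_seq=region, mother_phase=0, target_strand="-")
        plans = design_arrest(pair, max_codon=3, max_mutations=1, enzymes={})
        assert plan_keys(plans) >= {frozenset({(26, "A")})}
        for p in plans:
            mutated = apply_mutations(region, p.mutations)
            assert translate(mutated) == translate(region)  # partner preserved
            target_aa = translate(revcomp(mutated))
            assert "*" in target_aa[1 : p.target_stop_codon_index]
        assert plans == sorted(
            plans,
            key=lambda pl: (
                pl.target_stop_codon_index,
                pl.n_mutations,
                tuple(m.position for m in pl.mutations),
                tuple(m.alt_base for m in pl.mutations),
            ),
        )

    def test_no_solution_returns_empty_list(self):
        # a region whose partner frame tolerates no stop-creating edit:
        # tryptophan (TGG) partner codons have no synonymous alternative
        region = "TGG" * 10
        pair = OverlapPair(region_seq=region, mother_phase=0, target_strand="-")
        assert design_arrest(pair, max_mutations=1, enzymes={}) == []

    def test_short_overlap_rejected(self):
        pair = OverlapPair(region_seq="ATGTAA", mother_phase=0, target_strand="-")
        with pytest.raises(ValueError):
            design_arrest(pair, max_codon=1)

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_on_random_regions(self, seed):
        rng = np.random.default_rng(seed)
        region = "".join(BASES[i] for i in rng.integers(0, 4, size=30))
        pair = OverlapPair(region_seq=region, mother_phase=0, target_strand="-")
        kmax = 2 if seed % 2 else 3
        plans = design_arrest(pair, max_mutations=kmax, enzymes={})
        assert plan_keys(plans) == oracle_plans(region, kmax=kmax)
        # soundness: every plan preserves the partner protein
        for p in plans:
            mutated = apply_mutations(region, p.mutations)
            assert translate(mutated) == translate(region)

    def test_fixture_plan_loses_mnl1_site(self, fixture, embedded_orf):
        pair = OverlapPair.from_genome(fixture.record, fixture.mother, embedded_orf)
        plans = design_arrest(pair)
        assert plans
        assert any(
            any(s.enzyme == "MnlI" for s in p.sites_lost) for p in plans
        )

    def test_serine_partner_stays_serine(self):
        # the affected partner codon encodes serine before and after
        region = "GGC" * 8 + "TCT" + "GGC"
        pair = OverlapPair(region_seq=region, mother_phase=0, target_strand="-")
        plans = design_arrest(pair, max_codon=3, max_mutations=1, enzymes={})
        assert any(
            before == "S" and after == "S"
            for p in plans
            for _, before, after in p.partner_codon_changes
        )


class TestRestriction:
    def test_identical_sequences_no_diff(self):
        lost, gained = restriction_diff("ACCTCGGA", "ACCTCGGA")
        assert lost == [] and gained == []

    def test_mnl1_site_loss(self):
        wt = "AAACCTCAAA"
        mut = "AAACTTCAAA"
        lost, gained = restriction_diff(wt, mut)
        assert any(s.enzyme == "MnlI" and s.strand == "+" for s in lost)

    def test_sites_found_on_both_strands(self):
        # GAGG is the minus-strand face of the MnlI site CCTC
        sites = find_sites("TTGAGGTT", {"MnlI": "CCTC"})
        assert [s.strand for s in sites] == ["-"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            restriction_diff("ACGT", "ACGTA")

    @pytest.mark.parametrize("seq", ["", "ACGT", "CCTCCTC", "GAGGAGG"])
    def test_self_diff_is_empty(self, seq):
        assert restriction_diff(seq, seq) == ([], [])
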