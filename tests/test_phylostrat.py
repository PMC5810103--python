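"""Pairwise alignment, ORF projection, continuity calls, origin stratum."""

import numpy as np
import pytest

from olgkit.phylostrat import (
    HomologSet,
    align_pair,
    classify_continuity,
    classify_homolog_set,
    make_aligner,
    origin_stratum,
    project_orf,
)
from olgkit.seqcore import revcomp, translate
from olgkit.synthdata import (
    DEFAULT_CONTINUOUS_CLADE,
    DEFAULT_TREE_NEWICK,
    simulate_homolog_family,
)

ALIGNER = make_aligner()


def dp_score(a, b, match=5.0, mismatch=-4.0, gap_open=-24.0, gap_extend=-0.5):
    """Exhaustive affine-gap global alignment score (Gotoh recursion)."""
    import functools

    @functools.lru_cache(maxsize=None)
    def best(i, j, state):
        # state: 0 = free, 1 = gap in b open, 2 = gap in a open
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


class TestAlignPair:
    def test_identity_alignment(self):
        aln = align_pair("ACGTACGT", "ACGTACGT", ALIGNER)
        assert str(aln[0]) == str(aln[1])
        assert aln.counts().gaps == 0

    def test_single_internal_deletion_of_three(self):
        ref = "ATGAAACCCGGGTTTTAA"
        hom = ref[:6] + ref[9:]
        aln = align_pair(ref, hom, ALIGNER)
        assert aln.counts().gaps == 3

    @pytest.mark.parametrize("seed", range(15))
    def test_score_matches_dp_oracle_on_short_strings(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=rng.integers(3, 12)))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=rng.integers(3, 12)))
        assert ALIGNER.score(a, b) == pytest.approx(dp_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACGT")


class TestProjectOrf:
    def test_no_indels_returns_equal_length_segment(self):
        ref = "AAACCCGGGTTT"
        aln = align_pair(ref, ref, ALIGNER)
        seg, ledger = project_orf(aln, 3, 9)
        assert seg == "CCCGGG"
        assert ledger == []

    def test_planted_deletion_recorded(self):
        ref = "ATGAAACCTCGTGGGTTTACGTAA"
        hom = ref[:9] + ref[11:]  # 2 bp deletion inside [6, 18)
        aln = align_pair(ref, hom, ALIGNER)
        seg, ledger = project_orf(aln, 6, 18)
        assert sum(ledger) == -2

    def test_indels_outside_interval_ignored(self):
        ref = "ATGAAACCTCGTGGGTTTACGTAA"
        hom = ref[:2] + ref[4:]  # deletion before the interval
        aln = align_pair(ref, hom, ALIGNER)
        seg, ledger = project_orf(aln, 6, 18)
        assert ledger == []
        assert seg == ref[6:18]


class TestClassifyContinuity:
    REF_NT = "ATG" + "GCT" * 40 + "TAA"  # 41-aa ORF, plus-strand convention
    REF_PEP = translate(REF_NT)[:-1]

    def test_reference_against_itself_is_continuous(self):
        call = classify_continuity(
            revcomp(self.REF_NT), [], self.REF_PEP, orf_strand="-"
        )
        assert call.status == "continuous"
        assert call.aa_identity_to_reference == 1.0
        assert call.aa_len == 41

    def test_internal_stop_detected(self):
        broken = "ATG" + "GCT" * 20 + "TAA" + "GCT" * 19 + "TAA"
        call = classify_continuity(revcomp(broken), [], self.REF_PEP, orf_strand="-")
        assert call.status == "disrupted_stop"
        assert call.n_internal_stops == 1

    def test_net_plus_one_indel_is_frameshift(self):
        call = classify_continuity(
            revcomp(self.REF_NT) + "A", [1], self.REF_PEP, orf_strand="-"
        )
        assert call.status == "disrupted_frameshift"
        assert call.net_indel_mod3 == 1

    def test_frameshift_takes_precedence_over_stop(self):
        broken = "ATG" + "GCT" * 20 + "TAA" + "GCT" * 19 + "TAA"
        call = classify_continuity(
            revcomp(broken) + "A", [1], self.REF_PEP, orf_strand="-"
        )
        assert call.status == "disrupted_frameshift"

    def test_short_fragment_is_divergent(self):
        short = "ATG" + "GCT" * 30 + "TAA"  # 31 aa < 41
        call = classify_continuity(
            revcomp(short), [-30], self.REF_PEP, orf_strand="-"
        )
        assert call.status == "divergent"

    def test_mostly_missing_segment(self):
        call = classify_continuity("GCTGCT", [], self.REF_PEP, orf_strand="-")
        assert call.status == "missing"


class TestOriginStratum:
    TREE = DEFAULT_TREE_NEWICK
    TIPS = (
        "E_coli_Sakai", "E_albertii", "E_fergusonii", "Shigella_flexneri",
        "Salmonella_enterica", "Citrobacter_rodentium",
        "Klebsiella_pneumoniae", "Enterobacter_cloacae",
    )

    def test_all_continuous_gives_root(self):
        calls = {t: "continuous" for t in self.TIPS}
        st = origin_stratum(self.TREE, calls)
        assert set(st.clade_taxa) == set(self.TIPS)
        assert st.inconsistent_taxa == ()

    def test_single_continuous_tip(self):
        calls = {t: "disrupted_stop" for t in self.TIPS}
        calls["E_albertii"] = "continuous"
        st = origin_stratum(self.TREE, calls)
        assert st.clade_taxa == ("E_albertii",)

    def test_clade_restricted_continuity(self):
        calls = {
            t: ("continuous" if t in DEFAULT_CONTINUOUS_CLADE else "disrupted_stop")
            for t in self.TIPS
        }
        st = origin_stratum(self.TREE, calls)
        assert st.clade_taxa == DEFAULT_CONTINUOUS_CLADE
        assert st.inconsistent_taxa == ()

    def test_loss_inside_clade_is_flagged(self):
        calls = {
            t: ("continuous" if t in DEFAULT_CONTINUOUS_CLADE else "disrupted_stop")
            for t in self.TIPS
        }
        calls["E_fergusonii"] = "disrupted_stop"
        st = origin_stratum(self.TREE, calls)
        assert "E_fergusonii" in st.inconsistent_taxa

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="not on tree"):
            origin_stratum(self.TREE, {"E_coli_K12": "continuous"})


class TestFamilyRecovery:
    @pytest.mark.parametrize("seed", range(3))
    def test_calls_match_planted_truth(self, fixture, seed):
        homologs, truth, tree = simulate_homolog_family(fixture, seed=500 + seed)
        mother = fixture.mother
        hset = HomologSet(
            ref_seq=fixture.record.seq[mother.start : mother.end],
            orf_start=fixture.ledger["orf"][0] - mother.start,
            orf_end=fixture.ledger["orf"][1] - mother.start,
            orf_strand="-",
            homologs=homologs,
        )
        calls = classify_homolog_set(hset)
        assert {c.taxon: c.status for c in calls} == truth
        st = origin_stratum(tree, calls)
        assert st.clade_taxa == DEFAULT_CONTINUOUS_CLADE

    def test_zero_disruption_rate_keeps_everything_continuous(self, fixture):
        _, truth, _ = simulate_homolog_family(fixture, seed=7, disruption_rate=0.0)
        assert set(truth.values()) == {"continuous"}
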