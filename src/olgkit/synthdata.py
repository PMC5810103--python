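"""Synthetic data with known ground truth for every stage of the pipeline.

The generator emulates the study system: a bacterial "mother" gene
(a 1539-bp CadC-like regulator stand-in) carrying a fully embedded antisense
ORF in relative frame -2 (41 aa), an additional weakly translated upstream
antisense ORF (61 aa), the transcript geometry measured for the antisense
operon (TSS 289 bp upstream of the start codon, transcription termination
155 bp downstream of the stop, SD element 15 bp upstream of the start), a
planted SD core (TAAGGAGG) and, optionally, an exact-consensus sigma-32
promoter with the optimal 14-bp spacer and 6 bp to the TSS.

Every generator is a pure function of its seed.  Ground-truth ledgers are
emitted alongside all outputs so downstream tests never re-derive truth from
the data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .competition import CompetitionObservation
from .regulatory import Sigma32Model, scan_sd, scan_sigma32
from .seqcore import (
    DEFAULT_START_CODONS,
    GeneAnnotation,
    GenomeRecord,
    enumerate_embedded_orfs,
    revcomp,
    translate,
)
from .translatome import AlignmentSet, Read

__all__ = [
    "FixtureSpec",
    "Fixture",
    "PRESETS",
    "DEFAULT_TREE_NEWICK",
    "DEFAULT_CONTINUOUS_CLADE",
    "make_overlap_genome",
    "simulate_reads",
    "simulate_homolog_family",
    "simulate_competition",
]

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
_NONSTOP = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)
_SAFE_INTERIOR = tuple(
    c for c in _NONSTOP if c not in DEFAULT_START_CODONS
)

SD_CORE = "TAAGGAGG"  # planted on the transcript strand; 3' end at sd_offset

# Per-condition expression targets for the three fixture genes:
# (transcriptome RPKM, RCV, RIBOseq ORF coverage).  The three conditions
# mirror rich-medium growth at 37 C (LB37, BHI37) and combined cold/osmotic
# stress (BHI_NaCl14), under which translation of the antisense pair is
# essentially switched off.
PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "LB37": {
        "overlapping": {"rna_rpkm": 29.5, "rcv": 6.83, "coverage": 0.7},
        "mother": {"rna_rpkm": 19.0, "rcv": 0.65, "coverage": 0.35},
        "putative": {"rna_rpkm": 38.3, "rcv": 0.27, "coverage": 0.51},
    },
    "BHI37": {
        "overlapping": {"rna_rpkm": 49.4, "rcv": 0.48, "coverage": 0.6},
        "mother": {"rna_rpkm": 26.9, "rcv": 0.27, "coverage": 0.45},
        "putative": {"rna_rpkm": 36.3, "rcv": 0.05, "coverage": 0.37},
    },
    "BHI_NaCl14": {
        "overlapping": {"rna_rpkm": 28.3, "rcv": 0.01, "coverage": 0.07},
        "mother": {"rna_rpkm": 10.2, "rcv": 0.07, "coverage": 0.16},
        "putative": {"rna_rpkm": 12.7, "rcv": 0.02, "coverage": 0.16},
    },
}

DEFAULT_TREE_NEWICK = (
    "(((E_coli_Sakai:0.02,(E_albertii:0.015,E_fergusonii:0.018):0.01)"
    ":0.008,Shigella_flexneri:0.014):0.05,"
    "((Salmonella_enterica:0.03,Citrobacter_rodentium:0.035):0.02,"
    "(Klebsiella_pneumoniae:0.04,Enterobacter_cloacae:0.04):0.02):0.05);"
)
DEFAULT_CONTINUOUS_CLADE = (
    "E_albertii",
    "E_coli_Sakai",
    "E_fergusonii",
    "Shigella_flexneri",
)


@dataclass
class FixtureSpec:
    """All knobs of the synthetic study system (defaults = study geometry)."""

    seed: int = 0
    mother_len: int = 1539
    arrest_codon: int = 5
    orf_aa_len: int = 41
    upstream_orf_aa_len: int = 61
    tss_offset: int = 289
    term_offset: int = 155
    sd_offset: int = 15
    plant_sigma32: bool = True
    sigma32_tss_distance: int = 6
    sigma32_spacer: int = 14
    orf_offset: int = 400  # mother-start to ORF left end (adjusted to phase)
    left_flank: int = 300
    right_flank: int = 300
    read_len: int = 30
    n_total_reads: int = 10_000_000
    n_background: int = 20
    min_aa_len: int = 20
    conditions: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: copy.deepcopy(PRESETS)
    )

    def __post_init__(self) -> None:
        if self.mother_len % 3:
            raise ValueError("mother_len must be divisible by 3")


@dataclass
class Fixture:
    """A generated toy genome plus its ground-truth ledger."""

    record: GenomeRecord
    annotations: list[GeneAnnotation]
    ledger: dict
    spec: FixtureSpec

    @property
    def mother(self) -> GeneAnnotation:
        return next(a for a in self.annotations if a.kind == "mother")

    @property
    def by_kind(self) -> dict[str, GeneAnnotation]:
        return {a.kind: a for a in self.annotations}


def _rand_codons(rng: np.random.Generator, n: int, pool: Sequence[str]) -> list[str]:
    return [pool[i] for i in rng.integers(0, len(pool), size=n)]


def _draw_orf_nt(rng: np.random.Generator, aa_len: int, min_aa_len: int) -> str:
    """Coding sequence of a planted ORF: ATG + interior + TAA.

    Interior codons early enough to seed a nested >= min_aa_len ORF are drawn
    from non-start codons so the planted ORF is the only one in its frame.
    """
    n_interior = aa_len - 1
    no_start_until = max(0, aa_len - min_aa_len + 1)  # 1-based codon bound
    codons = ["ATG"]
    for j in range(2, 2 + n_interior):
        pool = _SAFE_INTERIOR if j <= no_start_until else _NONSTOP
        codons.append(_rand_codons(rng, 1, pool)[0])
    codons.append("TAA")
    return "".join(codons)


def _orf_clean(nt: str, min_aa_len: int) -> bool:
    """Planted-ORF sanity: start, stop, stop-free, no early nested start."""
    if nt[:3] != "ATG" or nt[-3:] not in STOPS:
        return False
    aa_len = len(nt) // 3 - 1
    if "*" in translate(nt)[:-1]:
        return False
    no_start_until = max(0, aa_len - min_aa_len + 1)
    for j in range(2, no_start_until + 1):
        if nt[3 * (j - 1) : 3 * j] in DEFAULT_START_CODONS:
            return False
    return True


def _layout(spec: FixtureSpec) -> dict:
    """Compute all genomic coordinates; raise on infeasible geometry."""
    orf_len = 3 * (spec.orf_aa_len + 1)
    up_len = 3 * (spec.upstream_orf_aa_len + 1)
    m0 = spec.left_flank
    m_end = m0 + spec.mother_len
    if orf_len > spec.mother_len:
        raise ValueError("embedded ORF longer than mother gene")
    # frame -2 under the package convention: leftmost-coordinate offset == 1 (mod 3)
    off = spec.orf_offset + ((1 - spec.orf_offset) % 3)
    orf_start = m0 + off
    orf_end = orf_start + orf_len
    if orf_end > m_end:
        raise ValueError("embedded ORF does not fit inside the mother gene")
    if orf_start - spec.term_offset < 0:
        raise ValueError("terminator position before genome start")
    sd_end = orf_end + spec.sd_offset  # exclusive genomic end of SD gap
    sd_core = (sd_end, sd_end + len(SD_CORE))  # fwd-strand interval of core
    guard = sd_end - 1  # base adjacent to core 3' end on the minus strand
    up_start = sd_core[1] + 10
    up_end = up_start + up_len
    tss = orf_end - 1 + spec.tss_offset
    if up_end > tss - 3:
        raise ValueError("upstream ORF does not fit inside the 5' UTR")
    term = orf_start - spec.term_offset
    box10 = (tss + 1 + spec.sigma32_tss_distance, 0)
    box10 = (box10[0], box10[0] + 8)
    box35 = (box10[1] + spec.sigma32_spacer, 0)
    box35 = (box35[0], box35[0] + 7)
    genome_len = max(m_end, box35[1] + 20) + spec.right_flank
    return {
        "genome_len": int(genome_len),
        "mother": (m0, m_end),
        "orf": (orf_start, orf_end),
        "upstream_orf": (up_start, up_end),
        "sd_core": sd_core,
        "sd_guard": guard,
        "tss": int(tss),
        "term": int(term),
        "box10": box10,
        "box35": box35,
    }


def _patch(seq: list[str], start: int, patch: str) -> None:
    seq[start : start + len(patch)] = list(patch)


def _mother_codon_bounds(m0: int, m_end: int, pos: int) -> tuple[int, int]:
    k = (pos - m0) // 3
    return m0 + 3 * k, m0 + 3 * k + 3


def _mother_has_stop(seq: list[str], m0: int, m_end: int) -> bool:
    aa = translate("".join(seq[m0:m_end]))
    return "*" in aa[:-1]


def _fix_patched_codons(
    seq: list[str],
    m0: int,
    m_end: int,
    fixed: set[int],
    rng: np.random.Generator,
) -> None:
    """Redraw free bases of mother codons that a patch turned into stops."""
    for cs in range(m0, m_end - 3, 3):
        codon = "".join(seq[cs : cs + 3])
        if codon not in STOPS:
            continue
        free = [p for p in range(cs, cs + 3) if p not in fixed]
        if not free:
            raise RuntimeError("planted elements force a mother-frame stop")
        for _ in range(50):
            for p in free:
                seq[p] = BASES[rng.integers(0, 4)]
            if "".join(seq[cs : cs + 3]) not in STOPS:
                break
        else:  # pragma: no cover - 50 uniform draws cannot all be stops
            raise RuntimeError("could not repair mother codon")


def _plant_orf(
    seq: list[str],
    rng: np.random.Generator,
    s: int,
    e: int,
    aa_len: int,
    arrest: bool,
    spec: "FixtureSpec",
    m0: int,
    m_end: int,
) -> bool:
    """Write a fresh planted ORF into [s, e), keeping the mother frame clean.

    The main (arrest) ORF additionally receives an editable arrest context
    at the target codon: Pro(CCT) + Arg(CGA) mother codons put Glu(GAG) in
    the ORF frame; a single C>A edit converts it to a TAG stop (Arg stays
    Arg) and destroys the spanning MnlI site CCTC.
    """
    for _ in range(500):
        nt = _draw_orf_nt(rng, aa_len, spec.min_aa_len)
        _patch(seq, s, revcomp(nt))
        if arrest:
            a = e - 3 * spec.arrest_codon
            _patch(seq, a - 1, "CCTCGA")
            if not _orf_clean(revcomp("".join(seq[s:e])), spec.min_aa_len):
                continue
        lo, _ = _mother_codon_bounds(m0, m_end, max(s, m0))
        hi = min(m_end, e + 3)
        hi = lo + ((hi - lo) // 3) * 3
        if "*" not in translate("".join(seq[lo:hi]))[:-1]:
            return True
    return False


def _kill_extra_orf(
    seq: list[str],
    extra,
    protected: set[int],
    m0: int,
    m_end: int,
    min_aa_len: int,
    rng: np.random.Generator,
) -> bool:
    """Disrupt an accidental antisense ORF by a single safe substitution.

    Preference: destroy its start codon; fall back to introducing an early
    stop in its frame.  A substitution is safe when it avoids protected
    positions and leaves the mother frame stop-free.
    """

    def safe_set(p: int, alt: str) -> bool:
        if p in protected or seq[p] == alt:
            return False
        old = seq[p]
        seq[p] = alt
        if m0 <= p < m_end:
            cs, ce = _mother_codon_bounds(m0, m_end, p)
            if ce <= m_end and "".join(seq[cs:ce]) in STOPS:
                seq[p] = old
                return False
        return True

    # the start codon of a minus-strand ORF occupies [end-3, end)
    start_positions = (
        list(range(extra.end - 3, extra.end))
        if extra.strand == "-"
        else list(range(extra.start, extra.start + 3))
    )
    orf_nt = extra.nt_seq
    for p in rng.permutation(start_positions).tolist():
        # index within the start codon, on the coding strand
        q = (extra.end - 1 - p) if extra.strand == "-" else (p - extra.start)
        for alt in rng.permutation(list(BASES)).tolist():
            coding_alt = revcomp(alt) if extra.strand == "-" else alt
            new_start = orf_nt[:q] + coding_alt + orf_nt[q + 1 : 3]
            if new_start[:3] in DEFAULT_START_CODONS:
                continue
            if safe_set(p, alt):
                return True
    # fall back: premature stop early enough that the truncated ORF drops
    # below min_aa_len (a stop at codon j leaves j amino acids)
    def to_genomic(q: int) -> int:
        return (extra.end - 1 - q) if extra.strand == "-" else (extra.start + q)

    def set_multi(edits: list[tuple[int, str]]) -> bool:
        saved = [(p, seq[p]) for p, _ in edits]
        if any(p in protected for p, _ in edits):
            return False
        for p, alt in edits:
            seq[p] = alt
        for p, _ in edits:
            if m0 <= p < m_end:
                cs, ce = _mother_codon_bounds(m0, m_end, p)
                if ce <= m_end and "".join(seq[cs:ce]) in STOPS:
                    for sp, sb in saved:
                        seq[sp] = sb
                    return False
        return True

    max_j = min(min_aa_len, len(orf_nt) // 3 - 1)
    for j in range(1, max_j):
        codon = orf_nt[3 * j : 3 * j + 3]
        for stop in STOPS:
            edits = []
            for i in range(3):
                if codon[i] == stop[i]:
                    continue
                q = 3 * j + i
                alt = revcomp(stop[i]) if extra.strand == "-" else stop[i]
                edits.append((to_genomic(q), alt))
            if edits and set_multi(edits):
                return True
    return False


def make_overlap_genome(spec: FixtureSpec | None = None) -> Fixture:
    """Generate the overlapping-gene toy genome with its truth ledger.

    Postconditions (verified before returning): the mother gene is a valid
    stop-free CDS; the planted antisense ORF has relative frame -2 and the
    planted geometry; antisense-ORF enumeration recovers exactly the two
    planted ORFs; the SD scan finds the planted core at the configured
    spacing; if requested, the sigma-32 scan finds the planted promoter with
    the optimal spacer at the proper TSS distance.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    lay = _layout(spec)
    m0, m_end = lay["mother"]
    orf_start, orf_end = lay["orf"]
    up_start, up_end = lay["upstream_orf"]

    sigma_model = Sigma32Model.default()
    box10_nt = sigma_model.box10_consensus.replace("N", "A")
    box35_nt = sigma_model.box35_consensus

    last_error = "unknown"
    for _ in range(30):
        n = lay["genome_len"]
        seq = [BASES[i] for i in rng.integers(0, 4, size=n)]
        # mother CDS: start, stop-free interior, stop
        _patch(seq, m0, "ATG")
        interior = _rand_codons(rng, (m_end - m0) // 3 - 2, _NONSTOP)
        _patch(seq, m0 + 3, "".join(interior))
        _patch(seq, m_end - 3, "TAA")

        fixed: set[int] = set()
        fixed.update(range(m0, m0 + 3))
        fixed.update(range(m_end - 3, m_end))

        # planted ORFs on the minus strand, mother-frame safety by redraw
        planted_specs = (
            ((orf_start, orf_end), spec.orf_aa_len, True),
            ((up_start, up_end), spec.upstream_orf_aa_len, False),
        )
        for (s, e), aa_len, arrest in planted_specs:
            if not _plant_orf(seq, rng, s, e, aa_len, arrest, spec, m0, m_end):
                raise RuntimeError("could not draw a mother-safe embedded ORF")
            fixed.update(range(s, e))

        # SD core + guard on the minus strand
        _patch(seq, lay["sd_core"][0], revcomp(SD_CORE))
        seq[lay["sd_guard"]] = "T"  # 'A' on the minus strand: blocks 3' pairing
        fixed.update(range(lay["sd_core"][0], lay["sd_core"][1]))
        fixed.add(lay["sd_guard"])

        if spec.plant_sigma32:
            _patch(seq, lay["box10"][0], revcomp(box10_nt))
            _patch(seq, lay["box35"][0], revcomp(box35_nt))
            fixed.update(range(*lay["box10"]))
            fixed.update(range(*lay["box35"]))

        _fix_patched_codons(seq, m0, m_end, fixed, rng)
        if _mother_has_stop(seq, m0, m_end):
            last_error = "mother frame not stop-free"
            continue

        mother = GeneAnnotation("mother_gene", "synth1", m0, m_end, "+", "mother")
        planted = {
            (orf_start, orf_end, "-"),
            (up_start, up_end, "-"),
        }

        # remove accidental antisense ORFs; extras nested inside a planted
        # ORF (every base protected) are resolved by redrawing that ORF
        ok = False
        stuck = False
        for _ in range(150):
            record = GenomeRecord("synth1", "".join(seq))
            orfs = enumerate_embedded_orfs(
                record, mother, min_aa_len=spec.min_aa_len
            )
            extras = [
                o for o in orfs if (o.start, o.end, o.strand) not in planted
            ]
            if not extras:
                ok = {(o.start, o.end, o.strand) for o in orfs} == planted
                break
            if _kill_extra_orf(
                seq, extras[0], fixed, m0, m_end, spec.min_aa_len, rng
            ):
                continue
            redrawn = False
            for (s, e), aa_len, arrest in planted_specs:
                if extras[0].start < e and extras[0].end > s:
                    redrawn = _plant_orf(
                        seq, rng, s, e, aa_len, arrest, spec, m0, m_end
                    )
                    break
            if not redrawn:
                stuck = True
                break
        if not ok or stuck:
            last_error = "accidental antisense ORFs could not be removed"
            continue
        if _mother_has_stop(seq, m0, m_end):
            last_error = "mother frame broken during cleanup"
            continue

        record = GenomeRecord("synth1", "".join(seq))

        # verify the planted SD is what the scanner reports
        upstream = revcomp(record.seq[orf_end : orf_end + 30])
        hit = scan_sd(upstream)
        if hit is None or hit.spacing_to_start != spec.sd_offset:
            last_error = "SD scan does not recover the planted core"
            continue

        sigma_ok = True
        if spec.plant_sigma32:
            region_fwd = record.seq[lay["tss"] + 1 : lay["tss"] + 51]
            region = revcomp(region_fwd)
            hits = scan_sigma32(region, sigma_model, tss_pos=len(region))
            sigma_ok = bool(hits) and hits[0].score == 0 and (
                hits[0].spacer_len == spec.sigma32_spacer
            )
        if not sigma_ok:
            last_error = "sigma-32 scan does not recover the planted promoter"
            continue

        annotations = [
            mother,
            GeneAnnotation(
                "antisense_orf", "synth1", orf_start, orf_end, "-", "overlapping"
            ),
            GeneAnnotation(
                "upstream_orf", "synth1", up_start, up_end, "-", "putative"
            ),
        ]
        ledger = {
            "seed": int(spec.seed),
            "record_id": "synth1",
            "genome_len": len(record),
            "mother": [m0, m_end],
            "orf": [orf_start, orf_end],
            "upstream_orf": [up_start, up_end],
            "orf_strand": "-",
            "relative_frame": -2,
            "sd_core": list(lay["sd_core"]),
            "sd_spacing": spec.sd_offset,
            "sd_delta_g": float(hit.delta_g),
            "tss": lay["tss"],
            "term": lay["term"],
            "arrest": {
                "codon": spec.arrest_codon,
                "edit_pos": orf_end - 3 * spec.arrest_codon + 2,
                "mnl1_site": [
                    orf_end - 3 * spec.arrest_codon - 1,
                    orf_end - 3 * spec.arrest_codon + 3,
                ],
            },
            "tss_offset": spec.tss_offset,
            "term_offset": spec.term_offset,
            "sigma32": (
                {
                    "box10": list(lay["box10"]),
                    "box35": list(lay["box35"]),
                    "spacer": spec.sigma32_spacer,
                    "tss_distance": spec.sigma32_tss_distance,
                }
                if spec.plant_sigma32
                else None
            ),
        }
        return Fixture(record, annotations, ledger, spec)
    raise RuntimeError(f"fixture generation failed: {last_error}")


# ---------------------------------------------------------------------------
# read simulation


def _feature_reads(
    rng: np.random.Generator,
    feat: GeneAnnotation,
    n_reads: int,
    read_len: int,
    coverage_window: float,
) -> list[Read]:
    """Place reads inside a feature, anchored at its 5' end.

    ``coverage_window`` limits placements to that 5' fraction of the feature
    so the realized RIBOseq coverage approximates the configured target
    (1.0 for RNAseq: uniform over the feature).
    """
    w = max(1, round(coverage_window * len(feat)))
    if feat.strand == "+":
        ws, we = feat.start, feat.start + w
    else:
        ws, we = feat.end - w, feat.end
    reads = []
    if we - ws >= read_len:
        starts = rng.integers(ws, we - read_len + 1, size=n_reads)
        reads = [Read(feat.record_id, int(s), int(s) + read_len, feat.strand) for s in starts]
    else:
        reads = [Read(feat.record_id, ws, we, feat.strand)] * n_reads
    return reads


def simulate_reads(
    fixture: Fixture,
    conditions: Iterable[str] | None = None,
    replicates: Sequence[int] = (1, 2),
    seed: int | None = None,
) -> dict[tuple[str, str, int], AlignmentSet]:
    """Poisson-sampled strand-specific reads for each library/replicate.

    For every annotated gene with a target in the condition preset, the
    expected read count is ``rpkm_target * len_bp * n_total / 1e9`` (RIBOseq
    target RPKM = transcriptome RPKM x RCV), realized by Poisson sampling.
    Background reads are scattered genome-wide on random strands;
    ``total_mapped`` is the configured library depth.
    """
    spec = fixture.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    conditions = list(conditions) if conditions else list(spec.conditions)
    by_kind = fixture.by_kind
    out: dict[tuple[str, str, int], AlignmentSet] = {}
    for condition in conditions:
        targets = spec.conditions[condition]
        for rep in replicates:
            for lib in ("RNA", "RIBO"):
                reads: list[Read] = []
                for kind, t in targets.items():
                    feat = by_kind.get(kind)
                    if feat is None:
                        continue
                    rpkm_target = (
                        t["rna_rpkm"] if lib == "RNA" else t["rna_rpkm"] * t["rcv"]
                    )
                    mu = rpkm_target * len(feat) * spec.n_total_reads / 1e9
                    k = int(rng.poisson(mu))
                    window = 1.0 if lib == "RNA" else float(t["coverage"])
                    reads.extend(
                        _feature_reads(rng, feat, k, spec.read_len, window)
                    )
                n_bg = int(rng.poisson(spec.n_background))
                if n_bg:
                    starts = rng.integers(
                        0, len(fixture.record) - spec.read_len, size=n_bg
                    )
                    strands = rng.integers(0, 2, size=n_bg)
                    reads.extend(
                        Read(
                            fixture.record.id,
                            int(s),
                            int(s) + spec.read_len,
                            "+-"[int(st)],
                        )
                        for s, st in zip(starts, strands)
                    )
                out[(condition, lib, rep)] = AlignmentSet(
                    library=lib,
                    replicate=rep,
                    condition=condition,
                    reads=reads,
                    total_mapped=spec.n_total_reads,
                )
    return out


# ---------------------------------------------------------------------------
# homolog families


def _orf_intact(seq: list[str], orf_start: int, orf_end: int) -> bool:
    nt = revcomp("".join(seq[orf_start:orf_end]))
    if nt[:3] != "ATG" or nt[-3:] not in STOPS:
        return False
    return "*" not in translate(nt)[:-1]


def simulate_homolog_family(
    fixture: Fixture,
    tree: str | dendropy.Tree | None = None,
    clade_continuous: Sequence[str] = DEFAULT_CONTINUOUS_CLADE,
    sub_rate: float = 1.0,
    disruption_rate: float = 1.0,
    seed: int | None = None,
) -> tuple[dict[str, str], dict[str, str], dendropy.Tree]:
    """Evolve mother-gene homologs on a tree with clade-restricted continuity.

    Substitutions accumulate along every branch at ``sub_rate`` expected
    substitutions per site per unit branch length, always rejecting changes
    that would break the embedded ORF (its start, stop, or stop-free
    interior).  Each tip outside ``clade_continuous`` is then disrupted with
    probability ``disruption_rate``: either a premature-stop substitution or
    a 1-2 bp indel in the middle of the ORF.  Returns (homolog sequences,
    truth labels, tree); truth labels are continuity statuses.
    """
    spec = fixture.spec
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    if tree is None:
        tree = DEFAULT_TREE_NEWICK
    if isinstance(tree, str):
        tree = dendropy.Tree.get(
            data=tree, schema="newick", preserve_underscores=True
        )
    mother = fixture.mother
    region = fixture.record.seq[mother.start : mother.end]
    orf_s = fixture.ledger["orf"][0] - mother.start
    orf_e = fixture.ledger["orf"][1] - mother.start

    def evolve(seq: list[str], edge_len: float) -> list[str]:
        seq = list(seq)
        n_sub = int(rng.poisson(sub_rate * edge_len * len(seq)))
        applied = 0
        guard = 0
        while applied < n_sub and guard < 50 * (n_sub + 1):
            guard += 1
            p = int(rng.integers(0, len(seq)))
            alt = BASES[int(rng.integers(0, 4))]
            if alt == seq[p]:
                continue
            old = seq[p]
            seq[p] = alt
            if orf_s <= p < orf_e and not _orf_intact(seq, orf_s, orf_e):
                seq[p] = old
                continue
            applied += 1
        return seq

    seqs_at_node: dict[int, list[str]] = {}
    root = tree.seed_node
    seqs_at_node[id(root)] = list(region)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_seq = seqs_at_node[id(node.parent_node)]
        seqs_at_node[id(node)] = evolve(parent_seq, node.edge.length or 0.0)

    homologs: dict[str, str] = {}
    truth: dict[str, str] = {}
    clade = set(clade_continuous)
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        seq = seqs_at_node[id(leaf)]
        if label in clade:
            truth[label] = "continuous"
        elif rng.random() >= disruption_rate:
            truth[label] = "continuous"
        else:
            mid_codon = (orf_e - orf_s) // 6  # middle codon index
            if rng.random() < 0.5:
                # premature stop: overwrite a mid-ORF codon with TAA
                hi = orf_e - 3 * mid_codon
                seq = list(seq)
                seq[hi - 3 : hi] = list(revcomp("TAA"))
                truth[label] = "disrupted_stop"
            else:
                k = int(rng.integers(1, 3))  # 1 or 2 bp
                pos = orf_s + 3 * mid_codon
                seq = list(seq)
                if rng.random() < 0.5:
                    del seq[pos : pos + k]
                else:
                    ins = [BASES[int(rng.integers(0, 4))] for _ in range(k)]
                    seq[pos:pos] = ins
                truth[label] = "disrupted_frameshift"
        homologs[label] = "".join(seq)
    return homologs, truth, tree


# ---------------------------------------------------------------------------
# competition assays


def simulate_competition(
    true_ci: float,
    n_reps: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    condition: str = "LB_arginine",
) -> list[CompetitionObservation]:
    """Observations whose endpoint ratios follow a competitive index.

    Each replicate's CI is ``true_ci`` perturbed by multiplicative
    log-normal noise; starts are 50:50 and endpoints follow
    ``mut_end = 100 * ci / (1 + ci)``.  With ``noise_sd = 0`` and a true CI
    of 5.67 the endpoint is the canonical 15:85 wild-type:mutant ratio.
    """
    if true_ci <= 0:
        raise ValueError("true_ci must be positive")
    rng = np.random.default_rng(seed)
    obs = []
    for rep in range(1, n_reps + 1):
        ci = true_ci * float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd else true_ci
        mut_end = 100.0 * ci / (1.0 + ci)
        obs.append(
            CompetitionObservation(
                condition=condition,
                replicate=rep,
                wt_start_pct=50.0,
                mut_start_pct=50.0,
                wt_end_pct=100.0 - mut_end,
                mut_end_pct=mut_end,
            )
        )
    return obs
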