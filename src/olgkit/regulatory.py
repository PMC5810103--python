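"""Regulatory-element scoring: SD hybridization energy, sigma-32 promoter scan,
and the transcript geometry model.

The Shine-Dalgarno (SD) strength of a candidate ribosome-binding region is
the hybridization free energy dG (kcal/mol, 37 C) of the best duplex between
a substring of the candidate and the anti-SD tail of the 16S rRNA, under an
RNA/RNA nearest-neighbor stacking model with a helix-initiation penalty.
Only contiguous, fully Watson-Crick-paired duplexes are scored (no bulges or
internal loops); more negative is stronger binding.  A dG at or below -2.9
indicates the presence of an SD sequence; the perfect SD (TAAGGAGGT) scores
-9.6 under the shipped parameter set.

The sigma-32 promoter scan matches the -35 and -10 consensus boxes with an
IUPAC-aware mismatch count, requires the invariant positions (first T of the
-35 box, A of the -10 box) to match exactly, constrains the spacer to
13-15 bp (optimum 14; each bp of deviation adds +1 to the score), and, when
a TSS is supplied, requires the -10 box to sit at the proper distance
upstream of it.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import yaml
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "SdModel",
    "SdHit",
    "Sigma32Model",
    "PromoterHit",
    "TranscriptModel",
    "duplex_delta_g",
    "scan_sd",
    "scan_sigma32",
    "build_transcript_model",
    "SD_THRESHOLD",
]

SD_THRESHOLD = -2.9

_RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def _load_data(name: str) -> dict:
    ref = importlib.resources.files("olgkit.data").joinpath(name)
    return yaml.safe_load(ref.read_text())


@dataclass
class SdModel:
    """Anti-SD sequence plus nearest-neighbor duplex parameters."""

    anti_sd: str
    stacks: dict[str, float]
    initiation: float
    temperature_c: float = 37.0
    threshold: float = SD_THRESHOLD

    @classmethod
    def default(cls) -> "SdModel":
        params = _load_data("sd_params.yaml")
        return cls(
            anti_sd=params["anti_sd"],
            stacks={k: float(v) for k, v in params["stacks"].items()},
            initiation=float(params["initiation"]),
            temperature_c=float(params["temperature_c"]),
            threshold=float(params["sd_threshold"]),
        )


@dataclass
class SdHit:
    """Best SD duplex found upstream of a start codon.

    ``window_start_offset``/``spacing_to_start`` are distances (bp) from the
    5' end / 3' end of the matched subsequence to the start codon.
    """

    window_start_offset: int
    matched_subseq: str
    delta_g: float
    spacing_to_start: int


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def duplex_delta_g(
    candidate: str,
    model: SdModel | None = None,
    min_len: int = 3,
    max_len: int = 12,
) -> float:
    """Hybridization dG of the best candidate/anti-SD duplex (kcal/mol).

    The minimum over all contiguous, fully paired duplexes between a
    candidate substring (length ``min_len``..``max_len``) and an anti-SD
    substring.  Returns ``inf`` when no duplex of at least ``min_len`` base
    pairs exists.  Extending a duplex by one complementary base never
    increases dG (all stack terms are negative).
    """
    if not candidate:
        raise ValueError("candidate sequence must be non-empty")
    model = model or SdModel.default()
    cand = _to_rna(candidate)
    anti = _to_rna(model.anti_sd)
    best = float("inf")
    max_len = min(max_len, len(anti), len(cand))
    for L in range(min_len, max_len + 1):
        for a in range(len(cand) - L + 1):
            for b in range(len(anti) - L + 1):
                # antiparallel: cand[a + t] pairs anti[b + L - 1 - t]
                if any(
                    (cand[a + t], anti[b + L - 1 - t]) not in _RNA_PAIRS
                    for t in range(L)
                ):
                    continue
                dg = model.initiation + sum(
                    model.stacks[cand[a + t : a + t + 2]] for t in range(L - 1)
                )
                best = min(best, dg)
    return best


def scan_sd(
    upstream_seq: str,
    model: SdModel | None = None,
    threshold: float | None = None,
    min_len: int = 5,
    max_len: int = 12,
    expected_window: int = 30,
) -> SdHit | None:
    """Scan the region immediately upstream of a start codon for an SD site.

    ``upstream_seq`` is the sequence 5' of the start codon on the coding
    strand, its last base adjacent to the start codon (canonically 30 bp; a
    shorter window at a contig edge is scanned with a warning).  All
    sub-windows of length ``min_len``..``max_len`` that pair fully and
    contiguously with the anti-SD are scored; the minimal-dG window is
    returned, ties broken 5'-most.  Returns ``None`` when the best dG is
    above the presence threshold (-2.9 by default).  The result is invariant
    to any sequence downstream of the start codon, which is never seen.
    """
    model = model or SdModel.default()
    if threshold is None:
        threshold = model.threshold
    if not upstream_seq:
        return None
    if len(upstream_seq) < expected_window:
        warnings.warn(
            f"SD scan window truncated to {len(upstream_seq)} bp "
            f"(expected {expected_window})",
            stacklevel=2,
        )
    n = len(upstream_seq)
    best: SdHit | None = None
    for a in range(n):
        for L in range(min_len, min(max_len, n - a) + 1):
            window = upstream_seq[a : a + L]
            dg = duplex_delta_g(window, model, min_len=L, max_len=L)
            if dg == float("inf"):
                continue
            if best is None or dg < best.delta_g:
                best = SdHit(
                    window_start_offset=n - a,
                    matched_subseq=window,
                    delta_g=dg,
                    spacing_to_start=n - (a + L),
                )
    if best is None or best.delta_g > threshold:
        return None
    return best


# ---------------------------------------------------------------------------
# sigma-32 promoter scan


@dataclass
class Sigma32Model:
    box35_consensus: str
    box10_consensus: str
    hard35: tuple[int, ...]
    hard10: tuple[int, ...]
    spacer_range: tuple[int, int]
    spacer_opt: int
    tss_distance_range: tuple[int, int]
    tss_distance_opt: int = 6
    max_score: int = 3

    def __post_init__(self) -> None:
        if self.spacer_range[0] > self.spacer_range[1]:
            raise ValueError("empty spacer range")
        for pos in self.hard35:
            if not 0 <= pos < len(self.box35_consensus):
                raise ValueError("hard position outside -35 box")
        for pos in self.hard10:
            if not 0 <= pos < len(self.box10_consensus):
                raise ValueError("hard position outside -10 box")

    @classmethod
    def default(cls) -> "Sigma32Model":
        p = _load_data("sigma32.yaml")
        return cls(
            box35_consensus=p["box35"],
            box10_consensus=p["box10"],
            hard35=tuple(p["hard35"]),
            hard10=tuple(p["hard10"]),
            spacer_range=tuple(p["spacer_range"]),
            spacer_opt=int(p["spacer_opt"]),
            tss_distance_range=tuple(p["tss_distance_range"]),
            tss_distance_opt=int(p["tss_distance_opt"]),
            max_score=int(p["max_score"]),
        )


@dataclass
class PromoterHit:
    score: int
    box35_start: int
    box10_start: int
    spacer_len: int
    tss_distance: int | None
    box35_seq: str
    box10_seq: str


def _iupac_match(base: str, consensus_char: str) -> bool:
    return base in ambiguous_dna_values.get(consensus_char, consensus_char)


def _box_mismatches(seq: str, consensus: str) -> int:
    return sum(
        0 if _iupac_match(b, c) else 1 for b, c in zip(seq, consensus, strict=True)
    )


def scan_sigma32(
    seq: str,
    model: Sigma32Model | None = None,
    tss_pos: int | None = None,
) -> list[PromoterHit]:
    """Scan a coding-strand sequence for sigma-32 promoter architectures.

    Positions are 0-based within ``seq`` (which the caller supplies in
    transcript orientation; the scan is strand-specific and never looks at
    the reverse complement).  A hit requires exact matches at the hard
    positions and a spacer within range; the score is the IUPAC-aware
    mismatch count over both boxes plus 1 per bp of spacer deviation from
    the optimum.  Hits scoring above ``max_score`` are dropped.  When
    ``tss_pos`` is given, the distance from the 3' end of the -10 box to
    the TSS must fall within the model's range.  Hits are sorted by
    (score, position).
    """
    model = model or Sigma32Model.default()
    if tss_pos is not None and not 0 <= tss_pos <= len(seq):
        raise ValueError("tss_pos outside sequence")
    b35, b10 = model.box35_consensus, model.box10_consensus
    min_span = len(b35) + model.spacer_range[0] + len(b10)
    if len(seq) < min_span:
        return []
    hits: list[PromoterHit] = []
    for p35 in range(len(seq) - min_span + 1):
        s35 = seq[p35 : p35 + len(b35)]
        if any(s35[i] != b35[i] for i in model.hard35):
            continue
        m35 = _box_mismatches(s35, b35)
        for spacer in range(model.spacer_range[0], model.spacer_range[1] + 1):
            p10 = p35 + len(b35) + spacer
            if p10 + len(b10) > len(seq):
                continue
            s10 = seq[p10 : p10 + len(b10)]
            if any(s10[i] != b10[i] for i in model.hard10):
                continue
            score = m35 + _box_mismatches(s10, b10) + abs(spacer - model.spacer_opt)
            if score > model.max_score:
                continue
            tss_distance = None
            if tss_pos is not None:
                tss_distance = tss_pos - (p10 + len(b10))
                lo, hi = model.tss_distance_range
                if not lo <= tss_distance <= hi:
                    continue
            hits.append(
                PromoterHit(
                    score=score,
                    box35_start=p35,
                    box10_start=p10,
                    spacer_len=spacer,
                    tss_distance=tss_distance,
                    box35_seq=s35,
                    box10_seq=s10,
                )
            )
    hits.sort(key=lambda h: (h.score, h.box35_start))
    return hits


# ---------------------------------------------------------------------------
# transcript geometry


@dataclass
class TranscriptModel:
    """Offsets describing a transcript around an ORF (all in bp, >= 0)."""

    tss_offset_upstream_of_start: int
    terminator_offset_downstream_of_stop: int
    sd_offset: int = 0

    def __post_init__(self) -> None:
        if min(
            self.tss_offset_upstream_of_start,
            self.terminator_offset_downstream_of_stop,
            self.sd_offset,
        ) < 0:
            raise ValueError("transcript offsets must be non-negative")


def build_transcript_model(
    tss: int,
    start: int,
    stop: int,
    term: int,
    sd_end: int | None = None,
) -> TranscriptModel:
    """Derive transcript offsets from positions on the transcript axis.

    All arguments are coordinates along the transcript (5'->3'):
    transcription start site, ORF start codon position, position just after
    the stop codon, and transcription termination.  Requires
    ``tss <= start < stop <= term``.  ``sd_end`` is the position just after
    the SD element, giving the SD-to-start spacing.
    """
    if not (tss <= start < stop <= term):
        raise ValueError("require tss <= start < stop <= term on transcript axis")
    sd_offset = 0
    if sd_end is not None:
        if sd_end > start:
            raise ValueError("SD element must lie upstream of the start codon")
        sd_offset = start - sd_end
    return TranscriptModel(
        tss_offset_upstream_of_start=start - tss,
        terminator_offset_downstream_of_stop=term - stop,
        sd_offset=sd_offset,
    )
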