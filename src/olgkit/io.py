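"""Readers and writers for the standard formats the pipeline touches.

FASTA via Bio.SeqIO, GFF3 via gffutils, SAM via pysam, tabular files via
pandas.  Simulated alignments carry their library metadata (library,
replicate, condition, total mapped reads) in comment headers so that a
round trip through disk preserves the AlignmentSet.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .competition import CompetitionObservation, peak_ratio_to_pct
from .seqcore import EmbeddedOrf, GeneAnnotation, GenomeRecord
from .translatome import AlignmentSet, Read

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed6_features",
    "write_reads_bed",
    "read_reads_bed",
    "write_reads_sam",
    "read_reads_sam",
    "write_orf_table",
    "read_competition_tsv",
]


# -- FASTA -------------------------------------------------------------------

def read_fasta(path) -> list[GenomeRecord]:
    return [
        GenomeRecord(id=rec.id, seq=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[GenomeRecord | tuple[str, str]], path) -> None:
    out = []
    for rec in records:
        if isinstance(rec, GenomeRecord):
            rid, seq = rec.id, rec.seq
        else:
            rid, seq = rec
        out.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(out, str(path), "fasta")


# -- annotations -------------------------------------------------------------

def read_gff3(path) -> list[GeneAnnotation]:
    """Read CDS-like features; GFF3 1-based closed coords become 0-based half-open."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True)
    annots = []
    for feat in db.all_features():
        kind = feat.attributes.get("olg_kind", ["mother"])[0]
        gene_id = (feat.attributes.get("ID") or [feat.id or "feature"])[0]
        annots.append(
            GeneAnnotation(
                gene_id=gene_id,
                record_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                kind=kind,
            )
        )
    return annots


def write_gff3(annots: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annots:
            attrs = f"ID={a.gene_id};olg_kind={a.kind}"
            fh.write(
                f"{a.record_id}\tolgkit\tCDS\t{a.start + 1}\t{a.end}\t.\t"
                f"{a.strand}\t0\t{attrs}\n"
            )


def read_bed6_features(path) -> list[GeneAnnotation]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        GeneAnnotation(
            gene_id=str(r["name"]),
            record_id=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
        )
        for _, r in df.iterrows()
    ]


# -- reads (BED6 dialect) ----------------------------------------------------

def write_reads_bed(aln: AlignmentSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#olgkit library={aln.library} replicate={aln.replicate} "
            f"condition={aln.condition} total_mapped={aln.total_mapped}\n"
        )
        for i, r in enumerate(aln.reads):
            fh.write(
                f"{r.record_id}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n"
            )


def _parse_metadata_line(line: str) -> dict[str, str]:
    meta = {}
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_reads_bed(
    path,
    library: str | None = None,
    replicate: int | None = None,
    condition: str | None = None,
    total_mapped: int | None = None,
) -> AlignmentSet:
    """Read a reads BED6; metadata comes from the header comment unless overridden."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = _parse_metadata_line(first)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if df["strand"].isna().any() or not set(df["strand"]).issubset({"+", "-"}):
        raise ValueError(f"{path}: reads lack strand information (BED6 required)")
    reads = [
        Read(str(r["chrom"]), int(r["start"]), int(r["end"]), str(r["strand"]))
        for _, r in df.iterrows()
    ]
    return AlignmentSet(
        library=library or meta.get("library", "RNA"),
        replicate=replicate or int(meta.get("replicate", 1)),
        condition=condition or meta.get("condition", ""),
        reads=reads,
        total_mapped=total_mapped or int(meta.get("total_mapped", len(reads))),
    )


# -- reads (SAM) -------------------------------------------------------------

def write_reads_sam(aln: AlignmentSet, path, record: GenomeRecord) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": record.id, "LN": len(record)}],
        "CO": [
            f"olgkit library={aln.library} replicate={aln.replicate} "
            f"condition={aln.condition} total_mapped={aln.total_mapped}"
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, r in enumerate(aln.reads):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"read{i}"
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.cigarstring = f"{r.end - r.start}M"
            seg.flag = 16 if r.strand == "-" else 0
            seg.mapping_quality = 60
            out.write(seg)


def read_reads_sam(
    path,
    library: str | None = None,
    replicate: int | None = None,
    condition: str | None = None,
    total_mapped: int | None = None,
) -> AlignmentSet:
    """Read mapped primary alignments from a SAM file."""
    meta: dict[str, str] = {}
    reads: list[Read] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for co in sam.header.to_dict().get("CO", []):
            if co.startswith("olgkit"):
                meta = _parse_metadata_line(co.removeprefix("olgkit").strip())
        for seg in sam.fetch(until_eof=True):
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            reads.append(
                Read(
                    seg.reference_name,
                    seg.reference_start,
                    seg.reference_end,
                    "-" if seg.is_reverse else "+",
                )
            )
    return AlignmentSet(
        library=library or meta.get("library", "RNA"),
        replicate=replicate or int(meta.get("replicate", 1)),
        condition=condition or meta.get("condition", ""),
        reads=reads,
        total_mapped=total_mapped or int(meta.get("total_mapped", len(reads))),
    )


# -- tables ------------------------------------------------------------------

def write_orf_table(orfs: Sequence[EmbeddedOrf], path) -> None:
    pd.DataFrame(
        [
            {
                "orf_id": o.orf_id,
                "mother": o.mother_gene_id,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "frame": o.relative_frame,
                "aa_len": o.aa_len,
                "overlap_bp": o.overlap_bp,
            }
            for o in orfs
        ]
    ).to_csv(path, sep="\t", index=False)


_PCT_COLS = ("wt_start", "mut_start", "wt_end", "mut_end")
_PEAK_COLS = ("h_wt_start", "h_mut_start", "h_wt_end", "h_mut_end")


def read_competition_tsv(path) -> list[CompetitionObservation]:
    """Read competition observations from TSV.

    Accepts either percentage columns (condition, replicate, wt_start,
    mut_start, wt_end, mut_end) or peak-height columns (condition,
    replicate, h_wt_start, h_mut_start, h_wt_end, h_mut_end).  Malformed
    rows raise with the offending line number.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - diagnostics for CLI users
        raise ValueError(f"{path}: cannot parse TSV: {exc}") from exc
    cols = set(df.columns)
    if set(_PCT_COLS).issubset(cols):
        mode = "pct"
    elif set(_PEAK_COLS).issubset(cols):
        mode = "peaks"
    else:
        raise ValueError(
            f"{path}: line 1: expected columns {_PCT_COLS} or {_PEAK_COLS}"
        )
    obs = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header line
        try:
            if mode == "peaks":
                ws, ms = peak_ratio_to_pct(
                    float(row["h_wt_start"]), float(row["h_mut_start"])
                )
                we, me = peak_ratio_to_pct(
                    float(row["h_wt_end"]), float(row["h_mut_end"])
                )
            else:
                ws, ms = float(row["wt_start"]), float(row["mut_start"])
                we, me = float(row["wt_end"]), float(row["mut_end"])
            obs.append(
                CompetitionObservation(
                    condition=str(row["condition"]),
                    replicate=int(row.get("replicate", 1)),
                    wt_start_pct=ws,
                    mut_start_pct=ms,
                    wt_end_pct=we,
                    mut_end_pct=me,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
    return obs
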