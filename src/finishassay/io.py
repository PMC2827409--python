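"""Interchange formats: FASTA, placement TSV, BED, RepeatMasker .out.

All tabular coordinates are 0-based half-open except the RepeatMasker .out
dialect, which follows that format's 1-based inclusive convention.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    BiasRegion,
    ContigAlignment,
    ContigMap,
    Gap,
    Placement,
    ReadPair,
    ReadPlacement,
    RepeatAnnotation,
    TERMINAL,
)

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_placements",
    "read_placements_tsv",
    "pairs_from_placements",
    "write_gaps_bed",
    "write_gaps_tsv",
    "write_bias_tsv",
    "write_map_tsv",
    "read_alignments_tsv",
    "write_annotation_bed",
    "write_repeatmasker_out",
    "read_repeatmasker_out",
]

PLACEMENT_COLUMNS = [
    "read_id", "subclone_id", "seq_id", "start", "end", "strand",
    "mate_id", "library_id",
]

ALIGNMENT_COLUMNS = [
    "contig_id", "ref_id", "start", "end", "qstart", "qend", "strand",
    "identity", "note",
]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_placements(path: str | Path, rows: Iterable[ReadPlacement]) -> None:
    df = pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_placements_tsv(path: str | Path) -> list[ReadPlacement]:
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"placement TSV missing columns: {sorted(missing)}")
    return [ReadPlacement(*row) for row in df[PLACEMENT_COLUMNS].itertuples(index=False)]


def pairs_from_placements(
    rows: Sequence[ReadPlacement],
    insert_mean: float,
    insert_sd: float,
) -> list[ReadPair]:
    """Reassemble read pairs from placement rows (mates joined by read id)."""
    by_id = {r.read_id: r for r in rows}
    pairs = []
    seen = set()
    for r in rows:
        if r.read_id in seen or r.mate_id not in by_id:
            continue
        mate = by_id[r.mate_id]
        seen.update((r.read_id, mate.read_id))
        fwd, rev = (r, mate) if r.read_id.endswith(".f") or r.read_id < mate.read_id else (mate, r)
        pairs.append(
            ReadPair(
                subclone_id=r.subclone_id,
                fwd=Placement(fwd.seq_id, fwd.start, fwd.end, fwd.strand),
                rev=Placement(rev.seq_id, rev.start, rev.end, rev.strand),
                insert_mean=insert_mean,
                insert_sd=insert_sd,
                library_id=r.library_id,
            )
        )
    return pairs


def write_gaps_bed(path: str | Path, gaps: Iterable[Gap]) -> None:
    """BED: chrom, start, end, name=status, score=spanning subclones, kind."""
    with open(path, "w") as fh:
        for g in gaps:
            score = max(g.spanning_subclones, 0)
            fh.write(
                f"{g.sequence_id}\t{g.start}\t{g.end}\t{g.status}\t{score}\t"
                f"{g.kind}\n"
            )


def write_gaps_tsv(path: str | Path, gaps: Iterable[Gap]) -> None:
    df = pd.DataFrame(
        [
            {
                "sequence_id": g.sequence_id,
                "start": g.start,
                "end": g.end,
                "size": g.size,
                "kind": g.kind,
                "left_contig": g.left_contig,
                "right_contig": g.right_contig,
                "spanning_subclones": g.spanning_subclones,
                "status": g.status,
            }
            for g in gaps
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gaps_tsv(path: str | Path) -> list[Gap]:
    df = pd.read_csv(path, sep="\t")
    return [
        Gap(
            sequence_id=r.sequence_id,
            start=int(r.start),
            end=int(r.end),
            left_contig=r.left_contig,
            right_contig=r.right_contig,
            kind=r.kind,
            spanning_subclones=int(r.spanning_subclones),
            status=r.status,
        )
        for r in df.itertuples(index=False)
    ]


def write_bias_tsv(path: str | Path, regions: Iterable[BiasRegion]) -> None:
    pd.DataFrame(regions, columns=["start", "end", "viability"]).to_csv(
        path, sep="\t", index=False
    )


def write_map_tsv(path: str | Path, cmap: ContigMap) -> None:
    rows = [
        {
            "contig_id": a.contig_id,
            "ref_id": cmap.sequence_id,
            "start": a.start,
            "end": a.end,
            "qstart": a.qstart,
            "qend": a.qend,
            "strand": a.strand,
            "identity": a.identity,
            "note": "split" if a.contig_id in cmap.split_contigs else ".",
        }
        for a in cmap.placements
    ]
    for cid in cmap.unmapped_contigs:
        rows.append(
            {
                "contig_id": cid, "ref_id": cmap.sequence_id,
                "start": -1, "end": -1, "qstart": -1, "qend": -1,
                "strand": ".", "identity": 0.0, "note": "unmapped",
            }
        )
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path) -> list[ContigAlignment]:
    """Import externally produced alignments (9-column TSV dialect)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples(index=False):
        if getattr(r, "note", ".") == "unmapped":
            continue
        out.append(
            ContigAlignment(
                contig_id=str(r.contig_id),
                start=int(r.start),
                end=int(r.end),
                qstart=int(r.qstart),
                qend=int(r.qend),
                strand=str(r.strand),
                identity=float(r.identity),
            )
        )
    return out


def write_annotation_bed(path: str | Path, annotation: RepeatAnnotation) -> None:
    with open(path, "w") as fh:
        for s, e, cls in sorted(annotation.intervals):
            fh.write(f"{annotation.sequence_id}\t{s}\t{e}\t{cls}\n")


_RM_CLASS_OUT = {
    "Simple": ("(REP)n", "Simple_repeat"),
    "LINE": ("SynL1", "LINE/L1"),
    "SINE": ("SynAlu", "SINE/Alu"),
    "LTR": ("SynERV", "LTR/ERVL"),
    "DNA": ("SynMER", "DNA/hAT"),
}

_RM_CLASS_IN = [
    (re.compile(r"^Simple_repeat|^Low_complexity"), "Simple"),
    (re.compile(r"^LINE"), "LINE"),
    (re.compile(r"^SINE"), "SINE"),
    (re.compile(r"^LTR"), "LTR"),
    (re.compile(r"^DNA"), "DNA"),
]


def write_repeatmasker_out(path: str | Path, annotation: RepeatAnnotation,
                           sequence_length: int) -> None:
    """Write the annotation in RepeatMasker .out dialect (1-based inclusive)."""
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, (s, e, cls) in enumerate(sorted(annotation.intervals), 1):
            name, family = _RM_CLASS_OUT[cls]
            left = sequence_length - e
            fh.write(
                f"  255   0.0  0.0  0.0  {annotation.sequence_id}  {s + 1}  {e}"
                f"  ({left})  +  {name}  {family}  1  {e - s}  (0)  {i}\n"
            )


def read_repeatmasker_out(path: str | Path, sequence_id: str | None = None
                          ) -> RepeatAnnotation:
    """Parse RepeatMasker .out (whitespace-delimited dialect tolerated).

    Lines whose class/family does not map onto the tracked classes are
    skipped.  Coordinates are converted to 0-based half-open.
    """
    intervals: list[tuple[int, int, str]] = []
    seq_ids = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 11 or not parts[0].replace(".", "").isdigit():
                continue
            qseq, qbegin, qend = parts[4], parts[5], parts[6]
            if sequence_id is not None and qseq != sequence_id:
                continue
            family = parts[10]
            cls = next(
                (c for pat, c in _RM_CLASS_IN if pat.match(family)), None
            )
            if cls is None:
                continue
            seq_ids.add(qseq)
            intervals.append((int(qbegin) - 1, int(qend), cls))
    sid = sequence_id or (seq_ids.pop() if len(seq_ids) == 1 else "unknown")
    return RepeatAnnotation(sequence_id=sid, intervals=sorted(intervals))
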