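"""Captured / uncaptured gap classification from read-pair evidence.

A gap is *captured* when at least ``min_spanning_pairs`` subclones have their
two reads on opposite sides of the gap with an implied span (outermost
distance between the two reads on the reference) that does not greatly
exceed the library insert size; otherwise it is *uncaptured* and contributes
no contig order/orientation information.  Terminal gaps are never classified
(they have only one flank).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import CaptureRule, ContigMap, Gap, Placement, ReadPair, clone_gap

__all__ = [
    "spanning_subclones",
    "count_spanning_subclones",
    "classify_gap",
    "classify_gaps",
    "uncaptured_burden",
    "lift_placement",
    "lift_pairs_to_reference",
]


def spanning_subclones(
    gap: Gap, pairs: Iterable[ReadPair]
) -> list[tuple[ReadPair, int]]:
    """Subclones whose reads flank the gap, with their implied spans.

    A subclone spans the gap when one read ends at or before ``gap.start``
    and the other starts at or after ``gap.end`` (either orientation), both
    on the gap's reference sequence.
    """
    out = []
    for p in pairs:
        if p.fwd.seq_id != gap.sequence_id or p.rev.seq_id != gap.sequence_id:
            continue
        left, right = (p.fwd, p.rev) if p.fwd.start <= p.rev.start else (p.rev, p.fwd)
        if left.end <= gap.start and right.start >= gap.end:
            out.append((p, right.end - left.start))
    return out


def count_spanning_subclones(gap: Gap, pairs: Iterable[ReadPair]) -> int:
    return len(spanning_subclones(gap, pairs))


def classify_gap(
    gap: Gap,
    pairs: Iterable[ReadPair],
    rule: CaptureRule | None = None,
    insert_mean: float | None = None,
    insert_sd: float | None = None,
) -> Gap:
    """Return a copy of ``gap`` with capture status and qualifying count set.

    ``insert_mean`` / ``insert_sd`` default to the (unique) library stats of
    the supplied pairs; classification is rejected if they cannot be
    determined.
    """
    if gap.kind != "internal":
        raise ValueError("only internal gaps are classified")
    rule = rule or CaptureRule()
    pairs = list(pairs)
    if insert_mean is None or insert_sd is None:
        libs = {(p.insert_mean, p.insert_sd) for p in pairs}
        if len(libs) != 1:
            raise ValueError(
                "library insert statistics unset and not inferable from pairs"
            )
        insert_mean, insert_sd = libs.pop()
    max_span = rule.max_span(insert_mean, insert_sd)
    qualifying = [
        span for _, span in spanning_subclones(gap, pairs) if span <= max_span
    ]
    status = "captured" if len(qualifying) >= rule.min_spanning_pairs else "uncaptured"
    return clone_gap(gap, spanning_subclones=len(qualifying), status=status)


def classify_gaps(
    gaps: Sequence[Gap],
    pairs: Sequence[ReadPair],
    rule: CaptureRule | None = None,
    insert_mean: float | None = None,
    insert_sd: float | None = None,
) -> list[Gap]:
    """Classify internal gaps; terminal gaps pass through unclassified."""
    return [
        classify_gap(g, pairs, rule, insert_mean, insert_sd)
        if g.kind == "internal"
        else g
        for g in gaps
    ]


def uncaptured_burden(
    assemblies: Mapping[str, Sequence[Sequence[Gap]]],
    total_mb: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-unit uncaptured-gap burden.

    ``assemblies`` maps a unit (species or region) to its per-BAC lists of
    classified gaps.  Returns one row per unit with the fraction of
    assemblies carrying >= 2 uncaptured gaps (the finishing-difficulty
    criterion), the fraction of internal gaps uncaptured, and - when
    ``total_mb`` is given - captured and uncaptured gaps per Mb.
    """
    rows = []
    for unit, bac_gap_lists in assemblies.items():
        n_asm = len(bac_gap_lists)
        n_cap = n_unc = n_multi = 0
        for gaps in bac_gap_lists:
            internal = [g for g in gaps if g.kind == "internal"]
            if any(g.status == "unset" for g in internal):
                raise ValueError("all internal gaps must be classified")
            unc = sum(g.status == "uncaptured" for g in internal)
            n_unc += unc
            n_cap += sum(g.status == "captured" for g in internal)
            if unc >= 2:
                n_multi += 1
        n_gaps = n_cap + n_unc
        mb = total_mb.get(unit) if total_mb else None
        rows.append(
            {
                "unit": unit,
                "n_assemblies": n_asm,
                "n_gaps": n_gaps,
                "frac_assemblies_ge2_uncaptured": n_multi / n_asm if n_asm else 0.0,
                "frac_gaps_uncaptured": n_unc / n_gaps if n_gaps else 0.0,
                "captured_per_mb": n_cap / mb if mb else float("nan"),
                "uncaptured_per_mb": n_unc / mb if mb else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def lift_placement(p: Placement, cmap: ContigMap) -> Placement | None:
    """Lift a read placement from contig to reference coordinates.

    Returns None when the contig is unmapped or the read falls outside the
    retained (trimmed) aligned block.  Mapping is gapless within a block.
    """
    aln = next((a for a in cmap.placements if a.contig_id == p.seq_id), None)
    if aln is None:
        return None
    if p.start < aln.qstart or p.end > aln.qend:
        return None
    if aln.strand == "+":
        rs = aln.start + (p.start - aln.qstart)
        re = aln.start + (p.end - aln.qstart)
        strand = p.strand
    else:
        rs = aln.start + (aln.qend - p.end)
        re = aln.start + (aln.qend - p.start)
        strand = "-" if p.strand == "+" else "+"
    return Placement(cmap.sequence_id, rs, re, strand)


def lift_pairs_to_reference(
    pairs: Iterable[ReadPair], cmap: ContigMap
) -> list[ReadPair]:
    """Lift contig-coordinate read pairs to the reference through the map.

    Pairs with either mate on an unmapped contig (or outside its retained
    block) are dropped.
    """
    out = []
    for p in pairs:
        fwd = lift_placement(p.fwd, cmap)
        rev = lift_placement(p.rev, cmap)
        if fwd is None or rev is None:
            continue
        out.append(
            ReadPair(
                subclone_id=p.subclone_id,
                fwd=fwd,
                rev=rev,
                insert_mean=p.insert_mean,
                insert_sd=p.insert_sd,
                library_id=p.library_id,
            )
        )
    return out
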