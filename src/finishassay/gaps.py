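"""Gap cataloguing and headline gap statistics.

A gap is a reference interval left uncovered between adjacent placed contigs
(kind ``internal``) or outside the outermost placements (kind ``terminal``).
Terminal gaps are catalogued but excluded from headline statistics by
default: the per-BAC statistics concern gaps *between* ordered contigs, and
the choice is flag-reversible.
"""

from __future__ import annotations

import warnings
from statistics import median_low
from typing import Sequence

from .model import TERMINAL, ContigMap, Gap, GapStats

__all__ = ["call_gaps", "gap_stats", "gap_span_percent", "interval_complement"]


def interval_complement(
    intervals: Sequence[tuple[int, int]], bounds: tuple[int, int]
) -> list[tuple[int, int]]:
    """Complement of sorted disjoint intervals within [lo, hi)."""
    lo, hi = bounds
    out = []
    cursor = lo
    for s, e in intervals:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        out.append((cursor, hi))
    return out


def call_gaps(cmap: ContigMap, reference_length: int) -> list[Gap]:
    """Catalogue internal and terminal gaps from a resolved contig map."""
    cmap.validate()
    gaps: list[Gap] = []
    pl = cmap.placements
    if not pl:
        return gaps
    if pl[0].start > 0:
        gaps.append(
            Gap(cmap.sequence_id, 0, pl[0].start,
                left_contig=TERMINAL, right_contig=pl[0].contig_id, kind="terminal")
        )
    for a, b in zip(pl, pl[1:]):
        if b.start > a.end:
            gaps.append(
                Gap(cmap.sequence_id, a.end, b.start,
                    left_contig=a.contig_id, right_contig=b.contig_id,
                    kind="internal")
            )
    if pl[-1].end < reference_length:
        gaps.append(
            Gap(cmap.sequence_id, pl[-1].end, reference_length,
                left_contig=pl[-1].contig_id, right_contig=TERMINAL,
                kind="terminal")
        )
    return gaps


def gap_stats(
    gaps: Sequence[Gap],
    total_mb: float,
    unit: str = "all",
    include_terminal: bool = False,
) -> GapStats:
    """Per-Mb gap rates and the (lower) median gap size.

    ``total_mb`` is the finished-sequence length of the analyzed unit in Mb.
    """
    if total_mb <= 0:
        raise ValueError("total_mb must be > 0")
    use = [g for g in gaps if include_terminal or g.kind == "internal"]
    sizes = [g.size for g in use]
    return GapStats(
        unit=unit,
        n_gaps=len(use),
        total_mb=total_mb,
        gaps_per_mb=len(use) / total_mb,
        gap_bases_per_mb=sum(sizes) / total_mb,
        median_gap_size=median_low(sizes) if sizes else None,
    )


def gap_span_percent(gap_mb: float, total_mb: float) -> float:
    """Percentage of the total sequence residing in gaps, to one decimal."""
    if total_mb <= 0:
        raise ValueError("total_mb must be > 0")
    if gap_mb < 0:
        raise ValueError("gap_mb must be >= 0")
    if gap_mb > total_mb:
        warnings.warn("gap_mb exceeds total_mb", stacklevel=2)
    return round(100.0 * gap_mb / total_mb, 1)
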