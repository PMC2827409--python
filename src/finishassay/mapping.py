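"""Contig-to-reference alignment and contig-map resolution.

Draft and finished sequence derive from the same clone DNA, so placement only
needs to be near-exact: alignment is a unique-k-mer seed-and-chain scheme.
Reference k-mers occurring exactly once in the reference are matched against
contig k-mers occurring exactly once in the contig (both strands); anchors
sharing a diagonal (within a band) are chained into blocks, blocks are
extended outward by greedy exact extension, and short blocks are dropped.
Contigs yielding two or more mutually non-colinear blocks are putative
misassemblies (split contigs).

Map resolution replaces the manual curation of ambiguous contig endpoints
with a deterministic rule: per contig the highest-scoring block is retained
(score = aligned bp x identity) and reference overlaps between placements are
trimmed from the lower-priority placement (lower identity; tie -> shorter;
still tied -> lexicographically later contig id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import ContigAlignment, ContigMap, DraftContig, FinishedSequence

__all__ = ["align_contigs", "resolve_map", "find_split_contigs"]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    return out


def _unique_kmers(kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted unique codes, their positions) for k-mers occurring once."""
    order = np.argsort(kmers, kind="stable")
    srt = kmers[order]
    if len(srt) == 0:
        return srt, order
    is_uniq = np.ones(len(srt), dtype=bool)
    dup = srt[1:] == srt[:-1]
    is_uniq[1:] &= ~dup
    is_uniq[:-1] &= ~dup
    return srt[is_uniq], order[is_uniq]


@dataclass
class _Block:
    qs: int  # coordinates in the aligned orientation of the contig
    qe: int
    rs: int
    re: int


def _chain_anchors(
    qpos: np.ndarray, rpos: np.ndarray, k: int, band: int, max_anchor_gap: int
) -> list[_Block]:
    if len(qpos) == 0:
        return []
    diag = rpos.astype(np.int64) - qpos.astype(np.int64)
    order = np.lexsort((qpos, diag))
    qpos, rpos, diag = qpos[order], rpos[order], diag[order]
    blocks: list[_Block] = []
    start = 0
    for i in range(1, len(qpos) + 1):
        if (
            i == len(qpos)
            or abs(int(diag[i]) - int(diag[i - 1])) > band
            or int(qpos[i]) - int(qpos[i - 1]) > max_anchor_gap
        ):
            qs, qe = int(qpos[start]), int(qpos[i - 1]) + k
            rs, re = int(rpos[start:i].min()), int(rpos[start:i].max()) + k
            blocks.append(_Block(qs, qe, rs, re))
            start = i
    return blocks


def _extend_exact(
    block: _Block, q_codes: np.ndarray, r_codes: np.ndarray
) -> None:
    """Greedy exact extension of a block to the left and right."""
    left = min(block.qs, block.rs)
    if left:
        a = q_codes[block.qs - left : block.qs][::-1]
        b = r_codes[block.rs - left : block.rs][::-1]
        neq = np.flatnonzero(a != b)
        ext = int(neq[0]) if len(neq) else left
        block.qs -= ext
        block.rs -= ext
    right = min(len(q_codes) - block.qe, len(r_codes) - block.re)
    if right:
        a = q_codes[block.qe : block.qe + right]
        b = r_codes[block.re : block.re + right]
        neq = np.flatnonzero(a != b)
        ext = int(neq[0]) if len(neq) else right
        block.qe += ext
        block.re += ext


def _identity(block: _Block, q_codes: np.ndarray, r_codes: np.ndarray) -> float:
    a = q_codes[block.qs : block.qe]
    b = r_codes[block.rs : block.re]
    return float(np.mean(a == b))


def align_contigs(
    contigs: Sequence[DraftContig] | Mapping[str, str] | Sequence[tuple[str, str]],
    reference: FinishedSequence | str,
    k: int = 31,
    min_block: int = 200,
    *,
    band: int = 50,
    max_anchor_gap: int = 20000,
) -> list[ContigAlignment]:
    """Align draft contigs to the finished reference.

    Returns one :class:`ContigAlignment` per near-gapless block.  A contig
    producing several mutually non-colinear blocks (a putative misassembly)
    contributes all of them; use :func:`find_split_contigs` to list such
    contigs.
    """
    if k % 2 == 0 or not 11 <= k <= 63:
        raise ValueError("k must be odd and in [11, 63]")
    ref_seq = reference.seq if isinstance(reference, FinishedSequence) else reference
    if len(ref_seq) < k:
        raise ValueError("reference shorter than k")
    items = _as_items(contigs)
    if not items:
        raise ValueError("no contigs supplied")

    r_codes = _encode(ref_seq)
    ref_uniq_codes, ref_uniq_pos = _unique_kmers(_kmer_codes(r_codes, k))

    out: list[ContigAlignment] = []
    for cid, cseq in items:
        if len(cseq) < k:
            continue
        c_fwd = _encode(cseq)
        for strand, q_codes in (("+", c_fwd), ("-", _rc_codes(c_fwd))):
            cq_codes, cq_pos = _unique_kmers(_kmer_codes(q_codes, k))
            idx = np.searchsorted(ref_uniq_codes, cq_codes)
            idx = np.clip(idx, 0, len(ref_uniq_codes) - 1)
            hit = (
                ref_uniq_codes[idx] == cq_codes
                if len(ref_uniq_codes)
                else np.zeros(len(cq_codes), dtype=bool)
            )
            qpos = cq_pos[hit]
            rpos = ref_uniq_pos[idx[hit]]
            # chaining is exact-diagonal: draft and reference derive from the
            # same DNA, so true anchors of one block share one diagonal;
            # repeat-shifted anchors must not contaminate a block
            blocks = _chain_anchors(qpos, rpos, k, 0, max_anchor_gap)
            for blk in blocks:
                _extend_exact(blk, q_codes, r_codes)
            blocks = [b for b in blocks if b.qe - b.qs >= min_block]
            seen: set[tuple[int, int, int, int]] = set()
            for blk in blocks:
                key = (blk.qs, blk.qe, blk.rs, blk.re)
                if key in seen:
                    continue
                seen.add(key)
                ident = _identity(blk, q_codes, r_codes)
                if strand == "+":
                    qs, qe = blk.qs, blk.qe
                else:
                    qs, qe = len(cseq) - blk.qe, len(cseq) - blk.qs
                out.append(
                    ContigAlignment(
                        contig_id=cid,
                        start=blk.rs,
                        end=blk.re,
                        qstart=qs,
                        qend=qe,
                        strand=strand,
                        identity=ident,
                    )
                )
    return _drop_contained(out)


def _as_items(contigs) -> list[tuple[str, str]]:
    if isinstance(contigs, Mapping):
        return list(contigs.items())
    items = []
    for c in contigs:
        if isinstance(c, DraftContig):
            items.append((c.id, c.seq))
        else:
            cid, seq = c
            items.append((cid, seq))
    return items


def _drop_contained(alignments: list[ContigAlignment]) -> list[ContigAlignment]:
    """Drop blocks whose reference+query span is contained in a larger block
    of the same contig (arises when both strands anchor a palindromic span)."""
    kept: list[ContigAlignment] = []
    by_contig: dict[str, list[ContigAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig_id, []).append(a)
    for cid, blocks in by_contig.items():
        blocks.sort(key=lambda b: (-(b.ref_span), b.start))
        chosen: list[ContigAlignment] = []
        for b in blocks:
            contained = any(
                b.start >= c.start
                and b.end <= c.end
                and b.qstart >= c.qstart
                and b.qend <= c.qend
                for c in chosen
            )
            if not contained:
                chosen.append(b)
        kept.extend(chosen)
    kept.sort(key=lambda b: (b.start, b.contig_id))
    return kept


def _colinear(a: ContigAlignment, b: ContigAlignment, band: int) -> bool:
    if a.strand != b.strand:
        return False
    if a.strand == "+":
        da = a.start - a.qstart
        db = b.start - b.qstart
        order_ok = (a.qstart <= b.qstart) == (a.start <= b.start)
    else:
        da = a.start + a.qend
        db = b.start + b.qend
        order_ok = (a.qstart <= b.qstart) == (a.start >= b.start)
    return abs(da - db) <= band and order_ok


def find_split_contigs(
    alignments: Iterable[ContigAlignment], band: int = 50
) -> list[str]:
    """Contig ids with >= 2 mutually non-colinear aligned blocks."""
    by_contig: dict[str, list[ContigAlignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig_id, []).append(a)
    split = []
    for cid, blocks in sorted(by_contig.items()):
        if len(blocks) < 2:
            continue
        if any(
            not _colinear(blocks[i], blocks[j], band)
            for i in range(len(blocks))
            for j in range(i + 1, len(blocks))
        ):
            split.append(cid)
    return split


def resolve_map(
    alignments: Sequence[ContigAlignment],
    reference_length: int,
    *,
    sequence_id: str = "ref",
    all_contig_ids: Iterable[str] | None = None,
    band: int = 50,
) -> ContigMap:
    """Resolve alignments into an ordered, disjoint contig map.

    Per contig the highest-scoring block survives; placements then claim
    reference bases in priority order (identity desc, span desc, contig id
    asc), each keeping its longest unclaimed run, which implements pairwise
    trimming of the lower-priority placement.  Contigs with no surviving
    placement are listed in ``unmapped_contigs``.
    """
    split = find_split_contigs(alignments, band=band)

    best: dict[str, ContigAlignment] = {}
    for a in alignments:
        cur = best.get(a.contig_id)
        if (
            cur is None
            or (a.score(), a.ref_span, -a.start) > (cur.score(), cur.ref_span, -cur.start)
        ):
            best[a.contig_id] = a

    order = sorted(
        best.values(), key=lambda a: (-a.identity, -(a.ref_span), a.contig_id)
    )
    claimed = np.zeros(reference_length, dtype=bool)
    placements: list[ContigAlignment] = []
    unmapped: set[str] = set()
    for a in order:
        window = claimed[a.start : a.end]
        free = ~window
        if not free.any():
            unmapped.add(a.contig_id)
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], free, [False]))))
        runs = [
            (int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)
        ]
        rs_off, re_off = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        rs, re = a.start + rs_off, a.start + re_off
        trim_left = rs - a.start
        trim_right = a.end - re
        if a.strand == "+":
            qs, qe = a.qstart + trim_left, a.qend - trim_right
        else:
            qs, qe = a.qstart + trim_right, a.qend - trim_left
        placements.append(
            ContigAlignment(
                contig_id=a.contig_id,
                start=rs,
                end=re,
                qstart=qs,
                qend=qe,
                strand=a.strand,
                identity=a.identity,
            )
        )
        claimed[rs:re] = True

    placements.sort(key=lambda a: a.start)
    if all_contig_ids is not None:
        unmapped |= set(all_contig_ids) - set(best)
    cmap = ContigMap(
        sequence_id=sequence_id,
        placements=placements,
        unmapped_contigs=sorted(unmapped),
        split_contigs=split,
    )
    cmap.validate()
    return cmap
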