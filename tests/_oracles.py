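"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-base bitmaps, double loops,
all-offsets scans) and shares no code with the package internals.
"""

from __future__ import annotations

import math


def complement_bruteforce(intervals, lo, hi):
    """Uncovered sub-intervals of [lo, hi) via a per-base bitmap."""
    covered = [False] * (hi - lo)
    for s, e in intervals:
        for i in range(max(s, lo), min(e, hi)):
            covered[i - lo] = True
    out = []
    start = None
    for i, c in enumerate(covered):
        if not c and start is None:
            start = i
        elif c and start is not None:
            out.append((start + lo, i + lo))
            start = None
    if start is not None:
        out.append((start + lo, hi))
    return out


def spanning_count_bruteforce(gap_start, gap_end, pairs):
    """Naive double-sided scan: subclones with one read wholly at or left of
    the gap start and the other wholly at or right of the gap end.
    Returns a list of (subclone_id, span)."""
    hits = []
    for p in pairs:
        placements = [p.fwd, p.rev]
        for a, b in (placements, placements[::-1]):
            if a.end <= gap_start and b.start >= gap_end:
                span = max(a.end, b.end) - min(a.start, b.start)
                hits.append((p.subclone_id, span))
                break
    return hits


def repeat_fraction_bitmap(intervals_by_class, query, length):
    """Per-class fraction of query bases covered, via per-base bitmaps."""
    qmask = [False] * length
    for s, e in query:
        for i in range(s, e):
            qmask[i] = True
    nq = sum(qmask)
    fracs = {}
    union = [False] * length
    for cls, ivals in intervals_by_class.items():
        mask = [False] * length
        for s, e in ivals:
            for i in range(s, e):
                mask[i] = True
                union[i] = True
        cov = sum(1 for i in range(length) if mask[i] and qmask[i])
        fracs[cls] = cov / nq if nq else float("nan")
    all_cov = sum(1 for i in range(length) if union[i] and qmask[i])
    fracs["All"] = all_cov / nq if nq else float("nan")
    return fracs


def depth_bruteforce(placements, length, strand):
    """Per-base depth by naive counting."""
    depth = [0] * length
    for p in placements:
        if p.strand != strand:
            continue
        for i in range(p.start, p.end):
            depth[i] += 1
    return depth


def tandem_tracts_bruteforce(seq, min_lengths, purity):
    """All-offsets tandem scan with stepwise running-purity extension,
    reimplemented naively; returns the merged union of qualifying tracts."""
    n = len(seq)
    tracts = []
    for m, min_len in min_lengths.items():
        for s in range(n - m):
            good = 0
            best = None
            e = s + m
            while e < n:
                good += seq[e] == seq[e - m]
                if good / (e + 1 - s - m) < purity:
                    break
                e += 1
                if e - s >= min_len:
                    best = e
            if best is not None:
                tracts.append((s, best))
    tracts.sort()
    merged = []
    for s, e in tracts:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def lw_expected_gaps(n_reads, read_len, length):
    """Closed-form expected coverage-gap count, N * exp(-c) with
    c = N * read_len / length (circular-template coverage theory)."""
    c = n_reads * read_len / length
    return n_reads * math.exp(-c)
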