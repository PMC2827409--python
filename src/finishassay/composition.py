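"""GC and repeat-class composition of gap versus total sequence.

Gap composition is always read from the finished reference within the gap
interval (the draft, by construction, lacks those bases).  Repeat fractions
are computed against a flattened, class-disjoint annotation; when real
RepeatMasker annotation is ingested, overlaps between classes are resolved
by the priority order Simple > LINE > SINE > LTR > DNA before any fraction
is computed.  Confidence intervals are percentile bootstraps resampling BAC
units with replacement, matching the per-BAC structure of the data.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CompositionProfile,
    FinishedSequence,
    Gap,
    RepeatAnnotation,
    REPEAT_CLASSES,
)

__all__ = [
    "gc_content",
    "find_simple_repeats",
    "flatten_annotation",
    "repeat_fractions",
    "composition_ci",
    "merge_intervals",
    "overlap_bases",
    "SIMPLE_MIN_LENGTHS",
]

#: Default minimum tract lengths (bp) per motif size for the simple-repeat
#: finder.  Stated defaults of this implementation, not literature values.
SIMPLE_MIN_LENGTHS = {1: 12, 2: 20, 3: 21, 4: 24}


def _seq_of(reference: FinishedSequence | str) -> str:
    return reference.seq if isinstance(reference, FinishedSequence) else reference


def gc_content(
    reference: FinishedSequence | str,
    intervals: Sequence[tuple[int, int]] | None = None,
) -> float:
    """(#G + #C) / total bases over the given intervals (whole sequence when
    None).  NaN when the intervals cover zero bases."""
    seq = _seq_of(reference)
    if intervals is None:
        intervals = [(0, len(seq))]
    total = gc = 0
    for s, e in intervals:
        if not 0 <= s <= e <= len(seq):
            raise ValueError(f"interval ({s}, {e}) out of bounds")
        chunk = seq[s:e]
        gc += chunk.count("G") + chunk.count("C")
        total += e - s
    return gc / total if total else float("nan")


def find_simple_repeats(
    sequence: str,
    min_lengths: Mapping[int, int] | None = None,
    purity: float = 0.9,
) -> list[tuple[int, int]]:
    """Maximal tandem tracts of motif size 1-4.

    For every start offset and motif size ``m`` the tract is extended to the
    right one base at a time while the running purity - the fraction of
    positions ``i`` in the tract body with ``seq[i] == seq[i - m]`` - stays
    at or above ``purity``.  Tracts meeting the per-motif-size minimum
    length qualify; overlapping qualifying tracts are merged.
    """
    if not sequence:
        raise ValueError("empty sequence")
    min_lengths = dict(min_lengths or SIMPLE_MIN_LENGTHS)
    n = len(sequence)
    found: list[tuple[int, int]] = []
    for m, min_len in sorted(min_lengths.items()):
        if n <= m:
            continue
        match = [sequence[i] == sequence[i - m] for i in range(m, n)]
        s = 0
        while s < n - m:
            if not match[s]:
                s += 1
                continue
            good = 0
            e = s + m
            best_e = -1
            while e < n:
                good += match[e - m]
                body = e + 1 - (s + m)
                if good / body < purity:
                    break
                e += 1
                if e - s >= min_len:
                    best_e = e
            if best_e > 0:
                found.append((s, best_e))
            s += 1
    return merge_intervals(found)


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals (merging overlapping and abutting ones)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def overlap_bases(
    sorted_intervals: Sequence[tuple[int, int]],
    query: Sequence[tuple[int, int]],
) -> int:
    """Total bases of ``query`` covered by the (disjoint, sorted) intervals."""
    total = 0
    for qs, qe in query:
        for s, e in sorted_intervals:
            if s >= qe:
                break
            if e <= qs:
                continue
            total += min(e, qe) - max(s, qs)
    return total


def flatten_annotation(
    annotation: RepeatAnnotation,
    priority: Sequence[str] = REPEAT_CLASSES,
) -> RepeatAnnotation:
    """Resolve inter-class overlaps so classes are disjoint.

    Bases claimed by a higher-priority class are subtracted from
    lower-priority intervals; intervals within one class are unioned.
    """
    claimed: list[tuple[int, int]] = []
    flat: list[tuple[int, int, str]] = []
    for cls in priority:
        merged = merge_intervals(annotation.by_class(cls))
        for s, e in merged:
            cursor = s
            for cs, ce in claimed:
                if cs >= e:
                    break
                if ce <= cursor:
                    continue
                if cs > cursor:
                    flat.append((cursor, cs, cls))
                cursor = max(cursor, ce)
            if cursor < e:
                flat.append((cursor, e, cls))
        claimed = merge_intervals(claimed + merged)
    out = RepeatAnnotation(annotation.sequence_id, sorted(flat))
    out.validate()
    return out


def repeat_fractions(
    annotation: RepeatAnnotation,
    intervals: Sequence[tuple[int, int]],
    scope: str = "total",
    unit: str = "all",
    reference: FinishedSequence | str | None = None,
) -> CompositionProfile:
    """Fraction of interval bases annotated as each repeat class.

    ``All`` (union over classes) is stored under key ``"All"``.  GC content
    is filled when a reference sequence is supplied.  The annotation must be
    flattened (class-disjoint); see :func:`flatten_annotation`.
    """
    annotation.validate()
    n_bases = sum(e - s for s, e in intervals)
    fractions: dict[str, tuple[float, float | None, float | None]] = {}
    all_cov = 0
    for cls in REPEAT_CLASSES:
        cov = overlap_bases(annotation.by_class(cls), intervals)
        all_cov += cov
        fractions[cls] = (cov / n_bases if n_bases else float("nan"), None, None)
    fractions["All"] = (all_cov / n_bases if n_bases else float("nan"), None, None)
    gc = gc_content(reference, list(intervals)) if reference is not None else float("nan")
    return CompositionProfile(
        unit=unit, scope=scope, n_bases=n_bases, gc=gc, repeat_fraction=fractions
    )


def composition_ci(
    values: Sequence[float],
    weights: Sequence[float],
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float | None, float | None]:
    """Base-weighted pooled fraction with a percentile-bootstrap 95% CI.

    The resampling unit is the BAC: ``values`` are per-BAC fractions and
    ``weights`` their base counts.  Units are sorted before resampling so
    the result is invariant to input order under a fixed seed.  With a
    single unit the CI is undefined (None bounds).
    """
    if len(values) != len(weights) or not values:
        raise ValueError("values and weights must be equal-length and non-empty")
    pairs = sorted(zip(values, weights))
    v = np.array([p[0] for p in pairs], dtype=float)
    w = np.array([p[1] for p in pairs], dtype=float)
    if w.sum() <= 0:
        raise ValueError("total weight must be > 0")
    point = float(np.average(v, weights=w))
    if len(v) < 2:
        return point, None, None
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(reps, len(v)))
    num = (v[idx] * w[idx]).sum(axis=1)
    den = w[idx].sum(axis=1)
    boots = num / den
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(lo), float(hi)


def gap_composition_profiles(
    reference: FinishedSequence,
    annotation: RepeatAnnotation,
    gaps: Sequence[Gap],
    unit: str = "all",
) -> dict[str, CompositionProfile]:
    """Profiles for the four scopes of one BAC: total sequence, all internal
    gaps, captured gaps, uncaptured gaps."""
    internal = [g for g in gaps if g.kind == "internal"]
    scopes = {
        "total": [(0, reference.length)],
        "all_gaps": [g.interval for g in internal],
        "captured_gaps": [g.interval for g in internal if g.status == "captured"],
        "uncaptured_gaps": [g.interval for g in internal if g.status == "uncaptured"],
    }
    return {
        scope: repeat_fractions(annotation, ivals, scope, unit, reference)
        for scope, ivals in scopes.items()
    }
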