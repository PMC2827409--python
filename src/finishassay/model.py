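"""Core domain types for the finishing-effort assay.

Coordinates are 0-based, half-open throughout, on the finished (human-grade)
reference unless a type says otherwise.  A "BAC" is the unit of analysis: one
finished reference sequence plus the draft (comparative-grade) assembly and
shotgun read pairs derived from the same clone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "REPEAT_CLASSES",
    "SCORE_LEVELS",
    "FinishedSequence",
    "RepeatAnnotation",
    "BiasRegion",
    "BiasModel",
    "Placement",
    "ReadPlacement",
    "ReadPair",
    "SyntheticTruth",
    "DraftContig",
    "DraftAssembly",
    "ContigAlignment",
    "ContigMap",
    "Gap",
    "GapStats",
    "CaptureRule",
    "CompositionProfile",
    "RedundancyProfile",
    "BacResult",
]

#: Repeat classes tracked by the assay, in flattening priority order: when a
#: base is annotated by more than one class, the earlier class wins.
REPEAT_CLASSES = ("Simple", "LINE", "SINE", "LTR", "DNA")

#: Ordinal redundancy-variation scale, from uniform coverage to severe troughs.
SCORE_LEVELS = ("-", "+", "++", "++++")

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class FinishedSequence:
    """A human-grade finished reference sequence with clone metadata."""

    id: str
    seq: str
    species: str = "synthetic"
    region: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        if not _ALPHABET.issuperset(self.seq):
            bad = sorted(set(self.seq) - _ALPHABET)
            raise ValueError(f"sequence contains non-ACGT characters: {bad}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class RepeatAnnotation:
    """Flattened (class-disjoint) repeat intervals on one sequence.

    ``intervals`` holds ``(start, end, cls)`` tuples with ``cls`` drawn from
    :data:`REPEAT_CLASSES`.  Intervals of *different* classes must not overlap
    once flattened; use :func:`finishassay.composition.flatten_annotation` to
    enforce that on raw annotations.
    """

    sequence_id: str
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def validate(self, length: int | None = None) -> None:
        prev_end = -1
        for start, end, cls in sorted(self.intervals):
            if cls not in REPEAT_CLASSES:
                raise ValueError(f"unknown repeat class {cls!r}")
            if not (0 <= start < end):
                raise ValueError(f"bad interval ({start}, {end})")
            if length is not None and end > length:
                raise ValueError(f"interval ({start}, {end}) exceeds length {length}")
            if start < prev_end:
                raise ValueError("annotation intervals overlap; flatten first")
            prev_end = end

    def by_class(self, cls: str) -> list[tuple[int, int]]:
        return sorted((s, e) for s, e, c in self.intervals if c == cls)

    def total_bases(self) -> int:
        return sum(e - s for s, e, _ in self.intervals)


class BiasRegion(NamedTuple):
    start: int
    end: int
    viability: float


@dataclass
class BiasModel:
    """Region-specific subclone viability under a given cloning host.

    ``viability`` is the probability that a subclone whose insert overlaps the
    region survives propagation in the standard host.  Under a copy-control
    host the depression is partially rescued:
    ``v' = v + copy_control_rescue * (1 - v)``.
    """

    regions: list[BiasRegion] = field(default_factory=list)
    host: str = "standard"
    copy_control_rescue: float = 1.0

    def __post_init__(self) -> None:
        if self.host not in ("standard", "copy_control"):
            raise ValueError(f"unknown host {self.host!r}")
        if not 0.0 <= self.copy_control_rescue <= 1.0:
            raise ValueError("copy_control_rescue must be in [0, 1]")
        for r in self.regions:
            if not 0.0 <= r.viability <= 1.0:
                raise ValueError("viability must be in [0, 1]")

    def viability_of(self, start: int, end: int) -> float:
        """Effective survival probability of an insert spanning [start, end)."""
        v = 1.0
        for r in self.regions:
            if start < r.end and r.start < end:
                v = min(v, r.viability)
        if self.host == "copy_control":
            v = v + self.copy_control_rescue * (1.0 - v)
        return v

    def with_host(self, host: str) -> "BiasModel":
        return BiasModel(list(self.regions), host, self.copy_control_rescue)


class Placement(NamedTuple):
    """One read placed on a sequence (reference or contig)."""

    seq_id: str
    start: int
    end: int
    strand: str


class ReadPlacement(NamedTuple):
    """A read placement row as written to the 8-column placement TSV."""

    read_id: str
    subclone_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    mate_id: str
    library_id: str


@dataclass(frozen=True)
class ReadPair:
    """Forward- and reverse-primed reads from the two ends of one subclone."""

    subclone_id: str
    fwd: Placement
    rev: Placement
    insert_mean: float
    insert_sd: float
    library_id: str = "lib1"

    def __post_init__(self) -> None:
        for p in (self.fwd, self.rev):
            if not 0 <= p.start < p.end:
                raise ValueError(f"bad placement {p}")
        if self.fwd.seq_id == self.rev.seq_id and self.fwd.strand == self.rev.strand:
            raise ValueError("mates on one sequence must be on opposite strands")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated draft assembly."""

    true_gaps: list[tuple[int, int]]
    bias_regions: list[BiasRegion]
    planted_repeats: RepeatAnnotation
    seed: int

    def __post_init__(self) -> None:
        gaps = self.true_gaps
        if gaps != sorted(gaps) or any(
            gaps[i][1] > gaps[i + 1][0] for i in range(len(gaps) - 1)
        ):
            raise ValueError("true_gaps must be disjoint and sorted")


@dataclass
class DraftContig:
    """A draft contig with (hidden) placement truth for testing.

    ``true_start``/``true_end``/``true_flipped`` record where the contig came
    from on the reference; the mapping stage never reads them.
    """

    id: str
    seq: str
    true_start: int
    true_end: int
    true_flipped: bool = False
    chimeric: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class DraftAssembly:
    reference_id: str
    contigs: list[DraftContig]
    contig_placements: list[ReadPlacement]


@dataclass
class ContigAlignment:
    """One near-gapless aligned block of a contig on the reference."""

    contig_id: str
    start: int
    end: int
    qstart: int
    qend: int
    strand: str
    identity: float

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("empty reference interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def ref_span(self) -> int:
        return self.end - self.start

    def score(self) -> float:
        return self.ref_span * self.identity


@dataclass
class ContigMap:
    """Ordered, oriented, overlap-trimmed contig placements on one reference."""

    sequence_id: str
    placements: list[ContigAlignment]
    unmapped_contigs: list[str] = field(default_factory=list)
    split_contigs: list[str] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        prev_end = -1
        for p in self.placements:
            if p.contig_id in seen:
                raise ValueError(f"contig {p.contig_id} placed twice")
            seen.add(p.contig_id)
            if p.start < prev_end:
                raise ValueError("placements overlap or are unsorted")
            prev_end = p.end


#: Sentinel flank for terminal gaps.
TERMINAL = "<terminal>"


@dataclass
class Gap:
    """An uncovered reference interval between (or outside) placed contigs."""

    sequence_id: str
    start: int
    end: int
    left_contig: str = TERMINAL
    right_contig: str = TERMINAL
    kind: str = "internal"
    spanning_subclones: int = -1
    status: str = "unset"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("gap size must be >= 1")
        if self.kind not in ("internal", "terminal"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.kind == "internal":
            if TERMINAL in (self.left_contig, self.right_contig):
                raise ValueError("internal gap needs both flanking contigs")
        else:
            flanks = (self.left_contig, self.right_contig)
            if sum(f == TERMINAL for f in flanks) != 1:
                raise ValueError("terminal gap has exactly one flanking contig")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class GapStats:
    """Figure-style headline gap statistics for one analysis unit."""

    unit: str
    n_gaps: int
    total_mb: float
    gaps_per_mb: float
    gap_bases_per_mb: float
    median_gap_size: int | None  # None when there are no gaps


@dataclass
class CaptureRule:
    """Decision rule for captured vs uncaptured gaps.

    A gap is captured when at least ``min_spanning_pairs`` subclones span it
    with an implied span not greatly exceeding the library insert size.  The
    span ceiling is either ``insert_mean + k_sd * insert_sd`` (mode ``"sd"``)
    or ``multiplier * insert_mean`` (mode ``"multiplier"``).
    """

    min_spanning_pairs: int = 2
    mode: str = "sd"
    k_sd: float = 3.0
    multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.min_spanning_pairs < 1:
            raise ValueError("min_spanning_pairs must be >= 1")
        if self.mode not in ("sd", "multiplier"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def max_span(self, insert_mean: float, insert_sd: float) -> float:
        if self.mode == "sd":
            return insert_mean + self.k_sd * insert_sd
        return self.multiplier * insert_mean


@dataclass
class CompositionProfile:
    """GC and repeat-class composition of a set of intervals, with CIs.

    ``scope`` is one of total / all_gaps / captured_gaps / uncaptured_gaps.
    CI bounds are None when only one unit contributed.
    """

    unit: str
    scope: str
    n_bases: int
    gc: float
    gc_ci: tuple[float, float] | None = None
    repeat_fraction: dict[str, tuple[float, float | None, float | None]] = field(
        default_factory=dict
    )


@dataclass
class RedundancyProfile:
    """Per-base, per-strand read depth along one contig."""

    contig_id: str
    upper: np.ndarray
    lower: np.ndarray
    window_cv: list[tuple[int, float]] = field(default_factory=list)
    summary_cv: float | None = None
    score: str | None = None

    @property
    def total(self) -> np.ndarray:
        return self.upper + self.lower


@dataclass
class BacResult:
    """Per-BAC results bundle consumed by the reporting stage."""

    bac_id: str
    species: str
    region: str
    finished_length: int
    gaps: list[Gap]
    redundancy_score: str | None = None
    summary_cv: float | None = None


def clone_gap(gap: Gap, **changes) -> Gap:
    """Return a copy of ``gap`` with fields replaced."""
    return replace(gap, **changes)
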