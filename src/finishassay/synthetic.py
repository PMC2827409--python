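"""Synthetic BAC shotgun data with known gap truth.

The generator emulates the statistical structure of a BAC finishing project:
~165 kb finished references carrying interspersed (LINE/SINE/LTR/DNA) and
simple repeats plus GC-rich islands; paired-end shotgun reads from 3-5 kb
plasmid subclones at >= 8-fold redundancy; region-specific subclone-viability
bias (clone-"poisonous" DNA) producing coverage troughs; and draft assemblies
whose contigs are maximal covered reference intervals, with exact gap truth.

Drafts are derived from coverage truth rather than by running an assembler:
the object of study is the gap structure of the assembly, and deriving
contigs from the coverage vector keeps the truth exact.  No base-level
sequencing-error model is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import (
    BiasModel,
    BiasRegion,
    DraftAssembly,
    DraftContig,
    FinishedSequence,
    Placement,
    ReadPair,
    ReadPlacement,
    RepeatAnnotation,
    SyntheticTruth,
    REPEAT_CLASSES,
)

__all__ = [
    "PlantedRepeat",
    "RandomRepeats",
    "RepeatConfig",
    "GCIsland",
    "GCIslandConfig",
    "generate_reference",
    "simulate_shotgun",
    "build_draft",
    "revcomp",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Divergence between interspersed-repeat copies of one class (substitutions
#: per base relative to the class template).
_COPY_DIVERGENCE = 0.05


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """n base characters (uint8) with independent per-base GC probability."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


@dataclass(frozen=True)
class PlantedRepeat:
    """One repeat tract placed at a fixed offset.

    For Simple repeats give ``motif`` and ``copies`` (length = len(motif) *
    copies); for interspersed classes give ``length``.
    """

    cls: str
    start: int
    length: int | None = None
    motif: str | None = None
    copies: int | None = None

    def span(self) -> int:
        if self.cls == "Simple":
            if self.motif is None or self.copies is None:
                raise ValueError("Simple repeat needs motif and copies")
            return len(self.motif) * self.copies
        if self.length is None:
            raise ValueError(f"{self.cls} repeat needs a length")
        return self.length


@dataclass(frozen=True)
class RandomRepeats:
    """Randomly placed repeats of one class: count and length distribution."""

    cls: str
    count: int
    length_mean: float
    length_sd: float = 0.0
    #: Fraction of tracts whose position is drawn inside bias regions (when a
    #: bias model is supplied); models clone-toxic repeat-rich DNA.
    in_bias_fraction: float = 0.0


@dataclass(frozen=True)
class RepeatConfig:
    planted: tuple[PlantedRepeat, ...] = ()
    random: tuple[RandomRepeats, ...] = ()


@dataclass(frozen=True)
class GCIsland:
    start: int
    length: int
    gc: float


@dataclass(frozen=True)
class GCIslandConfig:
    planted: tuple[GCIsland, ...] = ()
    count: int = 0
    length: int = 2000
    gc: float = 0.8


_SIMPLE_MIN_LEN = {1: 12, 2: 20, 3: 21, 4: 24}


def _draw_simple_motif(rng: np.random.Generator) -> str:
    """A non-degenerate motif of size 1-4 (no motif that collapses to a
    shorter period, e.g. 'AA')."""
    while True:
        m = int(rng.integers(1, 5))
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, size=m))
        if all(motif[: d] * (m // d) != motif for d in range(1, m) if m % d == 0):
            return motif


def _place_features(
    length: int,
    spans: list[int],
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    windows: list[tuple[int, int]] | None = None,
    max_tries: int = 200,
) -> list[int]:
    """Draw non-overlapping start positions for feature spans.

    ``windows`` restricts candidate positions (used to enrich repeats inside
    bias regions); None means the whole sequence.
    """
    starts = []
    for span in spans:
        placed = False
        for attempt in range(max_tries):
            # preferential windows are a soft constraint: after half the
            # tries fall back to anywhere on the sequence
            if windows and attempt < max_tries // 2:
                ws, we = windows[int(rng.integers(len(windows)))]
                lo, hi = ws, max(ws + 1, we - span)
            else:
                lo, hi = 0, length - span
            if hi <= lo:
                continue
            s = int(rng.integers(lo, hi))
            if s + span > length:
                continue
            if all(s + span <= a or s >= b for a, b in occupied):
                occupied.append((s, s + span))
                starts.append(s)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place a {span} bp feature without overlap; "
                "configured repeats exceed available sequence"
            )
    return starts


def generate_reference(
    length: int,
    gc_target: float = 0.41,
    repeat_config: RepeatConfig | None = None,
    gc_island_config: GCIslandConfig | None = None,
    seed: int = 0,
    *,
    sequence_id: str = "ref",
    species: str = "synthetic",
    region: str = "synthetic",
    bias: BiasModel | None = None,
) -> tuple[FinishedSequence, RepeatAnnotation]:
    """Generate a finished reference sequence and its repeat annotation.

    The background is i.i.d. bases at ``gc_target``; planted features (repeat
    tracts, GC islands) are mutually non-overlapping and recorded exactly.
    ``bias`` is only consulted for repeat placement windows (see
    :class:`RandomRepeats.in_bias_fraction`); it does not alter the sequence.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seq = _random_bases(length, gc_target, rng)

    repeat_config = repeat_config or RepeatConfig()
    gc_island_config = gc_island_config or GCIslandConfig()

    occupied: list[tuple[int, int]] = []
    annotation: list[tuple[int, int, str]] = []

    # GC islands first (fixed then random positions).
    islands = list(gc_island_config.planted)
    for isl in islands:
        if isl.start + isl.length > length:
            raise ValueError("GC island exceeds sequence length")
        occupied.append((isl.start, isl.start + isl.length))
    if gc_island_config.count:
        starts = _place_features(
            length, [gc_island_config.length] * gc_island_config.count, rng, occupied
        )
        islands += [
            GCIsland(s, gc_island_config.length, gc_island_config.gc) for s in starts
        ]
    for isl in islands:
        seq[isl.start : isl.start + isl.length] = _random_bases(
            isl.length, isl.gc, rng
        )

    # Interspersed-repeat class templates: copies of one class are divergent
    # copies of a shared template, as in a real repeat library.
    templates: dict[str, np.ndarray] = {}

    def template(cls: str, min_len: int) -> np.ndarray:
        t = templates.get(cls)
        if t is None or len(t) < min_len:
            t_rng = np.random.default_rng((seed, REPEAT_CLASSES.index(cls) + 1))
            templates[cls] = _random_bases(max(min_len, 8000), 0.42, t_rng)
        return templates[cls]

    def write_repeat(cls: str, start: int, span: int, motif: str | None) -> None:
        if cls == "Simple":
            assert motif is not None
            tract = (motif * (span // len(motif) + 1))[:span]
            seq[start : start + span] = np.frombuffer(
                tract.encode(), dtype=np.uint8
            )
        else:
            copy = template(cls, span)[:span].copy()
            nmut = rng.binomial(span, _COPY_DIVERGENCE)
            if nmut:
                pos = rng.choice(span, size=nmut, replace=False)
                copy[pos] = _BASES[rng.integers(0, 4, size=nmut)]
            seq[start : start + span] = copy
        annotation.append((start, start + span, cls))

    for pr in repeat_config.planted:
        if pr.cls not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {pr.cls!r}")
        span = pr.span()
        if pr.start + span > length:
            raise ValueError(
                f"planted {pr.cls} repeat at {pr.start} (+{span} bp) exceeds "
                f"sequence length {length}"
            )
        if any(pr.start + span > a and pr.start < b for a, b in occupied):
            raise ValueError("planted repeat overlaps another feature")
        occupied.append((pr.start, pr.start + span))
        write_repeat(pr.cls, pr.start, span, pr.motif)

    bias_windows = (
        [(r.start, r.end) for r in bias.regions] if bias and bias.regions else None
    )
    for rr in repeat_config.random:
        if rr.cls not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {rr.cls!r}")
        for _ in range(rr.count):
            if rr.cls == "Simple":
                motif = _draw_simple_motif(rng)
                min_copies = math.ceil(_SIMPLE_MIN_LEN[len(motif)] / len(motif))
                mean_copies = max(min_copies, rr.length_mean / len(motif))
                copies = max(
                    min_copies,
                    int(round(rng.normal(mean_copies, rr.length_sd / len(motif))))
                    if rr.length_sd
                    else int(round(mean_copies)),
                )
                span = len(motif) * copies
            else:
                motif = None
                span = max(
                    50, int(round(rng.normal(rr.length_mean, rr.length_sd)))
                )
            windows = (
                bias_windows
                if bias_windows and rng.random() < rr.in_bias_fraction
                else None
            )
            start = _place_features(length, [span], rng, occupied, windows)[0]
            write_repeat(rr.cls, start, span, motif)

    ref = FinishedSequence(
        id=sequence_id,
        seq=seq.tobytes().decode(),
        species=species,
        region=region,
    )
    ann = RepeatAnnotation(sequence_id=sequence_id, intervals=sorted(annotation))
    ann.validate(length)
    return ref, ann


def expected_pairs(length: int, redundancy: float, read_len: int) -> int:
    """Read-pair count giving ``redundancy``-fold read coverage."""
    return int(round(redundancy * length / (2 * read_len)))


def simulate_shotgun(
    ref: FinishedSequence,
    redundancy: float = 8.0,
    read_len: int = 800,
    insert_mean: float = 4000.0,
    insert_sd: float = 400.0,
    bias: BiasModel | None = None,
    seed: int = 0,
    *,
    circular: bool = False,
) -> list[ReadPair]:
    """Simulate paired-end shotgun reads with cloning-viability bias.

    Subclone midpoints are uniform over the reference; each candidate
    subclone is accepted with probability equal to the effective viability
    of its insert interval (1.0 outside bias regions; copy-control hosts
    rescue a fraction of the depression).  Insert sizes follow a normal
    truncated at ``read_len + 1``.  The accepted pair count is exactly
    ``round(redundancy * length / (2 * read_len))``.

    With ``circular=True`` the template is treated as the circular clone
    molecule it models: subclones may span the coordinate origin and a
    wrapped placement is emitted with ``end > length`` (coordinates modulo
    the length).  In the default linear mode inserts are confined to the
    sequence, which leaves mild edge undercoverage within about one insert
    length of each end - the behaviour of a vector-trimmed linear
    coordinate system.
    """
    if redundancy <= 0:
        raise ValueError("redundancy must be > 0")
    if insert_sd < 0:
        raise ValueError("insert_sd must be >= 0")
    if read_len >= insert_mean:
        raise ValueError("read_len must be < insert_mean")
    length = ref.length
    n_pairs = expected_pairs(length, redundancy, read_len)
    if n_pairs < 1:
        raise ValueError("parameters imply fewer than one read pair")
    bias = bias or BiasModel()
    rng = np.random.default_rng(seed)
    lo = read_len + 1
    a = (lo - insert_mean) / insert_sd if insert_sd > 0 else -np.inf

    accepted: list[tuple[int, int, bool]] = []  # (start, insert, flipped)
    while len(accepted) < n_pairs:
        need = n_pairs - len(accepted)
        if insert_sd > 0:
            ins = stats.truncnorm.rvs(
                a, np.inf, loc=insert_mean, scale=insert_sd, size=need, random_state=rng
            )
        else:
            ins = np.full(need, float(insert_mean))
        ins = np.minimum(np.rint(ins).astype(int), length)
        if circular:
            mid = rng.random(need) * length
            start = np.rint(mid - ins / 2).astype(int) % length
        else:
            mid = ins / 2 + rng.random(need) * (length - ins)
            start = np.rint(mid - ins / 2).astype(int)
            start = np.clip(start, 0, length - ins)
        flipped = rng.random(need) < 0.5
        u = rng.random(need)
        for s, i, f, ui in zip(start, ins, flipped, u):
            s, i = int(s), int(i)
            if s + i <= length:
                v = bias.viability_of(s, s + i)
            else:  # wrapped insert: both arcs consulted
                v = min(
                    bias.viability_of(s, length),
                    bias.viability_of(0, s + i - length),
                )
            if ui < v:
                accepted.append((s, i, bool(f)))

    def norm(a: int, b: int, strand: str) -> Placement:
        if circular and a >= length:
            a, b = a - length, b - length
        return Placement(ref.id, a, b, strand)

    pairs: list[ReadPair] = []
    for idx, (s, ins, flipped) in enumerate(accepted):
        left = norm(s, s + read_len, "+")
        right = norm(s + ins - read_len, s + ins, "-")
        if flipped:
            left = left._replace(strand="-")
            right = right._replace(strand="+")
            fwd, rev = right, left
        else:
            fwd, rev = left, right
        pairs.append(
            ReadPair(
                subclone_id=f"sc{idx:05d}",
                fwd=fwd,
                rev=rev,
                insert_mean=insert_mean,
                insert_sd=insert_sd,
            )
        )
    return pairs


def read_placements(pairs: list[ReadPair]) -> list[ReadPlacement]:
    """Flatten pairs into 8-column placement rows (reference coordinates)."""
    rows = []
    for p in pairs:
        fid, rid = p.subclone_id + ".f", p.subclone_id + ".r"
        rows.append(
            ReadPlacement(fid, p.subclone_id, p.fwd.seq_id, p.fwd.start, p.fwd.end,
                          p.fwd.strand, rid, p.library_id)
        )
        rows.append(
            ReadPlacement(rid, p.subclone_id, p.rev.seq_id, p.rev.start, p.rev.end,
                          p.rev.strand, fid, p.library_id)
        )
    return rows


def coverage_depth(pairs: list[ReadPair], length: int) -> np.ndarray:
    """Per-base read depth (both strands) on the reference.

    Placements with ``end > length`` (circular mode) wrap around the origin.
    """
    diff = np.zeros(length + 1, dtype=np.int32)
    for p in pairs:
        for pl in (p.fwd, p.rev):
            if pl.end <= length:
                diff[pl.start] += 1
                diff[pl.end] -= 1
            else:
                diff[pl.start] += 1
                diff[length] -= 1
                diff[0] += 1
                diff[pl.end - length] -= 1
    return np.cumsum(diff[:-1])


def _covered_islands(depth: np.ndarray, min_depth: int) -> list[tuple[int, int]]:
    covered = depth >= min_depth
    edges = np.flatnonzero(np.diff(np.concatenate(([False], covered, [False]))))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def build_draft(
    ref: FinishedSequence,
    pairs: list[ReadPair],
    min_contig: int = 2000,
    min_depth: int = 1,
    *,
    shuffle: bool = False,
    chimera: bool = False,
    circular: bool = False,
    bias: BiasModel | None = None,
    annotation: RepeatAnnotation | None = None,
    seed: int = 0,
) -> tuple[DraftAssembly, SyntheticTruth]:
    """Derive a draft assembly and its gap truth from simulated coverage.

    Contigs are maximal reference intervals with read depth >= ``min_depth``;
    intervals shorter than ``min_contig`` are discarded.  ``true_gaps`` is
    the complement of the retained contig intervals within [first retained
    start, last retained end).  With ``shuffle`` the emitted contig order is
    permuted and each contig is reverse-complemented with probability 1/2
    (truth recorded per contig).  With ``chimera`` the two largest retained
    intervals are additionally joined into one chimeric contig record,
    replacing them, to exercise split-contig detection.
    """
    depth = coverage_depth(pairs, ref.length)
    islands = _covered_islands(depth, min_depth)
    if circular and len(islands) > 1 and islands[0][0] == 0 and islands[-1][1] == ref.length:
        # merge the origin-spanning island: last wraps into first
        islands = [(islands[-1][0], islands[0][1] + ref.length)] + islands[1:-1]
        islands.sort()
    retained = [(s, e) for s, e in islands if e - s >= min_contig]
    if not retained:
        raise ValueError(
            f"no covered interval reaches min_contig={min_contig}; "
            "increase redundancy or lower the threshold"
        )
    if circular:
        true_gaps = []
        for i, (s, e) in enumerate(retained):
            next_s = retained[i + 1][0] if i + 1 < len(retained) else retained[0][0] + ref.length
            if e < next_s:
                gap = (e, next_s)
                if gap[0] >= ref.length:
                    gap = (gap[0] - ref.length, gap[1] - ref.length)
                true_gaps.append(gap)
        true_gaps.sort()
        first, last = 0, ref.length
    else:
        first, last = retained[0][0], retained[-1][1]
        true_gaps = [
            (retained[i][1], retained[i + 1][0]) for i in range(len(retained) - 1)
        ]

    rng = np.random.default_rng(seed)
    pieces: list[tuple[list[tuple[int, int]], bool]] = [([iv], False) for iv in retained]
    if chimera and len(retained) >= 2:
        by_size = sorted(range(len(retained)), key=lambda i: retained[i][1] - retained[i][0])
        i, j = sorted(by_size[-2:])
        joined = ([retained[i], retained[j]], True)
        pieces = [p for k, p in enumerate(pieces) if k not in (i, j)]
        pieces.append(joined)
        pieces.sort(key=lambda p: p[0][0])

    order = list(range(len(pieces)))
    flips = [False] * len(pieces)
    if shuffle:
        order = list(rng.permutation(len(pieces)))
        flips = list(rng.random(len(pieces)) < 0.5)

    contigs: list[DraftContig] = []
    # contig-coordinate segment table: contig -> list of (ref_s, ref_e, offset)
    segments: dict[str, tuple[list[tuple[int, int, int]], bool]] = {}
    for out_idx, piece_idx in enumerate(order):
        intervals, is_chimera = pieces[piece_idx]
        cid = f"{ref.id}_ctg{out_idx:04d}"
        flipped = bool(flips[out_idx])
        parts = [
            ref.seq[s:e] if e <= ref.length else ref.seq[s:] + ref.seq[: e - ref.length]
            for s, e in intervals
        ]
        seq = "".join(parts)
        segs, off = [], 0
        for s, e in intervals:
            segs.append((s, e, off))
            off += e - s
        if flipped:
            seq = revcomp(seq)
        contigs.append(
            DraftContig(
                id=cid,
                seq=seq,
                true_start=intervals[0][0],
                true_end=intervals[-1][1],
                true_flipped=flipped,
                chimeric=is_chimera,
            )
        )
        segments[cid] = (segs, flipped)

    # Lift read placements from reference to contig coordinates.
    contig_placements: list[ReadPlacement] = []
    for row in read_placements(pairs):
        for cid, (segs, flipped) in segments.items():
            clen = sum(e - s for s, e, _ in segs)
            for s, e, off in segs:
                if row.start >= s and row.end <= e:
                    cs, ce = row.start - s + off, row.end - s + off
                    strand = row.strand
                    if flipped:
                        cs, ce = clen - ce, clen - cs
                        strand = "-" if strand == "+" else "+"
                    contig_placements.append(
                        row._replace(seq_id=cid, start=cs, end=ce, strand=strand)
                    )
                    break
            else:
                continue
            break

    truth = SyntheticTruth(
        true_gaps=true_gaps,
        bias_regions=list(bias.regions) if bias else [],
        planted_repeats=annotation
        or RepeatAnnotation(sequence_id=ref.id, intervals=[]),
        seed=seed,
    )
    draft = DraftAssembly(
        reference_id=ref.id, contigs=contigs, contig_placements=contig_placements
    )
    # Tiling invariant: retained intervals + true gaps tile the analyzed span
    # ([first, last) linear; the whole circle in circular mode).
    total = sum(e - s for s, e in retained) + sum(e - s for s, e in true_gaps)
    expected_span = ref.length if circular else last - first
    assert total == expected_span, "contig/gap tiling violated"
    return draft, truth
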