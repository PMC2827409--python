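"""Sequence-read redundancy profiles and the ordinal variation score.

The score reconstructs the -/+/++/++++ redundancy-variation scale used to
decide whether a clone would benefit from a copy-control relibrarying: the
coefficient of variation (population sd / mean) of total read depth is
computed in fixed windows along the contig and summarized as the 90th
percentile across windows, so a single severe coverage trough dominates.
Cutpoints between the four levels are implementation defaults exposed in
configuration; the scale itself is a reconstruction, not a published
quantification.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .model import Placement, ReadPlacement, RedundancyProfile, SCORE_LEVELS

__all__ = ["depth_profile", "variation_score", "DEFAULT_CV_CUTPOINTS"]

DEFAULT_CV_CUTPOINTS = (0.35, 0.55, 0.80)


def depth_profile(
    placements: Iterable[Placement | ReadPlacement],
    contig_length: int,
    contig_id: str = "contig",
) -> RedundancyProfile:
    """Per-base read depth on the upper (+) and lower (-) strand."""
    up = np.zeros(contig_length + 1, dtype=np.int32)
    lo = np.zeros(contig_length + 1, dtype=np.int32)
    for p in placements:
        if not (0 <= p.start < p.end <= contig_length):
            raise ValueError(f"placement ({p.start}, {p.end}) out of bounds")
        arr = up if p.strand == "+" else lo
        arr[p.start] += 1
        arr[p.end] -= 1
    return RedundancyProfile(
        contig_id=contig_id,
        upper=np.cumsum(up[:-1]),
        lower=np.cumsum(lo[:-1]),
    )


def variation_score(
    profile: RedundancyProfile,
    window: int = 2000,
    thresholds: Sequence[float] = DEFAULT_CV_CUTPOINTS,
) -> str:
    """Ordinal redundancy-variation score; also fills the profile's
    ``window_cv``, ``summary_cv`` and ``score`` fields.

    Windows are non-overlapping, full-length; a contig shorter than one
    window is scored from a single whole-contig window.  A window of zero
    mean depth has CV 0 by convention (cannot occur for contigs defined by
    covered intervals).
    """
    if len(thresholds) != 3 or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be three increasing CV cutpoints")
    total = profile.total
    n = len(total)
    if n == 0:
        raise ValueError("empty profile")
    starts = list(range(0, n - window + 1, window)) if n >= window else [0]
    cvs = []
    for s in starts:
        chunk = total[s : s + window] if n >= window else total
        mean = chunk.mean()
        cv = float(chunk.std() / mean) if mean > 0 else 0.0
        cvs.append((s, cv))
    summary = float(np.percentile([c for _, c in cvs], 90))
    level = sum(summary >= t for t in thresholds)
    profile.window_cv = cvs
    profile.summary_cv = summary
    profile.score = SCORE_LEVELS[level]
    return profile.score
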