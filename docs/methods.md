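# Methods

## The assay

The unit of analysis is a BAC-sized clone for which two sequences exist: a
finished (human-grade) reference and a draft (comparative-grade) assembly
whose contigs (> 2 kb) are to be ordered and oriented. The assay aligns the
draft contigs to the finished sequence, catalogues the uncovered reference
intervals (gaps), classifies each internal gap as captured or uncaptured
from paired-end subclone evidence, profiles the composition of gap versus
total sequence, and scores the variation in sequence-read redundancy. All
coordinates are 0-based half-open on the finished reference; Mb denominators
are the finished-sequence length of the analyzed unit.

## Contig mapping

Draft and finished sequence derive from the same DNA, so alignment only
requires near-exact placement. Anchors are k-mers (k = 31, odd, 11–63)
occurring exactly once in the reference and exactly once in the contig
(both strands tried). Anchors sharing one diagonal are chained into a block
(anchors more than 20 kb apart split chains); blocks are extended outward by
greedy exact extension, blocks under 200 bp are dropped, and identity is the
exact-match fraction over the block span. Chaining is strictly
exact-diagonal: near-diagonal anchors are produced by motif-shifted matches
inside tandem repeats and must not contaminate a block; the diagonal band
(50 bp) is used only when judging whether two blocks of one contig are
colinear. A contig with two or more mutually non-colinear blocks is reported
as split (putative misassembly).

Map resolution replaces manual curation of ambiguous endpoints with a
deterministic rule. Per contig the highest-scoring block survives
(score = aligned bp × identity), so each contig appears at most once in the
map; placements then claim reference bases in priority order (identity
descending, span descending, contig id ascending), each keeping its longest
unclaimed contiguous run. On a pairwise overlap this reduces to: trim the
lower-identity placement; tie → trim the shorter; still tied → trim the
lexicographically later contig id. Contigs with no surviving bases are
listed as unmapped. Externally produced alignments can be imported from a
9-column TSV instead of running the internal aligner.

## Gaps and capture

Internal gaps are the intervals between adjacent placements; uncovered
reference ends are catalogued as terminal gaps but excluded from headline
statistics (flag-reversible) and never classified (one flank only). The
conservation identity — placed bases + internal gap bases + terminal gap
bases = finished length — is asserted per BAC and aborts the run on
violation. The median gap size uses the lower median for even counts.
Because the appropriate denominator for a headline gap rate is arguable,
reports carry both normalizations: gaps per finished Mb and gaps per
contig-aligned Mb.

A subclone spans a gap when one read ends at or before the gap start and the
other starts at or after the gap end, either orientation; its implied span
is the outermost distance between the two reads. A gap is captured when at
least `min_spanning_pairs` (default 2) spanning subclones have span ≤
`insert_mean + k_sd · insert_sd` (k_sd = 3), formalizing "appropriately
spaced"; an alternative multiplier mode (span ≤ 1.5 × insert_mean) is
exposed. The default is a documented implementation choice, not a published
value. For reads placed on contigs, placements are lifted through the contig
map to reference coordinates; pairs with a mate on an unmapped contig are
ignored. The per-unit difficulty criterion is the fraction of assemblies
with ≥ 2 uncaptured gaps.

## Composition

Gap composition is read from the finished reference within the gap
interval. Repeat fractions are computed against a flattened, class-disjoint
annotation; overlaps between classes are resolved with priority
Simple > LINE > SINE > LTR > DNA (configurable). Real annotation is
ingested from RepeatMasker `.out`; for synthetic or annotation-free
operation an internal simple-repeat finder detects tandem tracts of motif
size 1–4 by stepwise extension while the running purity (fraction of
positions matching the base one motif-length back) stays ≥ 0.9, with
minimum tract lengths {1: 12, 2: 20, 3: 21, 4: 24} bp — stated defaults of
this implementation. Confidence intervals are percentile bootstraps
(1,000 replicates, 2.5/97.5) resampling BACs with replacement, the BAC
being the natural exchangeable unit; units are sorted before resampling so
results are order-invariant under a fixed seed, and a single unit yields a
point estimate with an undefined CI.

## Redundancy variation

Depth is accumulated per strand from read placements. The variation score
summarizes the coefficient of variation (population sd / mean) of total
depth in non-overlapping 2 kb windows as the 90th percentile across
windows — chosen over the mean so that a single severe trough dominates —
and maps it onto the ordinal scale −/+/++/++++ at CV cutpoints
0.35/0.55/0.80. The four-level scale is a reconstruction; the cutpoints are
implementation defaults exposed in configuration. Combined-strand depth
feeds the score; per-strand profiles are retained.

## Synthetic data

The generator emulates the statistical structure of a BAC finishing
project; its defaults are the study conditions: 165 kb references at
background GC 0.41, paired-end reads of 800 bp (a typical high-quality
dideoxy read length) from subclone inserts of 4,000 ± 400 bp (a "3–5 kb"
library, normal truncated at read_len + 1), 8-fold read redundancy, 2 kb
contig threshold. The accepted pair count is exactly
round(redundancy × length / (2 × read_len)).

Planted features (interspersed repeats as divergent copies of per-class
templates at 5% substitution, pure tandem simple repeats of motif size 1–4,
GC-rich islands) are mutually non-overlapping and recorded exactly in the
annotation. Cloning bias is a set of regions with a survival probability
(viability): a candidate subclone whose insert overlaps a region is accepted
with the minimum viability over overlapped regions; under a copy-control
host the depression is rescued by `v' = v + rescue · (1 − v)`. The paper
this emulates does not quantify the depression, so region viabilities are
placeholders varied in tests: zero-viability regions reproduce uncapturable
coverage holes, moderate depressions (≈ 0.15) produce capturable gaps. A
consequence of insert-overlap suppression worth stating: a zero-viability
region suppresses precisely the subclones that would span its gap, so such
gaps are intrinsically uncaptured — the clone-toxicity mechanism — whereas
captured-gap repeat enrichment requires partial depressions short enough
(~1 kb) for spanning inserts to survive.

Drafts are derived from coverage truth, not by running an assembler:
contigs are maximal reference intervals at depth ≥ 1, intervals under the
contig threshold are discarded, and the true gaps are the complement within
the covered span — keeping gap truth exact, since assembler behaviour is
out of scope. Contig order and orientation can be shuffled, and an optional
chimera flag joins the two largest covered intervals into one contig to
exercise the split-contig detector. No base-level sequencing-error,
chromatogram or chemistry model is applied; contigs are exact reference
substrings. Consequently the synthetic cohort reproduces per-Mb gap *rates*
at realistic scales but not the small-gap size spectrum of real drafts
(which includes many sub-100 bp quality-trimming gaps); passing tests
demonstrate the assay's bookkeeping and classification logic, not base-call
realism.

Template geometry: the default linear mode confines inserts to the
sequence, leaving mild edge undercoverage within about one insert length of
each end — the behaviour of a vector-trimmed linear coordinate system;
terminal effects are catalogued as terminal gaps and excluded from headline
statistics. A `circular` mode places subclone midpoints uniformly on the
circle (the physical clone molecule), for which coverage is stationary and
the mean coverage-gap count matches the classical N·e^(−c) expectation;
this mode backs the coverage-theory validation.

## Numerical and procedural choices

Seeds are explicit everywhere; identical inputs and seed give byte-identical
outputs (per-BAC seeds are drawn from a cohort seed stream). Report files
round rates to one decimal, with full precision in parallel `*_full.tsv`
files. Degenerate inputs: zero-base composition scopes and empty gap lists
are NaN/None-marked rather than zero-filled; empty alignment input yields an
empty map; an empty manifest, duplicate BAC ids, non-positive Mb
denominators and unclassified gaps in reporting are rejected with
diagnostics.

Validation scales used by the test suite (chosen to exercise the study
conditions at desk runtime): 100 simulated BACs for exact gap-truth
recovery; 1,000 randomized layouts against a brute-force spanning-pair
oracle; 200 seeds per coverage level for the Lander–Waterman comparison
(within three standard errors of N·e^(−c) at 4× and 8×); 100 paired
standard/copy-control genomes (sign test, p < 0.01, on gap count and
redundancy CV); 20 cohort seeds for the captured-gap simple-repeat
enrichment signature; 100 seeds for exact order/orientation recovery of
shuffled, reverse-complemented contigs.

## Known limitations

No divergence-tolerant (gapped/affine) alignment: the aligner assumes draft
and reference share the same underlying DNA, and inter-species mapping is
out of scope. No fosmid or 10 kb rescue-library model. The simple-repeat
finder is not a general tandem-repeat annotator (motif sizes ≤ 4 only). A
contig consisting entirely of sequence with no unique k-mer (e.g. one lying
wholly inside a long perfect repeat) would go unmapped; at the default
contig threshold and repeat length distributions this does not occur.
Real-data ingestion expects reads pre-placed on the finished sequence (the
8-column placement TSV); no read aligner is bundled.
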