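# finishassay

A finishing-effort assay for shotgun genome assemblies of BAC-sized clones.

When a draft ("comparative-grade") assembly — contigs above 2 kb, ordered and
oriented — is compared against the finished ("human-grade") sequence of the
same clone, the gaps between contigs are the main driver of the remaining
finishing effort. `finishassay` automates that comparison:

* **map** — align draft contigs to the finished reference with a unique-k-mer
  seed-and-chain aligner and resolve them into an ordered, oriented,
  overlap-trimmed contig map, flagging putatively misassembled (split)
  contigs;
* **gaps** — catalogue every uncovered reference interval (location, size,
  flanking contigs) and compute headline statistics: gaps per Mb, gap bases
  per Mb, median gap size, percent of sequence in gaps;
* **classify** — call each internal gap *captured* or *uncaptured* from
  read-pair evidence: a gap is captured when ≥ `min_spanning_pairs` (default
  2) subclones have mates on opposite flanks with an implied span at most
  `insert_mean + 3·insert_sd` (configurable); the fraction of assemblies with
  ≥ 2 uncaptured gaps is the finishing-difficulty criterion;
* **compose** — GC and repeat-class (Simple/LINE/SINE/LTR/DNA) composition of
  gap versus total sequence, with percentile-bootstrap 95% CIs resampling
  BACs;
* **profile** — per-strand read-redundancy profiles and an ordinal
  redundancy-variation score (−/+/++/++++) from windowed depth CVs, the
  predictor for whether a clone would benefit from relibrarying in a
  copy-control host;
* **simulate** — a fully self-contained synthetic generator: BAC-sized
  references with planted repeats and GC islands, paired-end shotgun reads
  with a region-specific subclone-viability (cloning-bias) model including a
  standard vs copy-control host switch, and draft assemblies with exact gap
  truth.

## Worked example

```python
from finishassay import (
    BiasModel, BiasRegion, align_contigs, build_draft, call_gaps,
    classify_gaps, gap_stats, generate_reference, resolve_map,
    simulate_shotgun,
)

# a 165 kb clone with a clone-toxic region at 80-83 kb
ref, ann = generate_reference(165_000, gc_target=0.41, seed=11)
bias = BiasModel([BiasRegion(80_000, 83_000, 0.05)])
pairs = simulate_shotgun(ref, redundancy=8, bias=bias, seed=11)
draft, truth = build_draft(ref, pairs, min_contig=2000, shuffle=True, seed=11)

cmap = resolve_map(align_contigs(draft.contigs, ref), ref.length,
                   sequence_id=ref.id)
gaps = classify_gaps(call_gaps(cmap, ref.length), pairs)
internal = [g for g in gaps if g.kind == "internal"]
print([(g.start, g.end, g.status) for g in internal])
print(gap_stats(internal, ref.length / 1e6))
```

prints

```
[(80699, 83339, 'uncaptured'), (85655, 86076, 'captured')]
GapStats(unit='all', n_gaps=2, total_mb=0.165, gaps_per_mb=12.121212121212121,
gap_bases_per_mb=18551.515151515152, median_gap_size=421)
```

Two gaps: the viability trough produced a 2.6 kb *uncaptured* gap — every
subclone whose insert spans the toxic region was itself suppressed, so no
spanning mate pairs exist, the mechanism by which clone-toxic DNA removes
contig order/orientation information along with coverage — while a small
random-coverage gap nearby is *captured* by spanning subclones and is merely
a sequencing, not a mapping, problem.

The same pipeline is available from the shell:

```bash
finishassay simulate --seed 11 --outdir sim/
finishassay map --contigs sim/contigs.fa --ref sim/reference.fa --out map/
finishassay run --outdir out/    # end-to-end simulated cohort with reports
```

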