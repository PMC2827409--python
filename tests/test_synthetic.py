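"""Generator contracts: sequence content, read-pair geometry, draft truth."""

import numpy as np
import pytest

from finishassay import (
    BiasModel,
    BiasRegion,
    FinishedSequence,
    GCIsland,
    GCIslandConfig,
    PlantedRepeat,
    RepeatConfig,
    build_draft,
    generate_reference,
    simulate_shotgun,
)
from finishassay.synthetic import expected_pairs, coverage_depth

from _oracles import complement_bruteforce


class TestGenerateReference:
    def test_length_and_empty_annotation(self):
        ref, ann = generate_reference(10_000, gc_target=0.5, seed=7)
        assert ref.length == 10_000
        assert ann.intervals == []

    def test_planted_simple_repeat_recorded(self):
        cfg = RepeatConfig(
            planted=(PlantedRepeat("Simple", 2000, motif="AC", copies=50),)
        )
        ref, ann = generate_reference(10_000, repeat_config=cfg, seed=1)
        assert (2000, 2100, "Simple") in ann.intervals
        assert ref.seq[2000:2100] == "AC" * 50

    def test_gc_island_hits_configured_gc(self):
        cfg = GCIslandConfig(planted=(GCIsland(3000, 2100, 0.83),))
        ref, _ = generate_reference(60_000, gc_target=0.41,
                                    gc_island_config=cfg, seed=5)
        island = ref.seq[3000:5100]
        gc = (island.count("G") + island.count("C")) / len(island)
        assert 0.78 <= gc <= 0.88

    def test_background_gc_within_tolerance(self):
        ref, _ = generate_reference(60_000, gc_target=0.41, seed=3)
        gc = (ref.seq.count("G") + ref.seq.count("C")) / ref.length
        assert abs(gc - 0.41) <= 0.02

    def test_oversized_planted_repeat_rejected(self):
        cfg = RepeatConfig(
            planted=(PlantedRepeat("LINE", 9000, length=5000),)
        )
        with pytest.raises(ValueError, match="exceeds"):
            generate_reference(10_000, repeat_config=cfg, seed=1)

    def test_deterministic_under_seed(self):
        a, _ = generate_reference(5_000, seed=42)
        b, _ = generate_reference(5_000, seed=42)
        assert a.seq == b.seq

    def test_interspersed_classes_disjoint_and_recorded(self):
        from finishassay.synthetic import RandomRepeats

        cfg = RepeatConfig(
            random=(
                RandomRepeats("LINE", 3, 2000, 300),
                RandomRepeats("SINE", 5, 300, 50),
            )
        )
        ref, ann = generate_reference(60_000, repeat_config=cfg, seed=9)
        ann.validate(ref.length)
        assert len(ann.by_class("LINE")) == 3
        assert len(ann.by_class("SINE")) == 5


class TestSimulateShotgun:
    def test_pair_count_formula_exact(self):
        ref = FinishedSequence(id="r", seq="ACGT" * 25_000)
        pairs = simulate_shotgun(ref, redundancy=8, read_len=800, seed=0)
        assert len(pairs) == 500
        # formula holds for arbitrary parameters
        for length, red, rl in [(50_000, 6.5, 700), (165_000, 8, 800)]:
            assert expected_pairs(length, red, rl) == round(red * length / (2 * rl))

    def test_zero_viability_region_excludes_overlapping_inserts(self):
        ref = FinishedSequence(id="r", seq="ACGT" * 25_000)
        bias = BiasModel([BiasRegion(40_000, 42_000, 0.0)])
        pairs = simulate_shotgun(ref, redundancy=8, bias=bias, seed=2)
        for p in pairs:
            lo = min(p.fwd.start, p.rev.start)
            hi = max(p.fwd.end, p.rev.end)
            assert hi <= 40_000 or lo >= 42_000

    def test_mates_on_opposite_strands_and_insert_geometry(self):
        ref = FinishedSequence(id="r", seq="ACGT" * 25_000)
        pairs = simulate_shotgun(ref, redundancy=4, insert_mean=4000,
                                 insert_sd=400, seed=11)
        for p in pairs:
            assert {p.fwd.strand, p.rev.strand} == {"+", "-"}
            span = max(p.fwd.end, p.rev.end) - min(p.fwd.start, p.rev.start)
            assert span > 800  # insert truncated above read length

    def test_rejects_unbuildable_parameters(self):
        ref = FinishedSequence(id="r", seq="ACGT" * 300)
        with pytest.raises(ValueError):
            simulate_shotgun(ref, redundancy=0.5, read_len=800,
                             insert_mean=900, insert_sd=10, seed=0)


class TestBuildDraft:
    def test_full_coverage_single_contig_no_gaps(self, small_ref):
        pairs = simulate_shotgun(small_ref, redundancy=20, seed=3)
        draft, truth = build_draft(small_ref, pairs)
        assert len(draft.contigs) == 1
        assert truth.true_gaps == []

    def test_planted_zero_coverage_yields_one_gap(self, small_ref):
        bias = BiasModel([BiasRegion(30_000, 32_000, 0.0)])
        pairs = simulate_shotgun(small_ref, redundancy=12, bias=bias, seed=5)
        draft, truth = build_draft(small_ref, pairs)
        assert len(truth.true_gaps) == 1
        (s, e), = truth.true_gaps
        # observed boundaries are at the coverage edges around the region
        assert 30_000 - 4000 < s <= 30_000 and 32_000 <= e < 32_000 + 4000

    def test_short_island_discarded_merges_flanking_gaps(self):
        # hand-built coverage: islands [0,3000), [5000,6500), [9000,12000)
        ref, _ = generate_reference(12_000, seed=8)
        from finishassay.model import Placement, ReadPair

        def pair_at(i, s, e):
            return ReadPair(
                f"s{i}", Placement("ref", s, s + 100, "+"),
                Placement("ref", e - 100, e, "-"), 4000, 400
            )

        pairs = []
        k = 0
        for a, b in [(0, 3000), (5000, 6500), (9000, 12000)]:
            for s in range(a, b - 100, 100):
                pairs.append(pair_at(k, s, min(s + 4000, b)))
                k += 1
        pairs = [p for p in pairs if p.fwd.end <= 12000 and p.rev.end <= 12000]
        draft, truth = build_draft(ref, pairs, min_contig=2000)
        retained = sorted((c.true_start, c.true_end) for c in draft.contigs)
        # 1.5 kb island dropped; its flanks merge into one truth gap
        assert all(e - s >= 2000 for s, e in retained)
        expected = complement_bruteforce(retained, retained[0][0], retained[-1][1])
        assert truth.true_gaps == expected
        assert all(not (5000 <= s and e <= 6500) for s, e in retained)

    def test_zero_retained_contigs_rejected(self, small_ref):
        pairs = simulate_shotgun(small_ref, redundancy=1, read_len=100,
                                 insert_mean=300, insert_sd=10, seed=1)
        with pytest.raises(ValueError, match="min_contig"):
            build_draft(small_ref, pairs, min_contig=59_000)

    def test_tiling_and_shuffle_truth(self, biased_assembly):
        draft = biased_assembly["draft"]
        truth = biased_assembly["truth"]
        retained = sorted((c.true_start, c.true_end) for c in draft.contigs)
        total = sum(e - s for s, e in retained) + sum(
            e - s for s, e in truth.true_gaps
        )
        assert total == retained[-1][1] - retained[0][0]

    def test_contig_coordinate_lifting_flips_strand(self, biased_assembly):
        draft = biased_assembly["draft"]
        by_contig = {c.id: c for c in draft.contigs}
        for row in draft.contig_placements[:200]:
            c = by_contig[row.seq_id]
            assert 0 <= row.start < row.end <= c.length

    def test_redundancy_monotonicity_in_gap_count(self):
        ref, _ = generate_reference(30_000, seed=55)
        means = {}
        for red in (6, 10):
            counts = []
            for s in range(100):
                pairs = simulate_shotgun(ref, redundancy=red, seed=1000 + s)
                _, truth = build_draft(ref, pairs, min_contig=1)
                counts.append(len(truth.true_gaps))
            means[red] = np.mean(counts)
        assert means[10] <= means[6]

    def test_copy_control_reduces_gap_count(self):
        ref, _ = generate_reference(30_000, seed=66)
        regions = [BiasRegion(8_000, 10_500, 0.1), BiasRegion(20_000, 22_500, 0.1)]
        means = {}
        for host in ("standard", "copy_control"):
            bias = BiasModel(regions, host=host, copy_control_rescue=1.0)
            counts = []
            for s in range(100):
                pairs = simulate_shotgun(ref, redundancy=8, bias=bias, seed=2000 + s)
                _, truth = build_draft(ref, pairs, min_contig=1)
                counts.append(len(truth.true_gaps))
            means[host] = np.mean(counts)
        assert means["copy_control"] <= means["standard"]

    def test_byte_identical_determinism(self, small_ref):
        out = []
        for _ in range(2):
            pairs = simulate_shotgun(small_ref, redundancy=6, seed=77)
            draft, truth = build_draft(small_ref, pairs, shuffle=True, seed=78)
            out.append((
                [(p.fwd, p.rev) for p in pairs],
                [(c.id, c.seq) for c in draft.contigs],
                truth.true_gaps,
            ))
        assert out[0] == out[1]


def _islands(depth):
    import numpy as np

    covered = depth >= 1
    edges = np.flatnonzero(np.diff(np.concatenate(([False], covered, [False]))))
    return edges[0::2], edges[1::2]
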