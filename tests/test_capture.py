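"""Capture classification against the brute-force spanning-pair oracle."""

import numpy as np
import pytest

from finishassay import (
    CaptureRule,
    classify_gap,
    classify_gaps,
    count_spanning_subclones,
    uncaptured_burden,
)
from finishassay.capture import lift_pairs_to_reference, spanning_subclones
from finishassay.model import ContigAlignment, ContigMap, Gap, Placement, ReadPair

from _oracles import spanning_count_bruteforce


def _pair(i, s1, e1, s2, e2, mean=4000.0, sd=400.0):
    return ReadPair(
        f"s{i:04d}",
        Placement("ref", s1, e1, "+"),
        Placement("ref", s2, e2, "-"),
        mean, sd,
    )


GAP = Gap("ref", 50_000, 52_000, "cL", "cR", "internal")


class TestSpanningCount:
    def test_flanking_pair_counted_with_span(self):
        pairs = [_pair(0, 48_500, 49_300, 52_600, 53_400)]
        hits = spanning_subclones(GAP, pairs)
        assert len(hits) == 1
        assert hits[0][1] == 53_400 - 48_500 == 4900

    def test_same_side_pair_not_counted(self):
        pairs = [_pair(0, 40_000, 40_800, 45_000, 45_800)]
        assert count_spanning_subclones(GAP, pairs) == 0

    def test_read_overlapping_gap_edge_not_counted(self):
        # left read pokes into the gap: not wholly on the left side
        pairs = [_pair(0, 49_500, 50_300, 52_600, 53_400)]
        assert count_spanning_subclones(GAP, pairs) == 0

    def test_orientation_agnostic(self):
        p = ReadPair(
            "s1",
            Placement("ref", 52_600, 53_400, "-"),
            Placement("ref", 48_500, 49_300, "+"),
            4000, 400,
        )
        assert count_spanning_subclones(GAP, [p]) == 1

    def test_random_layouts_match_bruteforce(self):
        rng = np.random.default_rng(17)
        pairs = []
        for i in range(1000):
            s1 = int(rng.integers(0, 99_000))
            s2 = int(rng.integers(0, 99_000))
            pairs.append(_pair(i, s1, s1 + 800, s2, s2 + 800))
        expected = spanning_count_bruteforce(GAP.start, GAP.end, pairs)
        assert count_spanning_subclones(GAP, pairs) == len(expected)


class TestClassifyGap:
    def test_enough_close_pairs_captured(self):
        pairs = [
            _pair(i, 49_000 - i * 10, 49_800 - i * 10, 52_200, 53_000)
            for i in range(3)
        ]
        g = classify_gap(GAP, pairs)
        assert g.status == "captured"
        assert g.spanning_subclones == 3

    def test_single_pair_uncaptured(self):
        pairs = [_pair(0, 49_000, 49_800, 52_200, 53_000)]
        g = classify_gap(GAP, pairs)
        assert g.status == "uncaptured"
        assert g.spanning_subclones == 1

    def test_overstretched_pairs_uncaptured(self):
        # spans of 9,000 bp exceed insert_mean + 3 sd = 5,200
        pairs = [
            _pair(i, 46_000, 46_800, 54_200 + i, 55_000 + i) for i in range(2)
        ]
        g = classify_gap(GAP, pairs)
        assert g.status == "uncaptured"
        assert g.spanning_subclones == 0

    def test_multiplier_mode(self):
        rule = CaptureRule(mode="multiplier", multiplier=1.5)
        assert rule.max_span(4000, 400) == 6000.0

    def test_terminal_gap_rejected(self):
        g = Gap("ref", 0, 100, right_contig="c0", kind="terminal")
        with pytest.raises(ValueError):
            classify_gap(g, [])

    def test_unset_library_stats_rejected(self):
        with pytest.raises(ValueError):
            classify_gap(GAP, [])

    def test_status_depends_only_on_qualifying_count(self):
        rng = np.random.default_rng(23)
        for trial in range(50):
            pairs = []
            for i in range(40):
                s1 = int(rng.integers(0, 98_000))
                s2 = int(rng.integers(0, 98_000))
                pairs.append(_pair(i, s1, s1 + 800, s2, s2 + 800))
            g = classify_gap(GAP, pairs)
            rule = CaptureRule()
            max_span = rule.max_span(4000, 400)
            expected_n = sum(
                1 for _, span in spanning_count_bruteforce(GAP.start, GAP.end, pairs)
                if span <= max_span
            )
            assert g.spanning_subclones == expected_n
            assert (g.status == "captured") == (expected_n >= 2)


class TestCaptureGeometry:
    """Capture status follows insert geometry on simulated coverage."""

    def test_small_unbiased_coverage_gaps_mostly_captured(self):
        """Random coverage holes at moderate redundancy are far smaller than
        the insert, and the subclone pairs around them are unsuppressed, so
        nearly all such gaps are captured."""
        from finishassay import (
            build_draft, call_gaps, classify_gaps, generate_reference,
            resolve_map, align_contigs, simulate_shotgun,
        )

        statuses, sizes = [], []
        for seed in range(40):
            ref, _ = generate_reference(60_000, seed=8000 + seed)
            pairs = simulate_shotgun(ref, redundancy=5.5, seed=8100 + seed)
            draft, _ = build_draft(ref, pairs)
            cmap = resolve_map(align_contigs(draft.contigs, ref), ref.length)
            gaps = classify_gaps(call_gaps(cmap, ref.length), pairs)
            internal = [g for g in gaps if g.kind == "internal"]
            statuses += [g.status for g in internal]
            sizes += [g.size for g in internal]
        assert len(statuses) >= 20
        assert np.mean(sizes) < 4000 / 2  # well below the insert mean
        frac_captured = statuses.count("captured") / len(statuses)
        assert frac_captured >= 0.95

    def test_gaps_wider_than_span_ceiling_always_uncaptured(self):
        rng = np.random.default_rng(41)
        # geometry alone forbids capture: any spanning pair's span is
        # gap size + two read lengths > insert_mean + 3 sd
        for _ in range(20):
            start = int(rng.integers(10_000, 60_000))
            size = int(rng.integers(5_300, 12_000))
            gap = Gap("ref", start, start + size, "cL", "cR", "internal")
            pairs = []
            for i in range(50):
                s1 = int(rng.integers(0, start - 800))
                s2 = int(rng.integers(gap.end, 90_000))
                pairs.append(_pair(i, s1, s1 + 800, s2, s2 + 800))
            g = classify_gap(gap, pairs)
            assert g.status == "uncaptured"


class TestUncapturedBurden:
    def _gaps(self, statuses):
        return [
            Gap("r", i * 1000, i * 1000 + 10, "a", "b", "internal",
                spanning_subclones=0, status=s)
            for i, s in enumerate(statuses)
        ]

    def test_fraction_of_multi_uncaptured_assemblies(self):
        assemblies = [self._gaps(["uncaptured", "uncaptured"])] * 3 + [
            self._gaps(["captured"])
        ] * 7
        df = uncaptured_burden({"sp": assemblies})
        row = df.iloc[0]
        assert row.frac_assemblies_ge2_uncaptured == pytest.approx(0.30)

    def test_all_captured_zero_uncaptured_fraction(self):
        df = uncaptured_burden({"sp": [self._gaps(["captured", "captured"])]})
        assert df.iloc[0].frac_gaps_uncaptured == 0

    def test_randomized_fractions_match_tally(self):
        rng = np.random.default_rng(31)
        assemblies = []
        for _ in range(40):
            statuses = list(
                rng.choice(["captured", "uncaptured"], size=rng.integers(0, 6))
            )
            assemblies.append(self._gaps(statuses))
        df = uncaptured_burden({"u": assemblies}, total_mb={"u": 2.0})
        n_unc = sum(
            sum(g.status == "uncaptured" for g in a) for a in assemblies
        )
        n_all = sum(len(a) for a in assemblies)
        row = df.iloc[0]
        assert row.frac_gaps_uncaptured == pytest.approx(n_unc / n_all)
        assert row.uncaptured_per_mb == pytest.approx(n_unc / 2.0)
        assert row.captured_per_mb + row.uncaptured_per_mb == pytest.approx(
            n_all / 2.0
        )


class TestLifting:
    def test_lift_through_reverse_placement(self):
        cmap = ContigMap(
            "ref",
            [ContigAlignment("c0", 10_000, 20_000, 0, 10_000, "-", 1.0)],
        )
        pair = ReadPair(
            "s0",
            Placement("c0", 100, 900, "+"),
            Placement("c0", 4_000, 4_800, "-"),
            4000, 400,
        )
        (lifted,) = lift_pairs_to_reference([pair], cmap)
        assert lifted.fwd == Placement("ref", 19_100, 19_900, "-")
        assert lifted.rev == Placement("ref", 15_200, 16_000, "+")

    def test_unmapped_contig_pairs_dropped(self):
        cmap = ContigMap("ref", [], unmapped_contigs=["c0"])
        pair = ReadPair(
            "s0", Placement("c0", 0, 800, "+"), Placement("c0", 3200, 4000, "-"),
            4000, 400,
        )
        assert lift_pairs_to_reference([pair], cmap) == []
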