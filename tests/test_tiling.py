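"""Probe tiling, phase arithmetic, geometry annotation and replication."""

import numpy as np
import pytest

from densetile import (
    ReferenceRegion,
    RepeatInterval,
    TilingPlan,
    Zone,
    min_segment_length_for_max_coverage,
    probe_count_bounds,
    segment_region,
    select_repeat_adjacent_probes,
    tile,
)

from conftest import random_region_and_masks


def make_region(length, masks=()):
    rng = np.random.default_rng(length)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    region = ReferenceRegion("chrT", 0, length, seq)
    return region, segment_region(region, list(masks))


class TestTile:
    def test_dense_offset_full_segment(self):
        region, segs = make_region(200)
        plan = TilingPlan(zones=[Zone(0, 200, 6)])
        ps = tile(region, segs, plan)
        starts = [p.start for p in ps.probes]
        assert starts == list(range(0, 139, 6))  # 0, 6, ..., 138
        assert len(ps) == 24

    def test_phase_shifted_segment_yields_minimum_count(self):
        # a 200 bp segment starting at 3 on a global grid anchored at 0
        region, segs = make_region(1000, [RepeatInterval(0, 3, "LINE", "l"),
                                          RepeatInterval(203, 1000, "LINE", "r")])
        plan = TilingPlan(zones=[Zone(0, 1000, 6)])
        ps = tile(region, segs, plan)
        assert len(ps) == 23
        assert all(p.start % 6 == 0 for p in ps.probes)

    def test_probe_extending_into_mask_discarded(self):
        region, segs = make_region(200, [RepeatInterval(100, 200, "SINE", "s")])
        plan = TilingPlan(zones=[Zone(0, 200, 26)])
        ps = tile(region, segs, plan)
        # candidates 0, 26 fit in (0, 100); 52 would end at 112 inside the mask
        assert [p.start for p in ps.probes] == [0, 26]

    def test_sequences_match_region_slices(self):
        region, segs = make_region(500)
        ps = tile(region, segs, TilingPlan(zones=[Zone(0, 500, 13)]))
        for p in ps.probes:
            assert p.sequence == region.sequence[p.start : p.end].upper()

    def test_per_segment_anchor_maximises_counts(self):
        region, segs = make_region(1000, [RepeatInterval(0, 3, "LINE", "l"),
                                          RepeatInterval(203, 1000, "LINE", "r")])
        plan = TilingPlan(zones=[Zone(0, 1000, 6)], anchor="per-segment")
        ps = tile(region, segs, plan)
        assert len(ps) == 24  # grid restarts at the segment start

    def test_no_probe_overlaps_any_mask_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            region, masks = random_region_and_masks(rng, length=1500)
            segs = segment_region(region, masks)
            offset = int(rng.choice([6, 13, 26]))
            ps = tile(region, segs, TilingPlan(zones=[Zone(0, 1500, offset)], probe_length=60))
            merged = [(m.start, m.end) for m in masks]
            for p in ps.probes:
                assert not any(p.start < e and p.end > s for s, e in merged)

    def test_coverage_monotone_in_offset(self):
        rng = np.random.default_rng(3)
        region, masks = random_region_and_masks(rng, length=3000)
        segs = segment_region(region, masks)
        fracs = []
        for offset in (3, 6, 13, 26, 52):
            ps = tile(region, segs, TilingPlan(zones=[Zone(0, 3000, offset)]))
            fracs.append(ps.coverage_fraction())
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestPhaseArithmetic:
    def test_replicate_threshold_for_dense_offset(self):
        assert min_segment_length_for_max_coverage(60, 6) == 114

    def test_offset_equal_probe_length(self):
        assert min_segment_length_for_max_coverage(60, 60) == 60

    def test_sparse_offset(self):
        assert min_segment_length_for_max_coverage(60, 26) == 112

    def test_threshold_matches_coverage_enumeration(self):
        # the returned length is the first at which per-base coverage
        # attains ceil(p / o) under the best phase
        for p, o in ((60, 6), (60, 26), (20, 7)):
            target = int(np.ceil(p / o))
            want = min_segment_length_for_max_coverage(p, o)
            for L in range(p, want + 10):
                cov = np.zeros(L, dtype=int)
                for s in range(0, L - p + 1, o):
                    cov[s : s + p] += 1
                if cov.max() >= target:
                    assert L == want
                    break

    def test_worked_example_200bp(self):
        assert probe_count_bounds(200, 60, 6) == (23, 24)
        assert probe_count_bounds(200, 60, 26) == (5, 6)

    def test_segment_shorter_than_probe(self):
        assert probe_count_bounds(59, 60, 6) == (0, 0)

    def test_bounds_match_phase_enumeration(self):
        """Closed-form min/max equal brute-force enumeration over phases."""
        for p in (20, 60):
            for o in range(1, p + 1):
                for L in range(p, 501, 7):
                    counts = [
                        sum(1 for s in range(phase, L - p + 1, o))
                        for phase in range(o)
                    ]
                    assert probe_count_bounds(L, p, o) == (min(counts), max(counts))


class TestGeometry:
    def _probeset(self, length, offset=6, masks=()):
        region, segs = make_region(length, masks)
        return tile(region, segs, TilingPlan(zones=[Zone(0, length, offset)])), segs

    def test_position_palindrome_odd(self):
        ps, _ = self._probeset(60 + 4 * 6)  # 5 probes
        assert [p.position for p in ps.probes] == [1, 2, 3, 2, 1]

    def test_position_palindrome_even(self):
        ps, _ = self._probeset(60 + 5 * 6)  # 6 probes
        assert [p.position for p in ps.probes] == [1, 2, 3, 3, 2, 1]

    def test_max_position_is_half_count(self):
        # 777 probes at offset 6 need a segment of 60 + 776*6 bp
        ps, _ = self._probeset(60 + 776 * 6)
        assert len(ps) == 777
        assert max(p.position for p in ps.probes) == 389

    def test_edge_probes_carry_gap_distance(self):
        ps, segs = self._probeset(400, masks=[RepeatInterval(120, 240, "LINE", "l")])
        by_seg = {}
        for p in ps.probes:
            by_seg.setdefault(p.segment_id, []).append(p)
        left = by_seg[0]
        assert left[0].is_edge_5p and left[0].distance == 0
        assert left[-1].is_edge_3p and left[-1].distance == 120
        right = by_seg[1]
        assert right[0].is_edge_5p and right[0].distance == 120
        assert all(p.distance is None for p in left[1:-1])

    def test_single_probe_segment_is_both_edges(self):
        # segment (102, 163) admits exactly one 60-mer on the global grid
        region, segs = make_region(1000, [RepeatInterval(0, 102, "LINE", "a"),
                                          RepeatInterval(163, 1000, "SINE", "b")])
        ps = tile(region, segs, TilingPlan(zones=[Zone(0, 1000, 6)]))
        assert len(ps) == 1
        p = ps.probes[0]
        assert p.is_edge_5p and p.is_edge_3p
        assert p.distance == max(segs[0].left_gap, segs[0].right_gap) == 837


class TestReplicates:
    def _zone_plan(self, length):
        return TilingPlan(zones=[Zone(0, length, 6)], replicate_offset=6, replicate_copies=4)

    def test_boundary_segment_replicated(self):
        region, segs = make_region(114)
        ps = tile(region, segs, self._zone_plan(114))
        first = min(ps.probes, key=lambda p: p.start)
        assert first.replicate_count == 5
        assert all(p.replicate_count == 1 for p in ps.probes if p is not first)

    def test_below_threshold_not_replicated(self):
        region, segs = make_region(113)
        ps = tile(region, segs, self._zone_plan(113))
        assert all(p.replicate_count == 1 for p in ps.probes)

    def test_sparse_zone_never_replicated(self):
        region, segs = make_region(5000)
        plan = TilingPlan(zones=[Zone(0, 5000, 26)], replicate_offset=6, replicate_copies=4)
        ps = tile(region, segs, plan)
        assert all(p.replicate_count == 1 for p in ps.probes)


class TestRepeatAdjacent:
    def test_dense_zone_selects_four_per_side(self):
        region, segs = make_region(1000, [RepeatInterval(400, 600, "LINE", "l")])
        ps = tile(region, segs, TilingPlan(zones=[Zone(0, 1000, 6)]))
        sel = select_repeat_adjacent_probes(ps, segs)
        assert len(sel) == 8
        assert set(sel["repeat_class"]) == {"LINE"}
        assert set(sel["repeat_length"]) == {200}
        assert (sel.groupby("side").size() == 4).all()

    def test_sparse_zone_selects_two_per_side(self):
        region, segs = make_region(1000, [RepeatInterval(400, 600, "SINE", "s")])
        ps = tile(region, segs, TilingPlan(zones=[Zone(0, 1000, 26)]))
        sel = select_repeat_adjacent_probes(ps, segs)
        assert len(sel) == 4
        assert (sel.groupby("side").size() == 2).all()

    def test_truncated_side_with_single_probe(self):
        region, segs = make_region(1000, [RepeatInterval(0, 102, "LINE", "a"),
                                          RepeatInterval(163, 500, "SINE", "b")])
        ps = tile(region, segs, TilingPlan(zones=[Zone(0, 1000, 6)]))
        sel = select_repeat_adjacent_probes(ps, segs)
        # the segment left of the (163, 500) gap holds a single probe
        left = sel[(sel["gap_start"] == 163) & (sel["side"] == "left")]
        assert len(left) == 1
        right = sel[(sel["gap_start"] == 163) & (sel["side"] == "right")]
        assert len(right) == 4

    def test_combined_length_and_longest_class(self):
        region, segs = make_region(1200, [RepeatInterval(400, 700, "LINE", "l"),
                                          RepeatInterval(700, 740, "SINE", "s")])
        ps = tile(region, segs, TilingPlan(zones=[Zone(0, 1200, 6)]))
        sel = select_repeat_adjacent_probes(ps, segs)
        assert set(sel["repeat_class"]) == {"LINE"}
        assert set(sel["repeat_length"]) == {340}

    def test_region_boundary_gaps_excluded(self):
        region, segs = make_region(500, [RepeatInterval(0, 100, "LINE", "l")])
        ps = tile(region, segs, TilingPlan(zones=[Zone(0, 500, 6)]))
        sel = select_repeat_adjacent_probes(ps, segs)
        assert sel.empty
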