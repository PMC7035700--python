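"""Path-gap exclusion: opposite-orientation coverage and cycle order."""

import numpy as np

from asmbreak.pair_builder import CATEGORY_CYCLE, Category
from asmbreak.path_builder import PathGap, ReadPath, detect_path_gaps
from asmbreak.gap_filter import (
    apply_gap_filters,
    exclude_by_type_alternation,
    exclude_opposite_covered,
    _successor,
)
from conftest import build_track_set

S, SM, M, MS = (
    Category.SINGLE,
    Category.SINGLE_MULTIPLE,
    Category.MULTIPLE,
    Category.MULTIPLE_SINGLE,
)


def _gap(start, end, cat=S, orient="forward"):
    return PathGap("chr", cat, orient, start, end)


def _paths(intervals, cat=S, orient="reverse"):
    return [ReadPath("chr", cat, orient, s, e) for s, e in intervals]


def _opposite_gaps(path_intervals, seq_len=1000, cat=S, orient="reverse"):
    return detect_path_gaps(_paths(path_intervals, cat, orient), seq_len, "chr", cat, orient)


class TestOppositeCoverage:
    def test_gap_under_continuous_opposite_path_is_excluded(self):
        gap = _gap(500, 600)
        exclude_opposite_covered([gap], _opposite_gaps([(400, 700)]))
        assert gap.excluded and gap.exclusion_reason == "opposite_coverage"

    def test_gap_overlapping_an_opposite_gap_survives(self):
        gap = _gap(500, 600)
        # opposite track broken over [550, 650): the strands agree
        exclude_opposite_covered([gap], _opposite_gaps([(0, 550), (650, 1000)]))
        assert not gap.excluded

    def test_no_opposite_paths_retains_everything(self):
        gap = _gap(500, 600)
        exclude_opposite_covered([gap], _opposite_gaps([]))
        assert not gap.excluded

    def test_nearby_opposite_break_within_slop_retains(self):
        # one physical junction, strand holes a few bases apart
        gap = _gap(500, 503)
        exclude_opposite_covered([gap], _opposite_gaps([(0, 495), (498, 1000)]))
        assert not gap.excluded

    def test_more_opposite_coverage_never_resurrects_a_gap(self):
        """Exclusion is monotone in opposite-strand coverage."""
        sparse = _opposite_gaps([(0, 400)])          # big trailing gap
        dense = _opposite_gaps([(0, 400), (420, 1000)])
        g1, g2 = _gap(500, 600), _gap(500, 600)
        exclude_opposite_covered([g1], sparse)
        exclude_opposite_covered([g2], dense)
        # the denser track can only add exclusions
        assert (not g2.excluded) <= (not g1.excluded)


class TestTypeAlternation:
    def test_successor_takeover_excludes_gap(self):
        # Single path ends at 500; Single_Multiple path [480, 900)
        # covers the gap beginning with ample overlap
        ts = build_track_set(
            2000,
            {
                (S, "forward"): [(0, 500), (1500, 2000)],
                (SM, "forward"): [(480, 900)],
            },
        )
        exclude_by_type_alternation(ts, "forward")
        gap = ts.track_gaps(S, "forward")[0]
        assert (gap.start, gap.end) == (500, 1500)
        assert gap.excluded and gap.exclusion_reason == "type_alternation"

    def test_repeated_type_retains_gap(self):
        # a Single path followed by another Single path: repetition
        ts = build_track_set(
            2000,
            {(S, "forward"): [(0, 500), (600, 2000)]},
        )
        exclude_by_type_alternation(ts, "forward")
        assert not ts.track_gaps(S, "forward")[0].excluded

    def test_skipped_type_retains_flanking_gaps(self):
        # Multiple path followed directly by Single (Multiple_Single missed)
        ts = build_track_set(
            3000,
            {
                (M, "forward"): [(500, 1000)],
                (S, "forward"): [(1100, 1600)],
            },
        )
        exclude_by_type_alternation(ts, "forward")
        for cat in (M, S):
            for gap in ts.track_gaps(cat, "forward"):
                assert not gap.excluded

    def test_insufficient_overlap_does_not_exclude(self):
        # successor path overlaps the gap beginning by only 4 bases
        ts = build_track_set(
            2000,
            {
                (S, "forward"): [(0, 500), (1500, 2000)],
                (SM, "forward"): [(496, 504)],
            },
        )
        exclude_by_type_alternation(ts, "forward")
        assert not ts.track_gaps(S, "forward")[0].excluded

    def test_leading_gap_judged_by_predecessor_at_its_end(self):
        # the walk arrives at the first Single path from a Multiple_Single
        # path covering the leading gap's end
        ts = build_track_set(
            2000,
            {
                (S, "forward"): [(500, 2000)],
                (MS, "forward"): [(100, 520)],
            },
        )
        exclude_by_type_alternation(ts, "forward")
        gap = ts.track_gaps(S, "forward")[0]
        assert (gap.start, gap.end) == (0, 500)
        assert gap.excluded

    def test_matches_brute_force_cycle_predicate(self):
        """Randomized track sets: decisions equal an exhaustive checker."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq_len = 5000
            tracks = {}
            for cat in CATEGORY_CYCLE:
                ivs = []
                pos = 0
                for _ in range(rng.integers(0, 6)):
                    pos += int(rng.integers(1, 400))
                    end = pos + int(rng.integers(50, 600))
                    if end >= seq_len:
                        break
                    ivs.append((pos, end))
                    pos = end
                tracks[(cat, "forward")] = ivs
            ts = build_track_set(seq_len, tracks)
            exclude_by_type_alternation(ts, "forward")
            for cat in CATEGORY_CYCLE:
                own = ts.track_paths(cat, "forward")
                succ = ts.track_paths(_successor(cat), "forward")
                pred_cat = CATEGORY_CYCLE[(CATEGORY_CYCLE.index(cat) - 1) % 4]
                pred = ts.track_paths(pred_cat, "forward")
                for gap in ts.track_gaps(cat, "forward"):
                    left = [p for p in own if p.end == gap.start]
                    right = [p for p in own if p.start == gap.end]
                    expect = False
                    if left:
                        expect = any(
                            p.start <= gap.start < p.end
                            and min(p.end, gap.end) - max(p.start, gap.start) >= 6
                            and min(p.end, left[0].end) - max(p.start, left[0].start) >= 6
                            for p in succ
                        )
                    elif right:
                        expect = any(
                            p.start < gap.end <= p.end
                            and min(p.end, gap.end) - max(p.start, gap.start) >= 6
                            and min(p.end, right[0].end) - max(p.start, right[0].start) >= 6
                            for p in pred
                        )
                    assert gap.excluded == expect, (cat, gap.start, gap.end)


class TestPipelineOrder:
    def test_rules_commute_on_disjoint_evidence(self):
        """When each gap is decided by one rule only, application order
        does not change the final excluded set."""
        tracks = {
            (S, "forward"): [(0, 500), (1500, 3000)],
            (SM, "forward"): [(480, 900)],      # explains the S gap (cycle)
            (S, "reverse"): [(0, 2000), (2600, 3000)],
        }
        ts1 = build_track_set(3000, tracks)
        apply_gap_filters(ts1)  # opposite first, then alternation
        ts2 = build_track_set(3000, tracks)
        for orient in ("forward", "reverse"):
            exclude_by_type_alternation(ts2, orient)
        from asmbreak.gap_filter import OPPOSITE

        for (cat, orient), gaps in ts2.gaps.items():
            exclude_opposite_covered(gaps, ts2.track_gaps(cat, OPPOSITE[orient]))
        for key in ts1.gaps:
            flags1 = [g.excluded for g in ts1.gaps[key]]
            flags2 = [g.excluded for g in ts2.gaps[key]]
            assert flags1 == flags2

    def test_uncovered_regions_are_never_excluded(self):
        """A hole with no coverage in either orientation (N-run or zero
        coverage) survives both rules in every track."""
        hole = (1000, 1200)
        tracks = {}
        for cat, orient in ((S, "forward"), (S, "reverse")):
            tracks[(cat, orient)] = [(0, hole[0]), (hole[1], 3000)]
        ts = build_track_set(3000, tracks)
        apply_gap_filters(ts)
        for orient in ("forward", "reverse"):
            (gap,) = ts.track_gaps(S, orient)
            assert (gap.start, gap.end) == hole
            assert not gap.excluded
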