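"""Insert-bounds estimation and the five properly-mapped conditions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmbreak.alignment_io import ReadAlignmentSet
from asmbreak.pair_builder import (
    Category,
    InsertBounds,
    categorize_pair,
    estimate_insert_bounds,
    form_proper_pairs,
    satisfies_conditions,
)
from conftest import make_record

LENGTHS = {"chr": 100000}
BOUNDS = InsertBounds(min_insert=500, max_insert=900, point_estimate=700)


def _sets(aligns1, aligns2):
    s1 = ReadAlignmentSet("r", 1, [make_record(*a[:2], orientation=a[2], mate=1, **(a[3] if len(a) > 3 else {})) for a in aligns1])
    s2 = ReadAlignmentSet("r", 2, [make_record(*a[:2], orientation=a[2], mate=2, **(a[3] if len(a) > 3 else {})) for a in aligns2])
    return s1, s2


class TestInsertBounds:
    def test_recovers_normal_insert_distribution(self):
        rng = np.random.default_rng(7)
        draws = np.rint(rng.normal(700, 40, size=10000)).astype(np.int64)
        bounds = estimate_insert_bounds(draws)
        covered = np.mean((draws >= bounds.min_insert) & (draws <= bounds.max_insert))
        assert covered >= 0.999
        assert abs(bounds.point_estimate - 700) <= 5

    def test_zero_spread_collapses_bounds(self):
        bounds = estimate_insert_bounds(np.full(2000, 700, dtype=np.int64))
        assert (bounds.min_insert, bounds.max_insert) == (700, 700)

    def test_robust_to_contaminating_inserts(self):
        rng = np.random.default_rng(8)
        clean = np.rint(rng.normal(700, 40, size=9900)).astype(np.int64)
        dirty = np.concatenate([clean, np.full(100, 10000, dtype=np.int64)])
        b_clean = estimate_insert_bounds(clean)
        b_dirty = estimate_insert_bounds(dirty)
        assert abs(b_dirty.point_estimate - b_clean.point_estimate) <= 3
        assert abs(b_dirty.max_insert - b_clean.max_insert) <= 10

    def test_small_sample_warns_and_empty_is_fatal(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="asmbreak.pair_builder"):
            estimate_insert_bounds(np.full(10, 700, dtype=np.int64))
        assert any("qualifying pairs" in m for m in caplog.messages)
        with pytest.raises(ValueError):
            estimate_insert_bounds(np.array([], dtype=np.int64))


class TestProperPairFormation:
    def test_canonical_fr_pair(self):
        s1, s2 = _sets([(100, 350, "forward")], [(600, 850, "reverse")])
        (pair,) = form_proper_pairs(s1, s2, BOUNDS, LENGTHS)
        assert pair.insert == 750
        assert pair.category is Category.SINGLE

    def test_fully_overlapping_pair_accepted(self):
        # reverse alignment at the same position as the forward one
        s1, s2 = _sets([(600, 850, "forward")], [(600, 850, "reverse")])
        pairs = form_proper_pairs(
            s1, s2, InsertBounds(100, 900, 700), LENGTHS
        )
        assert len(pairs) == 1

    def test_begin_clip_rejected_except_at_sequence_edges(self):
        clip = {"clip_begin": True}
        s1, s2 = _sets([(100, 350, "forward", clip)], [(600, 850, "reverse")])
        assert form_proper_pairs(s1, s2, BOUNDS, LENGTHS) == []
        # forward read clipped at the very beginning of the sequence
        s1, s2 = _sets([(0, 250, "forward", clip)], [(500, 750, "reverse")])
        assert len(form_proper_pairs(s1, s2, BOUNDS, LENGTHS)) == 1
        # reverse read clipped but reaching the sequence end
        L = LENGTHS["chr"]
        s1, s2 = _sets([(L - 750, L - 500, "forward")], [(L - 250, L, "reverse", clip)])
        assert len(form_proper_pairs(s1, s2, BOUNDS, LENGTHS)) == 1

    def test_selected_combinations_of_multimappers(self):
        s1, s2 = _sets(
            [(100, 350, "forward"), (5000, 5250, "forward")],
            [(600, 850, "reverse"), (9000, 9250, "reverse")],
        )
        pairs = form_proper_pairs(s1, s2, BOUNDS, LENGTHS)
        assert len(pairs) == 1  # only (100..350, 600..850) fits the bounds
        assert pairs[0].category is Category.MULTIPLE

    def test_combination_cap_skips_pair(self):
        s1, s2 = _sets(
            [(i * 1000, i * 1000 + 250, "forward") for i in range(5)],
            [(i * 1000 + 450, i * 1000 + 700, "reverse") for i in range(5)],
        )
        assert form_proper_pairs(s1, s2, BOUNDS, LENGTHS, max_combinations=10) == []

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        """Pair formation equals an exhaustive check of all combinations."""
        n1 = data.draw(st.integers(1, 6))
        n2 = data.draw(st.integers(1, 6))

        def draw_aligns(n, mate):
            out = []
            for i in range(n):
                start = data.draw(st.integers(0, 2000))
                length = data.draw(st.integers(50, 300))
                orient = data.draw(st.sampled_from(["forward", "reverse"]))
                cb = data.draw(st.booleans())
                out.append(
                    make_record(
                        start,
                        start + length,
                        orient,
                        seq_name="chr",
                        mate=mate,
                        clip_begin=cb,
                    )
                )
            return out

        a1 = draw_aligns(n1, 1)
        a2 = draw_aligns(n2, 2)
        s1 = ReadAlignmentSet("r", 1, a1)
        s2 = ReadAlignmentSet("r", 2, a2)
        bounds = InsertBounds(200, 800, 500)
        got = {
            ((p.fwd.start, p.fwd.end), (p.rev.start, p.rev.end))
            for p in form_proper_pairs(s1, s2, bounds, LENGTHS)
        }
        expected = set()
        for x in a1:
            for y in a2:
                for fwd, rev in ((x, y), (y, x)):
                    if satisfies_conditions(fwd, rev, bounds, LENGTHS):
                        expected.add(((fwd.start, fwd.end), (rev.start, rev.end)))
        assert got == expected
        # swapping the mate files never changes the produced intervals
        got_swapped = {
            ((p.fwd.start, p.fwd.end), (p.rev.start, p.rev.end))
            for p in form_proper_pairs(s2, s1, bounds, LENGTHS)
        }
        assert got_swapped == got


class TestCategorization:
    @pytest.mark.parametrize(
        "fm,rm,expected",
        [
            (1, 1, Category.SINGLE),
            (1, 3, Category.SINGLE_MULTIPLE),
            (3, 1, Category.MULTIPLE_SINGLE),
            (5, 5, Category.MULTIPLE),
        ],
    )
    def test_multiplicity_mapping(self, fm, rm, expected):
        assert categorize_pair(fm, rm) is expected

    def test_zero_multiplicity_is_an_assertion_failure(self):
        with pytest.raises(AssertionError):
            categorize_pair(0, 1)
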