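"""Path-gap exclusion rules.

Path gaps arise for three reasons: a genuine assembly error, a region
that is simply carried by paths of a *different* repeat category, or
thin read coverage.  Two rules remove the second kind:

* **opposite-orientation coverage** — a gap fully covered by a single
  path of the same category in the opposite orientation is not an
  error (the opposite strand demonstrates the region is intact);
  equivalently a gap survives only if it overlaps some gap of the
  opposite-orientation track of its category;

* **type alternation** — along the sequence the path categories of one
  orientation alternate in a fixed cycle around each repeat:
  Single → Single_Multiple → Multiple → Multiple_Single → Single …
  (the cycle may start anywhere).  A gap whose flank is taken over by
  the cyclically *next* category's path — with both the gap beginning
  and the adjacent path overlapping that path by more than 5 bases —
  is a normal repeat transition, not an error.  A repeated or skipped
  category breaks the cycle and the gap is kept.

Gaps caused by low coverage or N-runs match neither rule and are never
excluded; they are accepted as the method's residual false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .pair_builder import CATEGORY_CYCLE, Category
from .path_builder import MERGE_MIN_OVERLAP, PathGap, ReadPath

OPPOSITE = {"forward": "reverse", "reverse": "forward"}


def _successor(cat: Category) -> Category:
    i = CATEGORY_CYCLE.index(cat)
    return CATEGORY_CYCLE[(i + 1) % 4]


def _predecessor(cat: Category) -> Category:
    i = CATEGORY_CYCLE.index(cat)
    return CATEGORY_CYCLE[(i - 1) % 4]


@dataclass
class TrackSet:
    """All eight tracks (4 categories x 2 orientations) of one sequence."""

    seq_name: str
    seq_length: int
    paths: dict[tuple[Category, str], list[ReadPath]] = field(default_factory=dict)
    gaps: dict[tuple[Category, str], list[PathGap]] = field(default_factory=dict)

    def track_paths(self, category: Category, orientation: str) -> list[ReadPath]:
        return self.paths.get((category, orientation), [])

    def track_gaps(self, category: Category, orientation: str) -> list[PathGap]:
        return self.gaps.get((category, orientation), [])


def exclude_opposite_covered(
    gaps: Sequence[PathGap],
    opposite_gaps: Sequence[PathGap],
    margin: int = MERGE_MIN_OVERLAP - 1,
) -> None:
    """Exclude gaps with no counterpart gap on the opposite strand.

    A gap that does not overlap any gap of the same category in the
    opposite orientation lies under continuous opposite-strand coverage,
    so the region is intact and the gap reflects one strand's thin
    coverage.  Both gaps are dilated by ``margin`` bases before the
    overlap test: alignments extend past a shared breakpoint by a few
    chance-matching bases, so the two strands' holes for one junction
    can sit just apart, and flush opposite coverage within that slop is
    not evidence against an error.  An empty opposite track (one gap
    spanning the sequence) retains everything, vacuously.
    """
    for gap in gaps:
        if gap.excluded:
            continue
        survives = any(
            g2.start - margin < gap.end + margin
            and g2.end + margin > gap.start - margin
            for g2 in opposite_gaps
        )
        if not survives:
            gap.exclude("opposite_coverage")


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def exclude_by_type_alternation(
    track_set: TrackSet, orientation: str, strict_cycle: bool = True
) -> None:
    """Mark gaps explained by correct cyclic alternation of path types.

    A gap of track T with a left flanking path L is judged by its
    beginning only: it is excluded when some path of category
    successor(T) covers the gap beginning and overlaps both the gap and
    L by more than 5 bases (any covering path with correct type order
    and location wins).  A leading gap — no own-track path to its left —
    is judged by the mirrored test at its end against predecessor(T)
    paths, since the walk arrives there from the predecessor type.  A
    covering path whose category repeats T or skips a cycle position
    never excludes; judging only one flank keeps a long gap alive when
    its far side hides an error even though its near side looks like a
    normal repeat transition.  With ``strict_cycle`` false, gaps
    touching the sequence boundaries are additionally excluded when any
    other-category path covers their free end — a relaxation for the
    unmodelled special cases at sequence ends.
    """
    for cat in CATEGORY_CYCLE:
        gaps = track_set.track_gaps(cat, orientation)
        own = track_set.track_paths(cat, orientation)
        succ_paths = track_set.track_paths(_successor(cat), orientation)
        pred_paths = track_set.track_paths(_predecessor(cat), orientation)
        for gap in gaps:
            if gap.excluded:
                continue
            left = _left_path(own, gap)
            right = _right_path(own, gap)
            if left is not None and _covered_in_order(gap, left, succ_paths, side="left"):
                gap.exclude("type_alternation")
                continue
            # the walk arrives at a leading gap from the predecessor type;
            # gaps with a left flank are judged by their beginning only
            if (
                left is None
                and right is not None
                and _covered_in_order(gap, right, pred_paths, side="right")
            ):
                gap.exclude("type_alternation")
                continue
            if not strict_cycle and (left is None or right is None):
                candidates = [
                    p
                    for other in CATEGORY_CYCLE
                    if other != cat
                    for p in track_set.track_paths(other, orientation)
                ]
                for p in candidates:
                    if left is None and p.start <= gap.start < p.end:
                        gap.exclude("type_alternation")
                        break
                    if right is None and p.start < gap.end <= p.end:
                        gap.exclude("type_alternation")
                        break


def _left_path(own_paths: Sequence[ReadPath], gap: PathGap) -> ReadPath | None:
    for p in own_paths:
        if p.end == gap.start:
            return p
    return None


def _right_path(own_paths: Sequence[ReadPath], gap: PathGap) -> ReadPath | None:
    for p in own_paths:
        if p.start == gap.end:
            return p
    return None


def _covered_in_order(
    gap: PathGap, flank: ReadPath, candidate_paths: Sequence[ReadPath], side: str
) -> bool:
    """Does a correct-category path take over the gap's flank?

    ``side == "left"``: the path must cover the gap beginning;
    ``side == "right"``: the mirror test at the gap end.  In both cases
    the path must overlap the gap and the adjacent own-category path by
    at least MERGE_MIN_OVERLAP bases.
    """
    for p in candidate_paths:
        if _overlap(p.start, p.end, gap.start, gap.end) < MERGE_MIN_OVERLAP:
            continue
        if _overlap(p.start, p.end, flank.start, flank.end) < MERGE_MIN_OVERLAP:
            continue
        if side == "left" and p.start <= gap.start < p.end:
            return True
        if side == "right" and p.start < gap.end <= p.end:
            return True
    return False


def apply_gap_filters(track_set: TrackSet, strict_cycle: bool = True) -> None:
    """Run both exclusion rules on every track of a sequence.

    Opposite-orientation exclusion runs first, then type alternation —
    the two commute where each gap is decided by a single rule, so the
    order only fixes which reason is recorded.
    """
    for (cat, orient), gaps in track_set.gaps.items():
        exclude_opposite_covered(gaps, track_set.track_gaps(cat, OPPOSITE[orient]))
    for orient in ("forward", "reverse"):
        exclude_by_type_alternation(track_set, orient, strict_cycle=strict_cycle)
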