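"""Read-path construction and path-gap detection.

Alignments of properly paired reads, split by repeat category and
orientation, are chained into *read paths*: maximal runs of intervals in
which each neighbour overlaps the growing path by more than 5 bases.
The 5-base limit discards overlaps that reflect alignment uncertainty
rather than genuine shared positions; a 1–5 base overlap is clipped away
so that an uncovered hole separates the two paths, and touching or
disjoint intervals start a new path.  Paths are the assembly fragments
treated as free of structural errors; the complement intervals of a
track — the *path gaps* — are the error candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .pair_builder import Category

MERGE_MIN_OVERLAP = 6  # "more than 5 bases"


@dataclass(frozen=True, slots=True)
class ReadPath:
    seq_name: str
    category: Category
    orientation: str
    start: int
    end: int


@dataclass(slots=True)
class PathGap:
    seq_name: str
    category: Category
    orientation: str
    start: int
    end: int
    excluded: bool = False
    exclusion_reason: str | None = None
    adjusted_start: int = field(default=-1)
    adjusted_end: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.adjusted_start < 0:
            self.adjusted_start = self.start
        if self.adjusted_end < 0:
            self.adjusted_end = self.end

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclusion_reason = reason


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Chain intervals into path extents under the >5-base overlap rule.

    Input intervals are deduplicated and swept in (start, end) order; the
    current path's (possibly already extended) end is used for each
    overlap test.  Overlap b with the next interval:

    * b >= 6           — merged into the current path;
    * 1 <= b <= 5      — the shared bases are clipped from both sides
                         (path end retreats to the interval start, the
                         interval start advances to the old path end),
                         leaving a b-base uncovered hole;
    * b == 0 (touching) — a 1-base hole is enforced by retracting the
                         path end, keeping paths separated by >= 1 base;
    * b < 0            — a new path simply starts.
    """
    ivs = sorted(set(intervals))
    if not ivs:
        return []
    out: list[tuple[int, int]] = []
    cur_start, cur_end = ivs[0]
    for s, e in ivs[1:]:
        overlap = min(cur_end, e) - s
        if overlap >= MERGE_MIN_OVERLAP:
            cur_end = max(cur_end, e)
            continue
        if e <= cur_end:
            # short interval buried in the path; nothing new to chain
            continue
        if overlap > 0:
            new_left_end, new_right_start = s, cur_end
        elif overlap == 0:
            new_left_end, new_right_start = s - 1, cur_end
        else:
            new_left_end, new_right_start = cur_end, s
        if new_left_end > cur_start:
            out.append((cur_start, new_left_end))
        cur_start, cur_end = new_right_start, e
    if cur_end > cur_start:
        out.append((cur_start, cur_end))
    return out


def build_paths(
    intervals: Sequence[tuple[int, int]],
    seq_name: str,
    category: Category,
    orientation: str,
) -> list[ReadPath]:
    """Read paths of one (sequence, category, orientation) track."""
    return [
        ReadPath(seq_name, category, orientation, s, e)
        for s, e in merge_intervals(intervals)
    ]


def detect_path_gaps(paths: Sequence[ReadPath], seq_length: int,
                     seq_name: str | None = None,
                     category: Category | None = None,
                     orientation: str | None = None) -> list[PathGap]:
    """Complement of a track's paths over [0, seq_length).

    Includes the leading gap before the first path and the trailing gap
    after the last one when non-empty; an empty track yields one gap
    spanning the whole sequence.
    """
    if paths:
        seq_name = paths[0].seq_name
        category = paths[0].category
        orientation = paths[0].orientation
    elif seq_name is None or category is None or orientation is None:
        raise ValueError("empty track requires explicit seq_name/category/orientation")
    gaps: list[PathGap] = []
    prev_end = 0
    for p in paths:
        if p.start > prev_end:
            gaps.append(PathGap(seq_name, category, orientation, prev_end, p.start))
        prev_end = p.end
    if prev_end < seq_length:
        gaps.append(PathGap(seq_name, category, orientation, prev_end, seq_length))
    return gaps
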