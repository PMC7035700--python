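"""Error location adjustment and final call emission.

Every path gap that survives filtering is treated as containing an
assembly error.  Its bounds are narrowed against the pooled coverage of
*all* categories of its orientation: the gap beginning is shifted right
to the far edge of the coverage block overhanging it, the gap end left
to the near edge of the block overhanging the other side, and a gap
fully covered by one block (or collapsed by the shifts) is excluded.
Per orientation the adjusted gaps of the four categories are unioned
and reduced to their uncovered holes; the final error calls are the
intersection of the forward and reverse evidence, minus the
sequence-end regions one read length deep where properly mapped pairs
cannot exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .path_builder import PathGap, ReadPath

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class ErrorCall:
    seq_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid call [{self.start}, {self.end})")


def pooled_coverage_blocks(pooled_paths: Sequence[ReadPath]) -> list[tuple[int, int]]:
    """Chain orientation-pooled paths of all categories into coverage blocks.

    The same >5-base chaining rule used for read merging applies: paths
    overlapping by more than 5 bases form one continuous block, while a
    0-5 base overlap (the signature of a suspicious junction) leaves the
    blocks separated by an uncovered hole.
    """
    from .path_builder import merge_intervals

    return merge_intervals([(p.start, p.end) for p in pooled_paths])


def adjust_gap(gap: PathGap, pooled_blocks: Sequence[tuple[int, int]]) -> None:
    """Shrink one retained gap against pooled coverage blocks.

    The gap beginning is shifted right to the end of the coverage block
    overhanging it (the rightmost end its chained paths reach), and the
    gap end left to the start of the block overhanging the other side.
    Coverage strictly interior to the gap does not move the bounds —
    uncovered holes beside it surface through the other categories'
    own gaps.  A gap fully covered by one block, or whose bounds cross
    after the shifts (coverage continuous across it), is excluded.
    """
    if gap.excluded:
        return
    new_start, new_end = gap.start, gap.end
    for bs, be in pooled_blocks:
        if bs <= gap.start and gap.end <= be:
            gap.exclude("covered_after_pooling")
            return
        if bs <= gap.start < be:
            new_start = max(new_start, be)
        if bs < gap.end <= be:
            new_end = min(new_end, bs)
    if new_start >= new_end:
        gap.exclude("collapsed_after_adjustment")
        return
    gap.adjusted_start, gap.adjusted_end = new_start, new_end


def _union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract(
    intervals: Sequence[tuple[int, int]], blocks: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Remove block-covered stretches from a sorted disjoint interval set."""
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        cur = s
        for bs, be in blocks:
            if be <= cur:
                continue
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def combine_and_intersect(
    fwd_gaps: Iterable[PathGap],
    rev_gaps: Iterable[PathGap],
    seq_name: str,
    fwd_blocks: Sequence[tuple[int, int]] = (),
    rev_blocks: Sequence[tuple[int, int]] = (),
    junction_uncertainty: int = 5,
) -> list[ErrorCall]:
    """Union adjusted gaps per orientation, intersect the two unions.

    An adjusted gap stretching between two distant breakpoints still
    spans well-covered interior sequence, so each orientation's union is
    first reduced to its uncovered holes by subtracting the pooled
    coverage blocks.  Alignments also extend past a breakpoint by
    however many bases match by chance, leaving the forward- and
    reverse-strand holes for one physical junction a few bases apart;
    each reduced union is therefore dilated by ``junction_uncertainty``
    bases (the same 5-base margin the merge and order rules use for
    alignment uncertainty) before intersecting.
    """
    j = max(0, junction_uncertainty)
    unions = []
    for gaps, blocks in ((fwd_gaps, fwd_blocks), (rev_gaps, rev_blocks)):
        u = _union((g.adjusted_start, g.adjusted_end) for g in gaps if not g.excluded)
        u = _subtract(u, blocks)
        unions.append(_union((s - j, e + j) for s, e in u))
    return [
        ErrorCall(seq_name, max(0, s), e) for s, e in _intersect(unions[0], unions[1])
    ]


def trim_sequence_ends(
    calls: Sequence[ErrorCall], seq_length: int, read_length: int
) -> list[ErrorCall]:
    """Drop or truncate calls inside one read length of the sequence ends.

    Pairs satisfying the properly-mapped conditions cannot anchor these
    regions, so calls there are artefacts of missing evidence.
    """
    if seq_length < 2 * read_length:
        if calls:
            logger.warning(
                "sequence of length %d shorter than twice the read length; "
                "all %d calls dropped",
                seq_length,
                len(calls),
            )
        return []
    lo, hi = read_length, seq_length - read_length
    out: list[ErrorCall] = []
    for c in calls:
        s, e = max(c.start, lo), min(c.end, hi)
        if s < e:
            out.append(ErrorCall(c.seq_name, s, e))
    return out


def merge_adjacent(calls: Sequence[ErrorCall], merge_distance: int = 0) -> list[ErrorCall]:
    """Optionally merge calls separated by at most ``merge_distance`` bases."""
    if merge_distance < 0 or not calls:
        return list(calls)
    srt = sorted(calls, key=lambda c: (c.seq_name, c.start))
    out = [srt[0]]
    for c in srt[1:]:
        prev = out[-1]
        if c.seq_name == prev.seq_name and c.start - prev.end <= merge_distance and merge_distance > 0:
            out[-1] = ErrorCall(prev.seq_name, prev.start, max(prev.end, c.end))
        else:
            out.append(c)
    return out


def write_bed(calls: Sequence[ErrorCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.seq_name, c.start, c.end)):
            fh.write(f"{c.seq_name}\t{c.start}\t{c.end}\n")
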