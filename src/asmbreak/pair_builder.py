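"""Properly mapped read pair formation and repeat-context categorization.

A forward/reverse alignment combination of the two mates is a *properly
mapped pair* when five conditions hold:

1. both alignments lie on the same assembly sequence;
2. the alignments have opposite orientations;
3. the reverse alignment starts at the same position as, or downstream
   of, the forward alignment;
4. neither read's file-beginning is clipped — except a forward read at
   the very beginning of the sequence or a reverse read reaching its
   very end;
5. the insert (outermost span, ``rev.end - fwd.start``) lies within the
   estimated bounds.

Pairs are then labelled by the alignment multiplicity of each end:
``Single`` (1,1), ``Single_Multiple`` (1,>1), ``Multiple_Single`` (>1,1)
and ``Multiple`` (>1,>1) — unique reads anchor non-repeated sequence,
multi-mapping reads sit in repeats, and the mixed groups mark the
transitions between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np

from .alignment_io import AlignmentRecord, ReadAlignmentSet

logger = logging.getLogger(__name__)

MIN_SAMPLE_PAIRS = 1000


class Category(str, Enum):
    SINGLE = "Single"
    SINGLE_MULTIPLE = "Single_Multiple"
    MULTIPLE_SINGLE = "Multiple_Single"
    MULTIPLE = "Multiple"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# cyclic order of path types along the sequence around a repeat
CATEGORY_CYCLE: tuple[Category, ...] = (
    Category.SINGLE,
    Category.SINGLE_MULTIPLE,
    Category.MULTIPLE,
    Category.MULTIPLE_SINGLE,
)


@dataclass(frozen=True, slots=True)
class InsertBounds:
    min_insert: int
    max_insert: int
    point_estimate: int

    def __post_init__(self) -> None:
        if not 0 < self.min_insert <= self.point_estimate <= self.max_insert:
            raise ValueError(f"inconsistent insert bounds {self}")


@dataclass(frozen=True, slots=True)
class ProperPair:
    fwd: AlignmentRecord
    rev: AlignmentRecord
    category: Category

    @property
    def seq_name(self) -> str:
        return self.fwd.seq_name

    @property
    def insert(self) -> int:
        return self.rev.end - self.fwd.start


def _is_clean_unique(s: ReadAlignmentSet) -> AlignmentRecord | None:
    """The single alignment of a uniquely, fully mapped read, else None."""
    if s.multiplicity != 1:
        return None
    a = s.alignments[0]
    if a.clip_read_begin or a.clip_read_end:
        return None
    return a


def sample_inserts(
    pairs: Iterable[tuple[ReadAlignmentSet, ReadAlignmentSet]],
    max_sample: int = 10000,
) -> np.ndarray:
    """Outermost-span inserts of unambiguous FR pairs (estimation sample).

    A pair qualifies when both ends map uniquely and unclipped on one
    sequence, in FR orientation (forward alignment upstream of reverse).
    """
    inserts: list[int] = []
    for s1, s2 in pairs:
        a1, a2 = _is_clean_unique(s1), _is_clean_unique(s2)
        if a1 is None or a2 is None or a1.seq_name != a2.seq_name:
            continue
        if a1.orientation == a2.orientation:
            continue
        fwd, rev = (a1, a2) if a1.orientation == "forward" else (a2, a1)
        if rev.start < fwd.start:
            continue
        inserts.append(rev.end - fwd.start)
        if len(inserts) >= max_sample:
            break
    return np.asarray(inserts, dtype=np.int64)


def estimate_insert_bounds(
    pairs_sample: Iterable[tuple[ReadAlignmentSet, ReadAlignmentSet]] | np.ndarray,
    k: float = 4.0,
) -> InsertBounds:
    """Robust insert-size bounds: median ± k · (1.4826 · MAD).

    With k=4 the bounds cover ≈99.99% of a normal insert distribution
    while staying insensitive to the occasional chimeric or mis-placed
    pair.  Accepts either raw (set, set) pairs or a precomputed insert
    array.
    """
    if isinstance(pairs_sample, np.ndarray):
        inserts = pairs_sample.astype(np.int64)
    else:
        inserts = sample_inserts(pairs_sample)
    if inserts.size == 0:
        raise ValueError("no qualifying read pairs to estimate insert size from")
    if inserts.size < MIN_SAMPLE_PAIRS:
        logger.warning(
            "only %d qualifying pairs for insert estimation (<%d); using all",
            inserts.size,
            MIN_SAMPLE_PAIRS,
        )
    med = float(np.median(inserts))
    mad = float(np.median(np.abs(inserts - med)))
    spread = k * 1.4826 * mad
    return InsertBounds(
        min_insert=max(1, int(np.floor(med - spread))),
        max_insert=int(np.ceil(med + spread)),
        point_estimate=int(round(med)),
    )


def satisfies_conditions(
    fwd: AlignmentRecord,
    rev: AlignmentRecord,
    bounds: InsertBounds,
    seq_lengths: Mapping[str, int],
    end_slack: int = 0,
) -> bool:
    """Check the five properly-mapped conditions for an oriented combination."""
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        return False
    if fwd.seq_name != rev.seq_name:  # condition 1
        return False
    # condition 2 holds by construction (orientations differ)
    if rev.start < fwd.start:  # condition 3
        return False
    # condition 4: file-beginnings unclipped, with the sequence-end exceptions
    if fwd.clip_read_begin and fwd.start > end_slack:
        return False
    seq_len = seq_lengths[fwd.seq_name]
    if rev.clip_read_begin and rev.end < seq_len - end_slack:
        return False
    insert = rev.end - fwd.start  # condition 5
    return bounds.min_insert <= insert <= bounds.max_insert


def categorize_pair(fwd_multiplicity: int, rev_multiplicity: int) -> Category:
    """Repeat-context group from the two ends' alignment multiplicities."""
    assert fwd_multiplicity >= 1 and rev_multiplicity >= 1
    if fwd_multiplicity == 1:
        return Category.SINGLE if rev_multiplicity == 1 else Category.SINGLE_MULTIPLE
    return Category.MULTIPLE_SINGLE if rev_multiplicity == 1 else Category.MULTIPLE


def form_proper_pairs(
    set1: ReadAlignmentSet,
    set2: ReadAlignmentSet,
    bounds: InsertBounds,
    seq_lengths: Mapping[str, int],
    max_combinations: int = 10000,
    end_slack: int = 0,
) -> list[ProperPair]:
    """All properly mapped pairs formable from one input read pair.

    Every combination of one alignment per mate is tried, with either
    mate in the forward role as its orientation dictates; an input pair
    may yield none, one or several properly mapped pairs.
    """
    n_comb = set1.multiplicity * set2.multiplicity
    if n_comb == 0:
        return []
    if n_comb > max_combinations:
        logger.warning(
            "read %s: %d alignment combinations exceed cap %d; pair skipped",
            set1.read_id,
            n_comb,
            max_combinations,
        )
        return []
    m1, m2 = set1.multiplicity, set2.multiplicity
    out: list[ProperPair] = []
    for a1 in set1.alignments:
        for a2 in set2.alignments:
            if a1.orientation == a2.orientation:
                continue
            if a1.orientation == "forward":
                fwd, rev = a1, a2
                fm, rm = m1, m2
            else:
                fwd, rev = a2, a1
                fm, rm = m2, m1
            if satisfies_conditions(fwd, rev, bounds, seq_lengths, end_slack):
                out.append(ProperPair(fwd=fwd, rev=rev, category=categorize_pair(fm, rm)))
    return out


def iter_proper_pairs(
    read_pairs: Iterable[tuple[ReadAlignmentSet, ReadAlignmentSet]],
    bounds: InsertBounds,
    seq_lengths: Mapping[str, int],
    max_combinations: int = 10000,
    end_slack: int = 0,
) -> Iterator[ProperPair]:
    for s1, s2 in read_pairs:
        yield from form_proper_pairs(
            s1, s2, bounds, seq_lengths, max_combinations, end_slack
        )
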