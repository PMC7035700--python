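"""SAM ingestion for report-all local alignments.

The upstream aligner is run in local mode, once per read file, reporting
every alignment of every read (so alignments of one mate are independent
of the other).  This module normalizes those records into per-read
alignment sets with two pieces of semantics the rest of the pipeline
relies on:

* all coordinates are 0-based half-open on the assembly;
* clipping is expressed in *read-file* coordinates: for a reverse-strand
  alignment a CIGAR clip on the assembly-left side is a clip of the
  read's *end* as it appears in the FASTQ, and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger(__name__)

@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One local alignment of one read end on one assembly sequence."""

    read_id: str
    mate: int  # 1 or 2: which input read file the read came from
    seq_name: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    orientation: str  # "forward" | "reverse" relative to the assembly
    clip_read_begin: bool  # first bases of the read *as given in the file* unaligned
    clip_read_end: bool
    aligned_length: int  # read bases consumed by the alignment

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass
class ReadAlignmentSet:
    """All alignments reported for one read end (possibly none)."""

    read_id: str
    mate: int
    alignments: list[AlignmentRecord] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.alignments)


def _clips_from_cigar(cigartuples, is_reverse: bool) -> tuple[bool, bool, int]:
    """Derive file-coordinate clip flags and aligned read length from a CIGAR.

    pysam cigartuples are in assembly orientation; a leading soft/hard clip
    sits at the assembly-left end.  For a reverse-strand alignment the
    assembly-left end is the read's file *end*, so the flags swap.
    """
    lead_clip = bool(cigartuples) and cigartuples[0][0] in (4, 5)
    tail_clip = bool(cigartuples) and cigartuples[-1][0] in (4, 5)
    aligned = sum(n for op, n in cigartuples if op in (0, 1, 7, 8))  # M, I, =, X
    if is_reverse:
        lead_clip, tail_clip = tail_clip, lead_clip
    return lead_clip, tail_clip, aligned


def record_from_segment(
    seg: pysam.AlignedSegment, mate: int, assembly_lengths: Mapping[str, int] | None = None
) -> AlignmentRecord | None:
    """Convert one mapped SAM record; returns None for unmapped records."""
    if seg.is_unmapped:
        return None
    if seg.cigartuples is None:
        raise ValueError(f"mapped record without CIGAR: {seg.query_name}")
    seq_name = seg.reference_name
    if assembly_lengths is not None and seq_name not in assembly_lengths:
        raise KeyError(f"alignment on unknown sequence {seq_name!r}")
    begin_clip, end_clip, aligned = _clips_from_cigar(seg.cigartuples, seg.is_reverse)
    rec = AlignmentRecord(
        read_id=seg.query_name,
        mate=mate,
        seq_name=seq_name,
        start=seg.reference_start,
        end=seg.reference_end,
        orientation="reverse" if seg.is_reverse else "forward",
        clip_read_begin=begin_clip,
        clip_read_end=end_clip,
        aligned_length=aligned,
    )
    if assembly_lengths is not None and rec.end > assembly_lengths[seq_name]:
        raise ValueError(
            f"alignment [{rec.start},{rec.end}) exceeds length of {seq_name}"
        )
    return rec


def load_alignments(
    sam_path: str,
    mate: int,
    assembly_lengths: Mapping[str, int] | None = None,
) -> dict[str, ReadAlignmentSet]:
    """Load one report-all SAM file into per-read alignment sets.

    Secondary and supplementary records are kept as ordinary alignments;
    unmapped records yield empty sets.  Records with a malformed CIGAR are
    dropped with a warning; an alignment on a sequence absent from
    ``assembly_lengths`` is a fatal input error.
    """
    sets: dict[str, ReadAlignmentSet] = {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for seg in fh:
            name = seg.query_name
            if name not in sets:
                sets[name] = ReadAlignmentSet(read_id=name, mate=mate)
            try:
                rec = record_from_segment(seg, mate, assembly_lengths)
            except KeyError:
                raise
            except ValueError as exc:
                logger.warning("rejected record for %s: %s", name, exc)
                continue
            if rec is not None:
                sets[name].alignments.append(rec)
    return sets


def iter_read_pairs(
    fwd_sets: Mapping[str, ReadAlignmentSet],
    rev_sets: Mapping[str, ReadAlignmentSet],
) -> Iterator[tuple[ReadAlignmentSet, ReadAlignmentSet]]:
    """Pair up the per-file alignment sets by read id.

    Read ids are matched after stripping a trailing ``/1``/``/2`` suffix if
    present.  Ids present in only one file yield a pair with an empty set
    on the other side.
    """

    def norm(name: str) -> str:
        return name[:-2] if name.endswith(("/1", "/2")) else name

    fwd_by_id = {norm(k): v for k, v in fwd_sets.items()}
    rev_by_id = {norm(k): v for k, v in rev_sets.items()}
    for name, s1 in fwd_by_id.items():
        s2 = rev_by_id.get(name)
        if s2 is None:
            s2 = ReadAlignmentSet(read_id=name, mate=2)
        yield s1, s2
    for name, s2 in rev_by_id.items():
        if name not in fwd_by_id:
            yield ReadAlignmentSet(read_id=name, mate=1), s2


def write_alignments(
    records: Iterable[AlignmentRecord],
    out_path: str,
    assembly_lengths: Mapping[str, int],
    read_sequences: Mapping[str, str] | None = None,
) -> None:
    """Write records back to SAM (coordinates and clip flags round-trip).

    Clipped stretches are emitted as soft clips of the minimal length (1)
    when the true read length is unknown; with ``read_sequences`` supplied
    the clip lengths are reconstructed exactly.
    """
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in assembly_lengths.items()],
    }
    refmap = {n: i for i, n in enumerate(assembly_lengths)}
    with pysam.AlignmentFile(out_path, "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment()
            seg.query_name = rec.read_id
            seg.reference_id = refmap[rec.seq_name]
            seg.reference_start = rec.start
            seg.is_reverse = rec.orientation == "reverse"
            seg.is_read1 = rec.mate == 1
            seg.is_read2 = rec.mate == 2
            seg.is_paired = True
            ref_span = rec.end - rec.start
            # assembly-left / assembly-right clip lengths
            left_clip = rec.clip_read_end if seg.is_reverse else rec.clip_read_begin
            right_clip = rec.clip_read_begin if seg.is_reverse else rec.clip_read_end
            if read_sequences is not None and rec.read_id in read_sequences:
                total = len(read_sequences[rec.read_id])
                n_clipped = total - rec.aligned_length
                if left_clip and right_clip:
                    lc, rc = n_clipped // 2, n_clipped - n_clipped // 2
                elif left_clip:
                    lc, rc = n_clipped, 0
                elif right_clip:
                    lc, rc = 0, n_clipped
                else:
                    lc = rc = 0
            else:
                lc = 1 if left_clip else 0
                rc = 1 if right_clip else 0
            cigar = []
            if lc:
                cigar.append((4, lc))
            cigar.append((0, ref_span))
            if rc:
                cigar.append((4, rc))
            seg.cigartuples = cigar
            seg.query_sequence = "N" * (lc + ref_span + rc)
            seg.mapping_quality = 255
            out.write(seg)
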