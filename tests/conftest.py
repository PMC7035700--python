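import shutil

import pysam
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from asmbreak.alignment_io import AlignmentRecord
from asmbreak.pair_builder import Category
from asmbreak.path_builder import ReadPath, detect_path_gaps
from asmbreak.gap_filter import TrackSet


def make_record(
    start,
    end,
    orientation="forward",
    seq_name="chr",
    read_id="r1",
    mate=1,
    clip_begin=False,
    clip_end=False,
    aligned_length=None,
):
    return AlignmentRecord(
        read_id=read_id,
        mate=mate,
        seq_name=seq_name,
        start=start,
        end=end,
        orientation=orientation,
        clip_read_begin=clip_begin,
        clip_read_end=clip_end,
        aligned_length=aligned_length if aligned_length is not None else end - start,
    )


def write_sam(path, records, seq_lengths):
    """records: list of dicts with pysam AlignedSegment attributes."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in seq_lengths.items()],
    }
    refmap = {n: i for i, n in enumerate(seq_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            seg = pysam.AlignedSegment()
            seg.query_name = r["name"]
            if r.get("unmapped"):
                seg.is_unmapped = True
                seg.query_sequence = r.get("seq", "A" * 10)
                out.write(seg)
                continue
            seg.reference_id = refmap[r.get("ref", next(iter(seq_lengths)))]
            seg.reference_start = r["pos"]
            seg.cigarstring = r["cigar"]
            seg.is_reverse = r.get("reverse", False)
            seg.is_secondary = r.get("secondary", False)
            if r.get("seq"):
                seg.query_sequence = r["seq"]
            else:
                qlen = sum(
                    n for op, n in seg.cigartuples if op in (0, 1, 4, 7, 8)
                )
                seg.query_sequence = "A" * qlen
            seg.mapping_quality = 60
            out.write(seg)
    return path


def build_track_set(seq_length, track_intervals, seq_name="chr"):
    """TrackSet from {(Category, orientation): [(start, end), ...]}.

    Intervals are taken as ready-made path extents (no merging), so the
    tests control the geometry exactly.
    """
    ts = TrackSet(seq_name=seq_name, seq_length=seq_length)
    for cat in Category:
        for orient in ("forward", "reverse"):
            ivs = sorted(track_intervals.get((cat, orient), []))
            paths = [ReadPath(seq_name, cat, orient, s, e) for s, e in ivs]
            ts.paths[(cat, orient)] = paths
            ts.gaps[(cat, orient)] = detect_path_gaps(
                paths, seq_length, seq_name, cat, orient
            )
    return ts


@pytest.fixture(scope="session")
def bwa_available():
    if shutil.which("bwa") is None:
        raise RuntimeError("bwa is required for the end-to-end tests")
    return "bwa"
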