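"""End-to-end detection pipeline and aligner contract.

Stage order: read mapping (external local aligner, report-all, one run
per read file) → properly mapped pair formation and categorization →
read-path creation per (category, orientation) track → path-gap
exclusion → error location adjustment and call emission.  Each assembly
sequence is processed in isolation; output is sorted by (sequence,
start) and a run manifest plus per-stage count report make reruns
auditable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, asdict
from pathlib import Path

from Bio import SeqIO

from ._version import __version__
from .alignment_io import load_alignments, iter_read_pairs
from .pair_builder import (
    CATEGORY_CYCLE,
    InsertBounds,
    estimate_insert_bounds,
    iter_proper_pairs,
    sample_inserts,
)
from .path_builder import build_paths, detect_path_gaps
from .gap_filter import TrackSet, apply_gap_filters
from .locator import (
    ErrorCall,
    adjust_gap,
    combine_and_intersect,
    merge_adjacent,
    pooled_coverage_blocks,
    trim_sequence_ends,
    write_bed,
)

logger = logging.getLogger(__name__)

# Aligner contract: local alignment, match bonus 1, report all alignments,
# run separately for each read file.  bwa mem options matching it: -a
# (report all), -A1 (match 1), gap open/extend 5/3 and no clip penalty, as a
# match-bonus-1 local aligner scores; -T sets the local-mode score floor and
# -w 30 caps the alignable gap so that indels beyond ~30 bases are soft-
# clipped at the breakpoint instead of being absorbed into one alignment
# (seed-and-extend local alignment does not jump larger gaps).
BWA_MEM_ARGS = [
    "-a", "-A", "1", "-B", "4", "-O", "5,5", "-E", "3,3", "-L", "0,0",
    "-T", "60", "-w", "30",
]


@dataclass
class PipelineConfig:
    insert_k: float = 4.0
    insert_min: int | None = None
    insert_max: int | None = None
    max_combinations: int = 10000
    end_slack: int = 0
    strict_cycle: bool = True
    merge_distance: int = 0
    aligner_path: str = "bwa"
    threads: int = 1


@dataclass
class RunManifest:
    version: str
    config: dict
    inputs: dict[str, str]  # path -> md5
    insert_bounds: dict
    read_length: int
    counts: dict
    aligner_command: list[str] | None = None

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_assembly_lengths(fasta_path: str) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}


def invoke_aligner(
    reads1: str,
    reads2: str,
    assembly: str,
    workdir: str,
    config: PipelineConfig | None = None,
) -> tuple[str, str, list[str]]:
    """Map each read file separately in report-all local mode.

    Returns the two SAM paths and the argument template used (recorded
    in the manifest).  A missing aligner or a non-zero exit is fatal.
    """
    config = config or PipelineConfig()
    if shutil.which(config.aligner_path) is None:
        raise FileNotFoundError(
            f"aligner {config.aligner_path!r} not found on PATH; supply --sam "
            "files or install bwa"
        )
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    index_prefix = wd / "assembly_index.fa"
    shutil.copy(assembly, index_prefix)
    subprocess.run(
        [config.aligner_path, "index", str(index_prefix)],
        check=True,
        capture_output=True,
    )
    sams = []
    template = [config.aligner_path, "mem", *BWA_MEM_ARGS, "-t", str(config.threads)]
    for i, reads in enumerate((reads1, reads2), start=1):
        out_sam = wd / f"mapped_{i}.sam"
        cmd = template + [str(index_prefix), reads]
        with open(out_sam, "wb") as fh:
            proc = subprocess.run(cmd, stdout=fh, stderr=subprocess.PIPE)
        if proc.returncode != 0:
            raise RuntimeError(
                f"aligner failed ({proc.returncode}): {proc.stderr.decode(errors='replace')[-2000:]}"
            )
        sams.append(str(out_sam))
    return sams[0], sams[1], template


def run_pipeline(
    assembly_fasta: str,
    sam1: str,
    sam2: str,
    out_dir: str | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[ErrorCall], RunManifest]:
    """Detect assembly error intervals from two report-all SAM files."""
    config = config or PipelineConfig()
    seq_lengths = read_assembly_lengths(assembly_fasta)
    sets1 = load_alignments(sam1, mate=1, assembly_lengths=seq_lengths)
    sets2 = load_alignments(sam2, mate=2, assembly_lengths=seq_lengths)
    read_pairs = list(iter_read_pairs(sets1, sets2))
    if not read_pairs or all(
        s1.multiplicity == 0 and s2.multiplicity == 0 for s1, s2 in read_pairs
    ):
        logger.warning("no mapped reads in input; emitting empty call set")

    read_length = 0
    for sets in (sets1, sets2):
        for s in sets.values():
            for a in s.alignments:
                if not a.clip_read_begin and not a.clip_read_end:
                    read_length = max(read_length, a.aligned_length)
    if read_length == 0:
        read_length = max(
            (a.aligned_length for s1, s2 in read_pairs for a in (*s1.alignments, *s2.alignments)),
            default=0,
        )

    if config.insert_min is not None and config.insert_max is not None:
        bounds = InsertBounds(
            min_insert=config.insert_min,
            max_insert=config.insert_max,
            point_estimate=(config.insert_min + config.insert_max) // 2,
        )
    else:
        inserts = sample_inserts(read_pairs)
        bounds = estimate_insert_bounds(inserts, k=config.insert_k)
    logger.info(
        "insert bounds: [%d, %d], point estimate %d",
        bounds.min_insert,
        bounds.max_insert,
        bounds.point_estimate,
    )

    # accumulate deduplicated alignment intervals per (seq, category, orientation)
    tracks: dict[str, dict[tuple, set[tuple[int, int]]]] = {name: {} for name in seq_lengths}
    pair_counts = {cat.value: 0 for cat in CATEGORY_CYCLE}
    n_pairs = 0
    for pair in iter_proper_pairs(
        read_pairs, bounds, seq_lengths, config.max_combinations, config.end_slack
    ):
        n_pairs += 1
        pair_counts[pair.category.value] += 1
        seq_tracks = tracks[pair.seq_name]
        for aln, orient in ((pair.fwd, "forward"), (pair.rev, "reverse")):
            key = (pair.category, orient)
            seq_tracks.setdefault(key, set()).add((aln.start, aln.end))

    all_calls: list[ErrorCall] = []
    counts = {
        "read_pairs_input": len(read_pairs),
        "proper_pairs": n_pairs,
        "pairs_per_category": pair_counts,
        "gaps_total": 0,
        "gaps_excluded_opposite": 0,
        "gaps_excluded_type_alternation": 0,
        "gaps_excluded_adjustment": 0,
        "gaps_retained": 0,
        "calls": 0,
    }
    for seq_name in sorted(seq_lengths):
        seq_len = seq_lengths[seq_name]
        if not tracks[seq_name]:
            # no properly mapped pairs on this sequence: no evidence to
            # call against, not a sequence-wide error
            continue
        ts = TrackSet(seq_name=seq_name, seq_length=seq_len)
        for cat in CATEGORY_CYCLE:
            for orient in ("forward", "reverse"):
                ivs = sorted(tracks[seq_name].get((cat, orient), ()))
                paths = build_paths(ivs, seq_name, cat, orient)
                ts.paths[(cat, orient)] = paths
                ts.gaps[(cat, orient)] = detect_path_gaps(
                    paths, seq_len, seq_name, cat, orient
                )
        apply_gap_filters(ts, strict_cycle=config.strict_cycle)
        pooled = {
            orient: pooled_coverage_blocks(
                [p for cat in CATEGORY_CYCLE for p in ts.track_paths(cat, orient)]
            )
            for orient in ("forward", "reverse")
        }
        for (cat, orient), gaps in ts.gaps.items():
            for gap in gaps:
                counts["gaps_total"] += 1
                if not gap.excluded:
                    adjust_gap(gap, pooled[orient])
        for gaps in ts.gaps.values():
            for gap in gaps:
                if gap.excluded:
                    reason = gap.exclusion_reason
                    if reason == "opposite_coverage":
                        counts["gaps_excluded_opposite"] += 1
                    elif reason == "type_alternation":
                        counts["gaps_excluded_type_alternation"] += 1
                    else:
                        counts["gaps_excluded_adjustment"] += 1
                else:
                    counts["gaps_retained"] += 1
        fwd_gaps = [g for cat in CATEGORY_CYCLE for g in ts.track_gaps(cat, "forward")]
        rev_gaps = [g for cat in CATEGORY_CYCLE for g in ts.track_gaps(cat, "reverse")]
        calls = combine_and_intersect(
            fwd_gaps, rev_gaps, seq_name, pooled["forward"], pooled["reverse"]
        )
        calls = trim_sequence_ends(calls, seq_len, read_length)
        calls = merge_adjacent(calls, config.merge_distance)
        all_calls.extend(calls)

    all_calls.sort(key=lambda c: (c.seq_name, c.start, c.end))
    counts["calls"] = len(all_calls)

    manifest = RunManifest(
        version=__version__,
        config=asdict(config),
        inputs={p: _md5(p) for p in (assembly_fasta, sam1, sam2)},
        insert_bounds=asdict(bounds),
        read_length=read_length,
        counts=counts,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bed(all_calls, str(out / "errors.bed"))
        manifest.write(str(out / "manifest.json"))
        _write_report(str(out / "report.tsv"), counts)
    return all_calls, manifest


def _write_report(path: str, counts: dict) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in counts.items():
            if isinstance(v, dict):
                for k2, v2 in v.items():
                    fh.write(f"{k}.{k2}\t{v2}\n")
            else:
                fh.write(f"{k}\t{v}\n")
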