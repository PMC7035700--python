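"""Benchmark simulator: references, erroneous assemblies, reads, truth.

The simulator emulates the benchmark design the detector is meant for:

* a random reference genome seeded with interspersed and tandem repeat
  families (configurable copy number, unit length and divergence) — the
  repeats are what drives the multi-mapping read categories;
* an "assembly" derived from the reference by a catalogue of controlled
  structural modifications (insertions, duplications, tandem
  duplications, deletions — including deletions of repeat copies and
  tandem units — inversions, and relocations with plain, inserted-region
  or overlapping junctions), each recorded as a ground-truth interval in
  assembly coordinates with its type and size class;
* paired-end reads drawn from the *reference*, so that every
  disagreement between reads and assembly reflects a planted error:
  250 bp pairs with fragment length Normal(700, 40) at the configured
  coverage and a uniform per-base substitution error rate.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

ERROR_TYPES = (
    "insertion",
    "duplication",
    "tandem_duplication",
    "deletion",
    "deletion_repeat",
    "deletion_tandem",
    "inversion",
    "relocation",
    "relocation_insert",
    "relocation_overlap",
)

SIZE_CLASSES = {"small": (10, 49), "medium": (50, 299), "large": (300, 1000)}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTN", b"TGCAN"):
    _COMP[a] = b


@dataclass
class RepeatFamily:
    kind: str  # "interspersed" | "tandem"
    unit_length: int
    copies: int  # interspersed copies, or number of tandem arrays
    units_per_array: int = 1  # tandem only
    divergence: float = 0.02


def default_repeat_families() -> list[RepeatFamily]:
    return [
        RepeatFamily("interspersed", 2000, 4, divergence=0.02),
        RepeatFamily("interspersed", 1000, 5, divergence=0.02),
        RepeatFamily("interspersed", 500, 6, divergence=0.01),
        RepeatFamily("interspersed", 3000, 3, divergence=0.02),
        RepeatFamily("tandem", 200, 3, units_per_array=4, divergence=0.01),
        RepeatFamily("tandem", 100, 3, units_per_array=5, divergence=0.01),
        RepeatFamily("tandem", 400, 3, units_per_array=3, divergence=0.02),
    ]


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    repeat_families: list[RepeatFamily] = field(default_factory=default_repeat_families)
    errors_per_type_class: int = 30
    min_error_separation: int = 2000
    read_length: int = 250
    insert_mean: float = 700.0
    insert_sd: float = 40.0
    coverage: float = 40.0
    base_error_rate: float = 0.001
    n_run_length: int = 0
    n_run_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        repeat_bases = sum(
            f.unit_length * f.copies * f.units_per_array for f in self.repeat_families
        )
        if repeat_bases >= self.genome_length:
            raise ValueError(
                f"requested repeat content ({repeat_bases} bases) exceeds "
                f"genome length {self.genome_length}"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fams = raw.pop("repeat_families", None)
        cfg = cls(**raw)
        if fams is not None:
            cfg.repeat_families = [RepeatFamily(**f) for f in fams]
        return cfg

    def to_yaml(self, path: str) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True, slots=True)
class RepeatCopy:
    start: int
    end: int
    family: int
    kind: str


@dataclass(frozen=True, slots=True)
class GroundTruthError:
    seq_name: str
    start: int  # assembly coordinates, 0-based half-open
    end: int
    error_type: str
    size: int
    size_class: str
    edit_id: str


@dataclass(frozen=True, slots=True)
class Edit:
    """One modification as an edit-script entry on the reference.

    Replaces reference window [ref_start, ref_end) by ``replacement``.
    Replaying the sorted edits against the reference reproduces the
    assembly byte-for-byte.
    """

    ref_start: int
    ref_end: int
    replacement: str
    error_type: str
    size: int
    size_class: str
    edit_id: str
    # truth interval relative to the start of the replacement (assembly frame)
    truth_rel_start: int = 0
    truth_rel_end: int = 0


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, divergence: float) -> np.ndarray:
    out = seq.copy()
    n_sub = rng.binomial(len(seq), divergence)
    if n_sub:
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub)
        out[pos] = _BASES[(np.searchsorted(_BASES, out[pos]) + shift) % 4]
    return out


def revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _COMP[arr][::-1].tobytes().decode()


class _LocusRegistry:
    """Non-overlapping locus sampling with a minimum separation."""

    def __init__(self, genome_length: int, separation: int):
        self.length = genome_length
        self.sep = separation
        self.blocked: list[tuple[int, int]] = []

    def blocks(self, start: int, end: int) -> bool:
        s, e = start - self.sep, end + self.sep
        return any(s < be and bs < e for bs, be in self.blocked)

    def reserve(self, start: int, end: int) -> None:
        self.blocked.append((start, end))

    def sample(
        self, rng: np.random.Generator, width: int, margin: int, attempts: int = 1000
    ) -> int | None:
        lo, hi = margin, self.length - margin - width
        if hi <= lo:
            return None
        for _ in range(attempts):
            s = int(rng.integers(lo, hi))
            if not self.blocks(s, s + width):
                self.reserve(s, s + width)
                return s
        return None


def generate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[str, list[RepeatCopy]]:
    """Random background sequence with planted repeat families and N-runs."""
    rng = rng or np.random.default_rng(config.rng_seed)
    genome = _rand_seq(rng, config.genome_length)
    registry = _LocusRegistry(config.genome_length, separation=200)
    annotation: list[RepeatCopy] = []
    for fam_idx, fam in enumerate(config.repeat_families):
        unit = _rand_seq(rng, fam.unit_length)
        for _ in range(fam.copies):
            if fam.kind == "tandem":
                copy = np.concatenate(
                    [_mutate(rng, unit, fam.divergence) for _ in range(fam.units_per_array)]
                )
            else:
                copy = _mutate(rng, unit, fam.divergence)
            s = registry.sample(rng, len(copy), margin=1000)
            if s is None:
                logger.warning("no room for a copy of repeat family %d", fam_idx)
                continue
            genome[s : s + len(copy)] = copy
            annotation.append(RepeatCopy(s, s + len(copy), fam_idx, fam.kind))
    for _ in range(config.n_run_count):
        s = registry.sample(rng, config.n_run_length, margin=1000)
        if s is None:
            continue
        genome[s : s + config.n_run_length] = ord("N")
    annotation.sort(key=lambda r: r.start)
    return genome.tobytes().decode(), annotation


def _plan_edits(
    reference: str,
    repeats: list[RepeatCopy],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Edit]:
    L = len(reference)
    registry = _LocusRegistry(L, separation=config.min_error_separation)
    repeat_windows = [(r.start, r.end) for r in repeats]

    def overlaps_repeat(s: int, e: int, pad: int = 100) -> bool:
        return any(s - pad < re and rs < e + pad for rs, re in repeat_windows)

    requests = [
        (etype, cls)
        for etype in ERROR_TYPES
        for cls in SIZE_CLASSES
        for _ in range(config.errors_per_type_class)
    ]
    order = rng.permutation(len(requests))
    interspersed = [r for r in repeats if r.kind == "interspersed"]
    tandems = [r for r in repeats if r.kind == "tandem"]
    used_repeats: set[tuple[int, int]] = set()
    edits: list[Edit] = []
    n_skipped = 0

    def draw_size(cls: str) -> int:
        lo, hi = SIZE_CLASSES[cls]
        return int(rng.integers(lo, hi + 1))

    def sample_plain(width: int) -> int | None:
        for _ in range(50):
            s = registry.sample(rng, width, margin=2 * config.read_length + 100, attempts=50)
            if s is None:
                return None
            if not overlaps_repeat(s, s + width):
                return s
            registry.blocked.pop()  # un-reserve the repeat-overlapping locus
        return None

    for idx in order:
        etype, cls = requests[idx]
        size = draw_size(cls)
        edit_id = f"e{len(edits):04d}_{etype}_{cls}"
        edit: Edit | None = None
        if etype == "insertion":
            s = sample_plain(1)
            if s is not None:
                ins = _rand_seq(rng, size).tobytes().decode()
                edit = Edit(s, s, ins, etype, size, cls, edit_id, 0, size)
        elif etype == "duplication":
            s = sample_plain(1)
            if s is not None:
                for _ in range(100):
                    src = int(rng.integers(1000, L - 1000 - size))
                    if abs(src - s) > 5000 and not overlaps_repeat(src, src + size):
                        break
                else:
                    src = None
                if src is not None:
                    edit = Edit(s, s, reference[src : src + size], etype, size, cls, edit_id, 0, size)
        elif etype == "tandem_duplication":
            s = sample_plain(size)
            if s is not None:
                unit = reference[s : s + size]
                edit = Edit(s, s + size, unit + unit, etype, size, cls, edit_id, size, 2 * size)
        elif etype == "deletion":
            s = sample_plain(size)
            if s is not None:
                edit = Edit(s, s + size, "", etype, size, cls, edit_id, 0, 0)
        elif etype in ("deletion_repeat", "deletion_tandem"):
            pool = interspersed if etype == "deletion_repeat" else tandems
            candidates = [
                r
                for r in pool
                if (r.start, r.end) not in used_repeats
                and r.end - r.start >= size
                and not registry.blocks(r.start, r.start + size)
            ]
            if candidates:
                r = candidates[int(rng.integers(len(candidates)))]
                used_repeats.add((r.start, r.end))
                copy_len = r.end - r.start
                if cls == "large" and copy_len <= SIZE_CLASSES["large"][1]:
                    s, size = r.start, copy_len  # delete the whole copy
                else:
                    off = int(rng.integers(0, copy_len - size + 1))
                    s = r.start + off
                if not registry.blocks(s, s + size):
                    registry.reserve(s, s + size)
                    edit = Edit(s, s + size, "", etype, size, cls, edit_id, 0, 0)
        elif etype == "inversion":
            s = sample_plain(size)
            if s is not None:
                edit = Edit(s, s + size, revcomp(reference[s : s + size]), etype, size, cls, edit_id, 0, size)
        elif etype in ("relocation", "relocation_insert", "relocation_overlap"):
            # plain relocations misjoin a class-sized fragment with a
            # genome-scale partner; for the inserted-region and overlap
            # variants both misjoined fragments are genome-scale and the
            # class size is the inserted/overlapping junction sequence
            if etype == "relocation":
                len_a, len_b = size, int(rng.integers(300, 801))
            else:
                len_a, len_b = int(rng.integers(300, 801)), int(rng.integers(300, 801))
            width = len_a + len_b
            s = sample_plain(width)
            if s is not None:
                frag_a = reference[s : s + len_a]
                frag_b = reference[s + len_a : s + width]
                if etype == "relocation":
                    repl = frag_b + frag_a
                elif etype == "relocation_insert":
                    ins = _rand_seq(rng, size).tobytes().decode()
                    repl = frag_b + ins + frag_a
                else:
                    size = min(size, len_b)  # overlap cannot exceed the fragment
                    repl = frag_b + frag_b[-size:] + frag_a
                edit = Edit(s, s + width, repl, etype, size, cls, edit_id, 0, len(repl))
        else:  # pragma: no cover
            raise AssertionError(etype)
        if edit is None:
            n_skipped += 1
        else:
            edits.append(edit)
    if n_skipped:
        logger.info(
            "placed %d modifications; %d requests skipped for lack of a legal locus",
            len(edits),
            n_skipped,
        )
    edits.sort(key=lambda e: (e.ref_start, e.ref_end))
    return edits


def replay_edits(reference: str, edits: list[Edit]) -> str:
    """Apply a sorted edit script to the reference (assembly replay)."""
    parts: list[str] = []
    prev = 0
    for e in edits:
        parts.append(reference[prev : e.ref_start])
        parts.append(e.replacement)
        prev = e.ref_end
    parts.append(reference[prev:])
    return "".join(parts)


def apply_modifications(
    reference: str,
    repeats: list[RepeatCopy],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    seq_name: str = "asm",
) -> tuple[str, list[GroundTruthError], list[Edit]]:
    """Build the erroneous assembly and its assembly-coordinate truth."""
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    edits = _plan_edits(reference, repeats, config, rng)
    assembly_parts: list[str] = []
    truths: list[GroundTruthError] = []
    cur = 0  # assembly length so far
    prev = 0
    for e in edits:
        assembly_parts.append(reference[prev : e.ref_start])
        cur += e.ref_start - prev
        t_start = cur + e.truth_rel_start
        t_end = cur + e.truth_rel_end
        if t_end == t_start:  # 0-length junction (deletion) widened to 1 base
            t_end = t_start + 1
        truths.append(
            GroundTruthError(seq_name, t_start, t_end, e.error_type, e.size, e.size_class, e.edit_id)
        )
        assembly_parts.append(e.replacement)
        cur += len(e.replacement)
        prev = e.ref_end
    assembly_parts.append(reference[prev:])
    assembly = "".join(assembly_parts)
    truths.sort(key=lambda t: t.start)
    return assembly, truths, edits


def simulate_reads(
    sequence: str,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_pairs: int | None = None,
) -> tuple[list[bytes], list[bytes]]:
    """Paired-end reads from a sequence (normally the reference).

    Returns the two FASTQ files as lists of ready-made 4-line records.
    R1 is the forward strand of the fragment start, R2 the reverse
    complement of the fragment end; fragment lengths are
    Normal(insert_mean, insert_sd) rounded, resampled while shorter than
    the read length; substitution errors are uniform at base_error_rate.
    """
    rng = rng or np.random.default_rng(config.rng_seed + 2)
    L = len(sequence)
    rl = config.read_length
    if n_pairs is None:
        n_pairs = int(round(config.coverage * L / (2 * rl)))
    frags = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)).astype(np.int64)
    bad = (frags < rl) | (frags > L)
    while bad.any():
        frags[bad] = np.rint(
            rng.normal(config.insert_mean, config.insert_sd, size=int(bad.sum()))
        ).astype(np.int64)
        bad = (frags < rl) | (frags > L)
    starts = (rng.random(n_pairs) * (L - frags + 1)).astype(np.int64)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    offs = np.arange(rl)
    r1 = arr[starts[:, None] + offs]
    ends = starts + frags
    r2 = _COMP[arr[(ends - rl)[:, None] + offs]][:, ::-1]
    for reads in (r1, r2):
        n_err = rng.binomial(reads.size, config.base_error_rate)
        if n_err:
            flat = rng.choice(reads.size, size=n_err, replace=False)
            shift = rng.integers(1, 4, size=n_err)
            cur = reads.reshape(-1)[flat]
            cur_idx = np.searchsorted(_BASES, np.where(cur == ord("N"), ord("A"), cur))
            reads.reshape(-1)[flat] = _BASES[(cur_idx + shift) % 4]
    qual = b"I" * rl
    out1: list[bytes] = []
    out2: list[bytes] = []
    for i in range(n_pairs):
        name = b"rp%07d" % i
        out1.append(b"@" + name + b"/1\n" + r1[i].tobytes() + b"\n+\n" + qual + b"\n")
        out2.append(b"@" + name + b"/2\n" + r2[i].tobytes() + b"\n+\n" + qual + b"\n")
    return out1, out2


def write_fasta(path: str, name: str, sequence: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def write_truth_bed(path: str, truths: list[GroundTruthError]) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                f"{t.seq_name}\t{t.start}\t{t.end}\t{t.error_type}\t{t.size}\t"
                f"{t.size_class}\t{t.edit_id}\n"
            )


def write_repeat_bed(path: str, repeats: list[RepeatCopy], seq_name: str) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{seq_name}\t{r.start}\t{r.end}\tfam{r.family}_{r.kind}\n")


def simulate_dataset(config: SimConfig, out_dir: str, seq_name: str = "asm") -> dict:
    """One full fixture: reference, assembly, truth, reads, config.

    Reads are drawn from the reference so that read/assembly
    disagreements are exactly the planted errors.  Returns the paths of
    everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    reference, repeats = generate_reference(config, rng)
    assembly, truths, _edits = apply_modifications(reference, repeats, config, rng, seq_name)
    r1, r2 = simulate_reads(reference, config, rng)
    paths = {
        "reference": str(out / "reference.fasta"),
        "assembly": str(out / "assembly.fasta"),
        "truth": str(out / "truth.bed"),
        "repeats": str(out / "repeats.bed"),
        "reads_1": str(out / "reads_1.fastq"),
        "reads_2": str(out / "reads_2.fastq"),
        "config": str(out / "sim_config.yaml"),
    }
    write_fasta(paths["reference"], "ref", reference)
    write_fasta(paths["assembly"], seq_name, assembly)
    write_truth_bed(paths["truth"], truths)
    write_repeat_bed(paths["repeats"], repeats, "ref")
    with open(paths["reads_1"], "wb") as fh:
        fh.write(b"".join(r1))
    with open(paths["reads_2"], "wb") as fh:
        fh.write(b"".join(r2))
    config.to_yaml(paths["config"])
    paths["n_truth"] = len(truths)
    return paths
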