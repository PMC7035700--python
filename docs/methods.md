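# Methods

## Model

`asmbreak` treats assembly error detection as an interval problem over
*properly mapped* read pairs. The driving observation: around a true
structural error, no read alignment can cross the breakpoint (the read
and the assembly disagree there), so the chains of properly paired
alignments — *read paths* — break on both strands at the same physical
position. Around a mere repeat boundary, paths also break, but in a
predictable way: the repeat-context categories alternate in a fixed
cycle, and the opposite strand or the neighbouring category carries
coverage across. The detector therefore keeps exactly those path gaps
that neither strand symmetry nor category alternation can explain.

Assumptions worth stating explicitly:

* the aligner is local, reports *all* alignments of each read end
  independently of its mate, and uses a match bonus of 1 — so soft
  clipping beats gapped extension once an indel exceeds roughly 30
  bases. Errors smaller than that are absorbed into single alignments
  and are invisible to the method (a documented blind spot, shared with
  any approach built on properly mapped reads);
* errors covered by overlapping properly mapped reads — deletions of
  whole long-repeat copies bridged via repeat periodicity, rearrangement
  junctions with long duplicated overlap — cannot be seen either;
* fragment sizes are unimodal; the robust insert window
  (median ± k·1.4826·MAD, k = 4 ≈ 99.99% of a normal) assumes one
  library.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `insert_k` | 4.0 | half-width of the insert window in robust SDs |
| `insert_min`/`insert_max` | estimated | explicit insert window override (bases) |
| `max_combinations` | 10 000 | cap on alignment combinations per read pair |
| `end_slack` | 0 | slack (bases) for the condition-4 sequence-end exception |
| `strict_cycle` | true | skip the boundary relaxation of the cycle rule |
| `merge_distance` | 0 | optional post-merge of adjacent calls (bases) |
| merge threshold | 6 (fixed) | minimum chaining overlap, "more than 5 bases" |
| junction uncertainty | 5 (fixed) | dilation before intersecting strand evidence |

The 5-base constant exists because a local aligner extends past a
breakpoint by however many bases match by chance (expected ≈ 1/3 base,
tail up to a handful). It is used three times, consistently: overlaps
of ≤ 5 bases never chain paths; exclusion rules demand > 5-base
overlaps; and the final forward/reverse evidence is dilated by 5 bases
before intersection, since the two strands' holes for one junction sit
a few bases apart. A junction whose flanks share more than 5 bases of
microhomology is bridged and missed — rare (P ≈ 4⁻⁶ per junction) but
it happens once or twice per thousand errors.

Two rule details were genuinely open and are this implementation's own
choices. First, a gap is judged by cycle order at its *beginning* only
(its left flank); the mirrored test applies only to leading gaps, which
the walk reaches from the predecessor category. Judging both flanks
symmetrically turns out to exclude any long gap whose far side hides an
error behind a normal-looking near side. Second, location adjustment
shifts a gap's bounds using the coverage blocks *connected to its
flanks* (paths overhanging the gap ends, chained under the same >5-base
rule); coverage strictly interior to a long gap does not move the
bounds, and the per-orientation union is afterwards reduced to its
uncovered holes. The naive alternative — shifting to the rightmost path
end anywhere inside the gap — collapses exactly the gaps that contain
real errors next to repeats.

## Aligner contract

The pipeline consumes any SAM pair honouring the contract: local mode,
match bonus 1, all alignments reported, one run per read file. The
bundled invocation uses `bwa mem -a -A1 -B4 -O5,5 -E3,3 -L0,0 -T60
-w30`: scoring matched to a match-bonus-1 local aligner, no clip
penalty, a score floor comparable to local-mode defaults for 250 bp
reads, and a band width of 30 so gaps beyond ~30 bases soft-clip at the
breakpoint rather than being absorbed — the behaviour of seed-extension
local alignment, and the origin of the ~30 bp blind spot above.

## Synthetic benchmark

The simulator emulates the study design the detector targets:

* **Reference**: uniform-random sequence (default 1 Mb) with planted
  repeat families — four interspersed families (units 0.5–3 kb, 3–6
  copies, 1–2% divergence) and three tandem arrays (units 100–400 bp,
  3–5 units) — roughly 3% repeat content, bacterial-like. Optional
  N-runs.
* **Assembly**: the reference modified by a catalogue of ten error
  types (insertion, duplication, tandem duplication, deletion, deletion
  of interspersed-repeat copies or parts, deletion of tandem units,
  inversion, relocation, relocation with a 10–1000 bp inserted region,
  relocation with junction overlap) in three size classes (10–49,
  50–299, 300–1000 bases). For the relocation variants the misjoined
  fragments are genome-scale (300–800 bp) and the class size is the
  inserted/overlapping junction sequence. Thirty errors per type and
  class are requested; placement enforces a 2 kb minimum separation
  (so flanked truth regions and insert-sized neighbourhoods stay
  independent) and simply stops when no legal locus remains — on 1 Mb
  roughly 320–350 errors fit. Ground truth is written in assembly
  coordinates, one row per error; deletions are 1-base junctions,
  multi-breakpoint errors span the affected region.
* **Reads**: drawn from the *reference*, so read/assembly disagreements
  are exactly the planted errors: 250 bp pairs, fragment length
  Normal(700, 40) resampled below one read length, default 40x, 0.1%
  uniform substitution errors, constant quality strings. The error
  model is deliberately simple — the detector is interval-based and
  indifferent to quality-score realism — and contains no sequencing
  indels; passing benchmarks therefore say nothing about indel-rich
  platforms. Diploidy and real error profiles are out of scope.

Everything is byte-deterministic under the configured seed.

## Evaluation protocol

Truth intervals are widened by a flank (1–600 bp) and clamped at zero;
a truth entry is detected if any call overlaps its flanked interval by
at least one base (plain intersect semantics, no reciprocal-overlap
requirement), a call is false if it overlaps none. Multiple calls on
one truth count once; one call spanning several truths is a single true
prediction. Sensitivity is reported overall and per (type, size class);
FDR only overall. Degenerate inputs are flagged rather than guessed:
no calls → FDR reported 0 and marked undefined; no truth → sensitivity
marked undefined, FDR 1 if calls exist.

## Benchmark scales

The shipped protocols are desk-scale by choice: two 1 Mb genomes at
40x for the catalogue benchmark and one 500 kb fixture for the
5/10/40/100/200x coverage sweep, sizes at which a full
simulate–map–detect–score cycle takes seconds per genome on one CPU
while still planting several hundred errors of every type. On these
fixtures the detector reaches ≈ 0.80–0.84 overall sensitivity at a
600 bp flank with zero observed FDR at 40x; at 5x the FDR rises to a
few percent while sensitivity increases — uncovered regions get called
by chance — matching the expected low-coverage behaviour.

## Known limitations

* Errors ≲ 30 bp (and inversions ≲ 25 bp, absorbed as mismatch runs)
  are invisible; so are repeat-copy deletions bridged by periodicity
  and misjoins with long overlaps.
* The cycle rule's behaviour at sequence boundaries uses the base rule
  by default; `strict_cycle=false` enables a relaxation (any
  other-category coverage of a boundary gap's free end excludes it)
  for fragmented assemblies with many short sequences.
* Inter-sequence misjoins (translocations) produce pairs that fail
  condition 1 and surface only as coverage breaks at the junction; the
  simulator does not model them.
* Single-end evidence (singletons, split reads) is ignored by design.
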