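"""Self-contained benchmark protocols.

Two study designs are wired up end to end (simulate → map → detect →
score):

* the *first dataset*: repeat-bearing 1 Mb references with the full
  modification catalogue, 250 bp pairs at 40x; scored per flank;
* the *coverage sweep*: one 500 kb fixture re-sequenced at 5x, 10x,
  40x, 100x and 200x, scored at a 600 bp flank.

Each genome runs in its own working directory; results come back as the
evaluator's tables, so callers can aggregate or slice per group.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluator import DEFAULT_FLANKS, evaluate, read_calls_bed, read_truth_bed
from .pipeline import PipelineConfig, invoke_aligner, run_pipeline
from .simulator import SimConfig, simulate_dataset, simulate_reads


def simulate_and_run(
    config: SimConfig,
    workdir: str,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One fixture end to end; returns (truth, calls) tables."""
    wd = Path(workdir)
    paths = simulate_dataset(config, str(wd / "sim"))
    sam1, sam2, _ = invoke_aligner(
        paths["reads_1"], paths["reads_2"], paths["assembly"], str(wd / "map"),
        pipeline_config,
    )
    run_pipeline(paths["assembly"], sam1, sam2, out_dir=str(wd / "out"),
                 config=pipeline_config)
    truth = read_truth_bed(paths["truth"])
    calls = read_calls_bed(str(wd / "out" / "errors.bed"))
    return truth, calls


def first_dataset(
    seeds: tuple[int, ...],
    genome_length: int = 1_000_000,
    coverage: float = 40.0,
    workdir: str | None = None,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """The first-dataset protocol: one genome per seed at 40x."""
    results = []
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        for i, seed in enumerate(seeds):
            cfg = SimConfig(genome_length=genome_length, coverage=coverage, rng_seed=seed)
            results.append(simulate_and_run(cfg, str(Path(td) / f"g{i}")))
    return results


def aggregate_metrics(
    runs: list[tuple[pd.DataFrame, pd.DataFrame]], flank: int = 600
) -> dict:
    """Pooled sensitivity/FDR over several genome runs at one flank."""
    detected = total = false = calls = 0
    for truth, call_df in runs:
        res = evaluate(truth, call_df, flank)
        detected += res.n_truth_detected
        total += res.n_truth
        false += res.n_calls_false
        calls += res.n_calls
    return {
        "sensitivity": detected / total if total else 0.0,
        "fdr": false / calls if calls else 0.0,
        "n_truth": total,
        "n_truth_detected": detected,
        "n_calls": calls,
        "n_calls_false": false,
    }


def flank_profile(
    runs: list[tuple[pd.DataFrame, pd.DataFrame]],
    flanks: tuple[int, ...] = DEFAULT_FLANKS,
) -> pd.DataFrame:
    rows = [{"flank": f, **aggregate_metrics(runs, f)} for f in flanks]
    return pd.DataFrame(rows)


def coverage_sweep(
    seed: int,
    genome_length: int = 500_000,
    coverages: tuple[float, ...] = (5, 10, 40, 100, 200),
    flank: int = 600,
    workdir: str | None = None,
) -> pd.DataFrame:
    """The second-dataset protocol: one fixture, one read set per coverage."""
    rows = []
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        wd = Path(td)
        cfg = SimConfig(genome_length=genome_length, rng_seed=seed)
        paths = simulate_dataset(cfg, str(wd / "sim"))
        reference = _read_single_fasta(paths["reference"])
        truth = read_truth_bed(paths["truth"])
        for cov in coverages:
            cov_cfg = SimConfig(
                genome_length=genome_length, coverage=cov, rng_seed=seed
            )
            rng = np.random.default_rng(seed + int(cov))
            r1, r2 = simulate_reads(reference, cov_cfg, rng)
            d = wd / f"cov{cov:g}"
            d.mkdir()
            p1, p2 = d / "r1.fastq", d / "r2.fastq"
            p1.write_bytes(b"".join(r1))
            p2.write_bytes(b"".join(r2))
            sam1, sam2, _ = invoke_aligner(
                str(p1), str(p2), paths["assembly"], str(d / "map")
            )
            run_pipeline(paths["assembly"], sam1, sam2, out_dir=str(d / "out"))
            calls = read_calls_bed(str(d / "out" / "errors.bed"))
            res = evaluate(truth, calls, flank)
            rows.append(
                {
                    "coverage": cov,
                    "sensitivity": res.overall_sensitivity,
                    "fdr": res.overall_fdr,
                    "n_truth": res.n_truth,
                    "n_calls": res.n_calls,
                }
            )
    return pd.DataFrame(rows)


def _read_single_fasta(path: str) -> str:
    from Bio import SeqIO

    (rec,) = list(SeqIO.parse(path, "fasta"))
    return str(rec.seq)
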