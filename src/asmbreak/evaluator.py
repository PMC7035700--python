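"""Benchmark scoring: sensitivity and FDR under flanked-interval overlap.

Each ground-truth interval is widened by a flank on both sides (the
slack allowed in a prediction's position); a truth entry counts as
detected when at least one predicted interval overlaps its flanked form
by >= 1 base, and a prediction counts as true when it overlaps at least
one flanked truth interval.  Sensitivity is detected/total truth, FDR is
false predictions/total predictions, overall and per
(error type, size class) group.  The standard flank sweep
{1, 5, 10, 20, 50, 100, 200, 400, 600} yields the ROC-like table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_FLANKS = (1, 5, 10, 20, 50, 100, 200, 400, 600)

TRUTH_COLUMNS = ["seq_name", "start", "end", "error_type", "size", "size_class", "edit_id"]
CALL_COLUMNS = ["seq_name", "start", "end"]


@dataclass
class EvalResult:
    flank: int
    overall_sensitivity: float
    overall_fdr: float
    n_truth: int
    n_truth_detected: int
    n_calls: int
    n_calls_false: int
    per_group: dict[tuple[str, str], float] = field(default_factory=dict)
    sensitivity_defined: bool = True
    fdr_defined: bool = True


def read_truth_bed(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    df = df.iloc[:, : len(TRUTH_COLUMNS)]
    df.columns = TRUTH_COLUMNS[: df.shape[1]]
    for col in ("error_type", "size", "size_class", "edit_id"):
        if col not in df.columns:
            df[col] = "." if col != "size" else 0
    return df


def read_calls_bed(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CALL_COLUMNS)
    df.columns = CALL_COLUMNS
    return df


def _overlap_flags(
    truth: pd.DataFrame, calls: pd.DataFrame, flank: int
) -> tuple[np.ndarray, np.ndarray]:
    """(truth detected, call true) boolean vectors under the flank."""
    detected = np.zeros(len(truth), dtype=bool)
    call_true = np.zeros(len(calls), dtype=bool)
    if len(truth) == 0 or len(calls) == 0:
        return detected, call_true
    for seq in set(truth["seq_name"]).intersection(calls["seq_name"]):
        t_idx = np.flatnonzero((truth["seq_name"] == seq).to_numpy())
        c_idx = np.flatnonzero((calls["seq_name"] == seq).to_numpy())
        ts = truth["start"].to_numpy()[t_idx] - flank
        te = truth["end"].to_numpy()[t_idx] + flank
        np.clip(ts, 0, None, out=ts)
        cs = calls["start"].to_numpy()[c_idx]
        ce = calls["end"].to_numpy()[c_idx]
        hit = (cs[None, :] < te[:, None]) & (ce[None, :] > ts[:, None])
        detected[t_idx] |= hit.any(axis=1)
        call_true[c_idx] |= hit.any(axis=0)
    return detected, call_true


def evaluate(truth: pd.DataFrame, calls: pd.DataFrame, flank: int) -> EvalResult:
    """Score calls against truth at one flank size.

    With no calls, sensitivity is 0 and FDR is reported as 0 with
    ``fdr_defined`` false; with no truth, sensitivity is flagged
    undefined and FDR is 1 whenever calls exist.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    detected, call_true = _overlap_flags(truth, calls, flank)
    n_truth, n_calls = len(truth), len(calls)
    n_det = int(detected.sum())
    n_false = int((~call_true).sum()) if n_calls else 0
    res = EvalResult(
        flank=flank,
        overall_sensitivity=n_det / n_truth if n_truth else 0.0,
        overall_fdr=n_false / n_calls if n_calls else 0.0,
        n_truth=n_truth,
        n_truth_detected=n_det,
        n_calls=n_calls,
        n_calls_false=n_false,
        sensitivity_defined=n_truth > 0,
        fdr_defined=n_calls > 0,
    )
    if n_truth and n_calls == 0:
        res.overall_fdr = 0.0
    if n_truth == 0 and n_calls:
        res.overall_fdr = 1.0
    if n_truth and "error_type" in truth.columns:
        groups = truth.groupby(["error_type", "size_class"]).indices
        for (etype, cls), idx in groups.items():
            res.per_group[(str(etype), str(cls))] = float(detected[idx].mean())
    return res


def sweep(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    flanks: Sequence[int] = DEFAULT_FLANKS,
) -> pd.DataFrame:
    """Per-flank table (overall row plus one row per error group)."""
    rows = []
    for flank in flanks:
        res = evaluate(truth, calls, flank)
        rows.append(
            {
                "flank": flank,
                "group": "overall",
                "sensitivity": res.overall_sensitivity,
                "fdr": res.overall_fdr,
                "n_truth": res.n_truth,
                "n_detected": res.n_truth_detected,
                "n_calls": res.n_calls,
                "n_false": res.n_calls_false,
            }
        )
        for (etype, cls), sens in sorted(res.per_group.items()):
            sub = truth[(truth["error_type"] == etype) & (truth["size_class"] == cls)]
            rows.append(
                {
                    "flank": flank,
                    "group": f"{etype}:{cls}",
                    "sensitivity": sens,
                    "fdr": float("nan"),
                    "n_truth": len(sub),
                    "n_detected": int(round(sens * len(sub))),
                    "n_calls": res.n_calls,
                    "n_false": res.n_calls_false,
                }
            )
    return pd.DataFrame(rows)
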