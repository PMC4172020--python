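"""Serialization of suite results to plain-text run records.

Writes the standard output set of a suite: the across-run learning
curve, a JSON run summary (one object per trial with its action
sequence and outcome), the final weight matrices in the labelled table
layout, spike rasters and the per-block selectivity report.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import analysis
from .experiment import SuiteResult, final_window_accuracy
from .network import MOTOR_LABELS

__all__ = ["write_outputs"]

_ACTION_NAMES = {0: "dig", 1: "move"}


def _run_summary(suite: SuiteResult) -> dict:
    runs = []
    for r in suite.runs:
        trials = []
        for k, rec in enumerate(r.records):
            trials.append(
                {
                    "trial": k + 1,
                    "sequence": [
                        {
                            "triplet": s.triplet.label,
                            "hippo_winner": s.hippo_winner,
                            "action": _ACTION_NAMES[s.action],
                        }
                        for s in rec.steps
                    ],
                    "rewarded": bool(rec.rewarded),
                    "timed_out": bool(rec.timed_out),
                    "duration_ms": round(rec.duration * 1e3, 3),
                }
            )
        runs.append(
            {
                "seed": r.seed,
                "final_window_accuracy": final_window_accuracy(
                    r, suite.config.sliding_window
                ),
                "functional_cells": analysis.identify_functional_cells(r.synapses),
                "trials": trials,
            }
        )
    return {
        "n_runs": len(suite.runs),
        "n_trials": suite.config.n_trials,
        "master_seed": suite.config.master_seed,
        "runs": runs,
    }


def _rasters(suite: SuiteResult) -> pd.DataFrame:
    layer_labels = {
        "sensory": ["A1", "A2", "B1", "B2", "X", "Y"],
        "hippo": [f"H{j + 1}" for j in range(suite.config.network.n_hippo)],
        "motor": list(MOTOR_LABELS),
    }
    rows = []
    for r in suite.runs:
        for k, rec in enumerate(r.records):
            for layer, spikes in rec.spikes.items():
                labels = layer_labels[layer]
                for cell, t in spikes:
                    rows.append(
                        {
                            "run_seed": r.seed,
                            "trial": k + 1,
                            "cell": labels[cell],
                            "time_ms": round(t * 1e3, 3),
                        }
                    )
    return pd.DataFrame(rows, columns=["run_seed", "trial", "cell", "time_ms"])


def write_outputs(suite: SuiteResult, outdir: str | Path, rasters: bool = True) -> None:
    """Write the standard CSV/JSON output set of one suite to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    suite.curve.to_csv(out / "learning_curve.csv", index=False)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(_run_summary(suite), fh, indent=1)
    analysis.grouping_table(suite.runs[0].synapses).to_csv(out / "weights_final.csv")
    if not suite.block_stats.empty:
        suite.block_stats.to_csv(out / "selectivity_report.csv", index=False)
    if rasters:
        _rasters(suite).to_csv(out / "rasters.csv", index=False)
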