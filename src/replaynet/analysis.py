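"""Measurement layer: selectivity, weight binariness, functional network.

Selectivity of a hippocampal cell over a set of ``n`` stimulus events
with firing rates ``lambda_i`` (preferred rate ``lambda_pref`` = max) is

    SI = (n - sum_i lambda_i / lambda_pref) / (n - 1)

which is 0 for uniform firing and 1 for firing to a single event.
Place selectivity uses the four context-places (n = 4) with rates
averaged over items; item and context selectivity use the X-set vs
Y-set and A-set vs B-set mean rates (n = 2).

Rates are computed from behaviour-phase spikes only, pooled within
30-trial blocks: for each executed action, spikes between stimulus onset
and action execution are attributed to the triplet sensed during that
interval.

A hippocampal cell is part of the functional network when its strongest
weight onto a motor cell exceeds 1 - 1e-6, i.e. when it actually drives
behaviour; selectivity and binariness statistics are restricted to the
end-of-run functional set, applied retrospectively to all blocks.

Binariness of a weight is B = 4 (W - 0.5)^2 — 0 at the midpoint, 1 at
the extremes — and is averaged over the sensory inputs of the
functional cells.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import MOTOR_LABELS, SynapseSet
from .task import TRIPLETS, TrialRecord

__all__ = [
    "DEFAULT_BLOCKS",
    "FUNCTIONAL_WEIGHT_THRESHOLD",
    "event_rates",
    "compute_si",
    "si_place",
    "si_item",
    "si_context",
    "compute_binariness",
    "identify_functional_cells",
    "run_selectivity_report",
    "block_statistics",
    "grouping_table",
]

#: Trial blocks (half-open, zero-based) used for all block statistics.
DEFAULT_BLOCKS: tuple[tuple[int, int], ...] = ((0, 30), (30, 60), (60, 90), (90, 120))

#: A cell joins the functional network above this hippocampo-motor weight.
FUNCTIONAL_WEIGHT_THRESHOLD = 1.0 - 1e-6

_TRIPLET_INDEX = {t.label: k for k, t in enumerate(TRIPLETS)}
# index groups in canonical triplet order A1X A1Y A2X A2Y B1X B1Y B2X B2Y
_PLACE_GROUPS = ((0, 1), (2, 3), (4, 5), (6, 7))  # A1 A2 B1 B2, items averaged
_ITEM_GROUPS = ((0, 2, 4, 6), (1, 3, 5, 7))  # X-set, Y-set
_CONTEXT_GROUPS = ((0, 1, 2, 3), (4, 5, 6, 7))  # A-set, B-set


def event_rates(
    records: Sequence[TrialRecord],
    n_hippo: int,
    blocks: Sequence[tuple[int, int]] = DEFAULT_BLOCKS,
) -> np.ndarray:
    """Per-block mean firing rate of each hippocampal cell per triplet.

    Returns an array of shape ``(n_blocks, n_hippo, 8)`` in Hz.  Within a
    block, spike counts and stimulus-interval durations are pooled over
    all occurrences of a triplet before dividing; triplets never
    encountered in a block get a rate of zero.
    """
    rates = np.zeros((len(blocks), n_hippo, len(TRIPLETS)))
    for b, (lo, hi) in enumerate(blocks):
        counts = np.zeros((n_hippo, len(TRIPLETS)))
        durations = np.zeros(len(TRIPLETS))
        for rec in records[lo:hi]:
            hippo_spikes = rec.spikes.get("hippo", [])
            for step in rec.steps:
                k = _TRIPLET_INDEX[step.triplet.label]
                durations[k] += step.t_end - step.t_start
                for cell, t in hippo_spikes:
                    if step.t_start < t <= step.t_end:
                        counts[cell, k] += 1
        nonzero = durations > 0
        rates[b, :, nonzero] = (counts[:, nonzero] / durations[nonzero]).T
    return rates


def compute_si(rates: np.ndarray) -> float:
    """Selectivity index of one cell over a vector of event rates.

    Returns ``nan`` for a silent cell (all rates zero), which callers
    exclude from averages.
    """
    rates = np.asarray(rates, dtype=float)
    n = rates.shape[0]
    if n < 2:
        raise ValueError("selectivity needs at least two events")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    pref = rates.max()
    if pref <= 0:
        return float("nan")
    si = (n - rates.sum() / pref) / (n - 1)
    return float(min(max(si, 0.0), 1.0))  # guard float round-off at the bounds


def _grouped_si(rates8: np.ndarray, groups: Iterable[tuple[int, ...]]) -> float:
    means = np.array([np.mean(rates8[list(g)]) for g in groups])
    return compute_si(means)


def si_place(rates8: np.ndarray) -> float:
    """Place SI: n = 4 context-places, item-averaged rates."""
    return _grouped_si(rates8, _PLACE_GROUPS)


def si_item(rates8: np.ndarray) -> float:
    """Item SI: n = 2, X-set mean vs Y-set mean."""
    return _grouped_si(rates8, _ITEM_GROUPS)


def si_context(rates8: np.ndarray) -> float:
    """Context SI: n = 2, A-set mean vs B-set mean."""
    return _grouped_si(rates8, _CONTEXT_GROUPS)


def compute_binariness(
    weights: np.ndarray, functional_cells: Sequence[int]
) -> float:
    """Mean binariness 4 (W - 0.5)^2 of the sensory inputs to the given cells.

    Returns ``nan`` when the functional set is empty.
    """
    cells = list(functional_cells)
    if not cells:
        return float("nan")
    w = np.asarray(weights)[:, cells]
    return float(np.mean(4.0 * (w - 0.5) ** 2))


def identify_functional_cells(synapses: SynapseSet) -> list[int]:
    """Hippocampal cells whose strongest motor weight is near-saturated."""
    strongest = synapses.exc_hippo_to_motor.max(axis=1)
    return [int(i) for i in np.flatnonzero(strongest > FUNCTIONAL_WEIGHT_THRESHOLD)]


def run_selectivity_report(
    records: Sequence[TrialRecord],
    block_weights: Sequence[np.ndarray],
    synapses: SynapseSet,
    n_hippo: int,
    blocks: Sequence[tuple[int, int]] = DEFAULT_BLOCKS,
) -> pd.DataFrame:
    """Per-block, per-functional-cell selectivity and binariness of one run.

    ``block_weights`` holds the sensory-to-hippocampal weight matrix at
    the end of each block.  Returns a tidy frame with columns
    ``block`` (1-based), ``cell``, ``si_place``, ``si_item``,
    ``si_context`` and ``binariness`` (the block-level weight binariness,
    repeated per cell).  Silent cells yield ``nan`` selectivities.
    """
    functional = identify_functional_cells(synapses)
    rates = event_rates(records, n_hippo, blocks)
    rows = []
    for b in range(len(blocks)):
        binar = compute_binariness(block_weights[b], functional)
        for cell in functional:
            r = rates[b, cell]
            rows.append(
                {
                    "block": b + 1,
                    "cell": cell,
                    "si_place": si_place(r),
                    "si_item": si_item(r),
                    "si_context": si_context(r),
                    "binariness": binar,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["block", "cell", "si_place", "si_item", "si_context", "binariness"],
    )


def block_statistics(reports: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Across-run mean and standard error per block for each measure.

    Each run contributes one value per block and measure (its
    functional-cell average, silent cells excluded); the frame returned
    has columns ``block``, ``measure``, ``mean``, ``sem``, ``n_runs``.
    """
    if len(reports) < 2:
        raise ValueError("need at least two runs for across-run statistics")
    measures = ["si_place", "si_item", "si_context", "binariness"]
    per_run = []
    for k, rep in enumerate(reports):
        if rep.empty:
            continue
        g = rep.groupby("block")[measures].mean()
        g["run"] = k
        per_run.append(g.reset_index())
    if not per_run:  # no run produced a functional cell
        return pd.DataFrame(columns=["block", "measure", "mean", "sem", "n_runs"])
    pooled = pd.concat(per_run, ignore_index=True)
    rows = []
    for measure in measures:
        for block, vals in pooled.groupby("block")[measure]:
            v = vals.dropna().to_numpy()
            rows.append(
                {
                    "block": block,
                    "measure": measure,
                    "mean": float(np.mean(v)) if v.size else float("nan"),
                    "sem": float(np.std(v, ddof=1) / np.sqrt(v.size))
                    if v.size > 1
                    else float("nan"),
                    "n_runs": int(v.size),
                }
            )
    return pd.DataFrame(rows, columns=["block", "measure", "mean", "sem", "n_runs"])


_ROW_ORDER = ("A1", "B1", "A2", "B2", "X", "Y")  # presentation order
_SENSORY_POS = {"A1": 0, "A2": 1, "B1": 2, "B2": 3, "X": 4, "Y": 5}
_CONNECTED_THRESHOLD = 0.9


def _cell_function_label(column: np.ndarray) -> str:
    """Context-item grouping label of one hippocampal cell's input weights."""
    connected = {
        name for name, idx in _SENSORY_POS.items() if column[idx] > _CONNECTED_THRESHOLD
    }
    items = connected & {"X", "Y"}
    cps = connected - items
    if len(items) != 1:
        return "None"
    (item,) = items
    for ctx in ("A", "B"):
        if cps == {f"{ctx}1", f"{ctx}2"}:
            return f"{ctx}1/2,{item}"
    if len(cps) == 1:
        (cp,) = cps
        return f"{cp}{item}"
    return "None"


def grouping_table(synapses: SynapseSet) -> pd.DataFrame:
    """Labelled weight table of the learned connectivity.

    Rows are the sensory cells (A1, B1, A2, B2, X, Y), the motor weights
    (Dig, Move) and a ``Function`` row giving each hippocampal cell's
    context-item grouping (e.g. ``A1/2,X`` when its near-saturated
    inputs span both places of context A plus item X), or ``None`` when
    no such near-binary structure exists.
    """
    w_sh = synapses.exc_sensory_to_hippo
    w_hm = synapses.exc_hippo_to_motor
    n_hippo = w_sh.shape[1]
    cols = [f"Cell {j + 1}" for j in range(n_hippo)]
    data: dict[str, list] = {}
    for name in _ROW_ORDER:
        data[name] = [round(float(w_sh[_SENSORY_POS[name], j]), 2) for j in range(n_hippo)]
    for m, label in enumerate(MOTOR_LABELS):
        data[label] = [round(float(w_hm[j, m]), 2) for j in range(n_hippo)]
    data["Function"] = [_cell_function_label(w_sh[:, j]) for j in range(n_hippo)]
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
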