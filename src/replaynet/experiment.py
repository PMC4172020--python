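"""Run orchestration: seeded runs, learning curves, multi-run suites.

A run is 130 trials from one random weight initialization.  Each trial
has a behaviour phase (noisy dynamics, plasticity off) followed — unless
it timed out — by a replay phase (noise off, plasticity on) of the last
two state-action pairs, forward after reward and backward otherwise.
The whole suite is a pure function of its configuration and master
seed: run ``k`` uses the stream seeded with ``master_seed + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .network import NetworkConfig, SynapseSet, init_weights
from .neurons import NeuronParams
from .plasticity import PlasticityParams
from .replay import build_replay_plan, run_replay
from .task import TaskParams, TrialRecord, new_trial, run_behavior_phase

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "SuiteResult",
    "run_single",
    "run_suite",
    "learning_curve",
    "final_window_accuracy",
    "load_config",
    "apply_overrides",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a suite needs: all model constants plus run bookkeeping."""

    neurons: NeuronParams = field(default_factory=NeuronParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    task: TaskParams = field(default_factory=TaskParams)
    n_runs: int = 100
    n_trials: int = 130
    dt: float = 0.5e-3
    master_seed: int = 0
    sliding_window: int = 30
    block_size: int = 30

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_trials < 1:
            raise ValueError("n_runs and n_trials must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class RunResult:
    """Outcome of one seeded run."""

    seed: int
    correct: np.ndarray  # bool per trial
    timed_out: np.ndarray  # bool per trial
    durations: np.ndarray  # behaviour-phase length per trial, seconds
    records: list[TrialRecord]
    block_weights: list[np.ndarray]  # sensory->hippo matrix at each block end
    synapses: SynapseSet  # final weights

    @property
    def n_trials(self) -> int:
        return self.correct.shape[0]


@dataclass
class SuiteResult:
    """All runs of a suite plus the aggregated tables."""

    config: ExperimentConfig
    runs: list[RunResult]
    curve: pd.DataFrame  # trial, mean, sd (across runs, sliding window)
    block_stats: pd.DataFrame  # analysis.block_statistics output


def run_single(config: ExperimentConfig, seed: int) -> RunResult:
    """Execute one run: init weights, then trial after trial with replay.

    The single random stream seeded with ``seed`` drives the weight
    initialization, membrane noise, task draws and tie-breaks, so the
    result is bit-for-bit reproducible.
    """
    rng = np.random.default_rng(seed)
    synapses = init_weights(config.network, rng)
    n = config.n_trials
    correct = np.zeros(n, dtype=bool)
    timed_out = np.zeros(n, dtype=bool)
    durations = np.zeros(n)
    records: list[TrialRecord] = []
    block_weights: list[np.ndarray] = []
    block_ends = set(
        range(config.block_size - 1, n, config.block_size)
    )
    for trial in range(n):
        state = new_trial(rng, config.task)
        record = run_behavior_phase(
            config.network,
            synapses,
            state,
            config.neurons,
            config.task,
            config.dt,
            rng,
        )
        records.append(record)
        durations[trial] = record.duration
        timed_out[trial] = record.timed_out
        correct[trial] = record.rewarded and not record.timed_out
        if not record.timed_out and record.steps:
            plan = build_replay_plan(record, config.task.n_replay)
            run_replay(
                config.network,
                synapses,
                plan,
                config.plasticity,
                config.neurons,
                config.task,
                config.dt,
            )
        if trial in block_ends:
            block_weights.append(synapses.exc_sensory_to_hippo.copy())
    return RunResult(
        seed=seed,
        correct=correct,
        timed_out=timed_out,
        durations=durations,
        records=records,
        block_weights=block_weights,
        synapses=synapses,
    )


def learning_curve(
    correct: np.ndarray, window: int = 30
) -> pd.DataFrame:
    """Centred sliding-window mean of per-trial correctness.

    ``correct`` is either one run (1-D, n_trials) or a stack of runs
    (2-D, n_runs x n_trials).  The window is centred on each trial and
    the first and last ``window`` trials are omitted (boundary effects).
    Returns a frame with 1-based ``trial``, ``mean`` and ``sd`` (the
    across-run standard deviation of the windowed means; zero for a
    single run).  Fewer trials than ``2 * window`` yield an empty curve.
    """
    arr = np.atleast_2d(np.asarray(correct, dtype=float))
    n = arr.shape[1]
    half_lo = window // 2
    trials = [t for t in range(window, n - window)]
    if not trials:
        return pd.DataFrame(columns=["trial", "mean", "sd"])
    rows = []
    for t in trials:
        lo = max(t - half_lo, 0)
        hi = min(t + window - half_lo, n)
        per_run = arr[:, lo:hi].mean(axis=1)
        rows.append(
            {
                "trial": t + 1,
                "mean": float(per_run.mean()),
                "sd": float(per_run.std(ddof=0)) if arr.shape[0] > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["trial", "mean", "sd"])


def final_window_accuracy(result: RunResult, window: int = 30) -> float:
    """Fraction of correct trials in the run's final ``window`` trials."""
    return float(result.correct[-window:].mean())


def run_suite(config: ExperimentConfig, progress: bool = False) -> SuiteResult:
    """Execute ``n_runs`` seeded runs and aggregate the standard tables.

    Run ``k`` uses seed ``master_seed + k``.  Aggregates the across-run
    learning curve and the per-block selectivity/binariness statistics of
    the functional cells.
    """
    seeds = [config.master_seed + k for k in range(config.n_runs)]
    iterator = seeds
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(seeds, desc="runs")
        except ImportError:
            pass
    runs = [run_single(config, s) for s in iterator]
    stacked = np.stack([r.correct for r in runs])
    curve = learning_curve(stacked, config.sliding_window)
    reports = [
        analysis.run_selectivity_report(
            r.records,
            r.block_weights,
            r.synapses,
            config.network.n_hippo,
            _blocks(config),
        )
        for r in runs
    ]
    block_stats = analysis.block_statistics(reports) if len(runs) > 1 else pd.DataFrame()
    return SuiteResult(config=config, runs=runs, curve=curve, block_stats=block_stats)


def _blocks(config: ExperimentConfig) -> tuple[tuple[int, int], ...]:
    size = config.block_size
    n_blocks = min(config.n_trials // size, 4)
    return tuple((k * size, (k + 1) * size) for k in range(n_blocks))


# ---------------------------------------------------------------------------
# flat key-value configuration files
# ---------------------------------------------------------------------------

_PARAM_HOMES: dict[str, tuple[str, str]] = {
    # flat config name -> (sub-config attribute, field name)
    "C": ("neurons", "capacitance"),
    "G_l": ("neurons", "leak_conductance"),
    "V_peak": ("neurons", "v_peak"),
    "V_th": ("neurons", "v_threshold"),
    "V_reset": ("neurons", "v_reset"),
    "sigma": ("neurons", "noise_sd"),
    "tau_plus": ("plasticity", "tau_plus"),
    "tau_minus": ("plasticity", "tau_minus"),
    "A_plus": ("plasticity", "amp_plus"),
    "A_minus": ("plasticity", "amp_minus"),
    "w_min": ("plasticity", "w_min"),
    "w_max": ("plasticity", "w_max"),
    "tau_w": ("plasticity", "tau_w"),
    "pair_window": ("plasticity", "pair_window"),
    "pair_dt": ("plasticity", "pair_dt"),
    "n_sensory": ("network", "n_sensory"),
    "n_hippo": ("network", "n_hippo"),
    "n_motor": ("network", "n_motor"),
    "I_sensory": ("network", "i_sensory"),
    "I_hippo": ("network", "i_hippo"),
    "I_motor": ("network", "i_motor"),
    "n_th_move": ("task", "move_threshold"),
    "n_th_dig": ("task", "dig_threshold"),
    "T_trial": ("task", "t_trial"),
    "T_replay": ("task", "t_replay"),
    "n_replay": ("task", "n_replay"),
}
_TOP_LEVEL = {"n_runs", "n_trials", "dt", "master_seed", "sliding_window", "block_size"}


def apply_overrides(
    config: ExperimentConfig, overrides: dict[str, float | int]
) -> ExperimentConfig:
    """Return a config with the given flat parameters replaced.

    Keys use the conventional parameter names (``A_plus``, ``I_hippo``,
    ``n_hippo``, ``T_trial``, ...) or the top-level run settings
    (``n_runs``, ``n_trials``, ``dt``, ``master_seed``).
    """
    sub_updates: dict[str, dict[str, float | int]] = {}
    top_updates: dict[str, float | int] = {}
    for key, value in overrides.items():
        if key in _TOP_LEVEL:
            top_updates[key] = value
        elif key in _PARAM_HOMES:
            home, attr = _PARAM_HOMES[key]
            sub_updates.setdefault(home, {})[attr] = value
        else:
            raise KeyError(f"unknown parameter {key!r}")
    for home, kwargs in sub_updates.items():
        top_updates[home] = replace(getattr(config, home), **kwargs)
    return replace(config, **top_updates)


def load_config(path: str | None = None) -> ExperimentConfig:
    """Build a config from a flat key-value (YAML mapping) file.

    Every entry must be one of the recognised parameter names; missing
    entries keep their defaults.  ``load_config(None)`` returns the
    defaults.
    """
    config = ExperimentConfig()
    if path is None:
        return config
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    numeric = {}
    for key, value in raw.items():
        if isinstance(value, str):
            value = float(value)
        numeric[key] = value
    return apply_overrides(config, numeric)


def default_config_text() -> str:
    """The default configuration serialized as a flat key-value file."""
    config = ExperimentConfig()
    lines = []
    for key, (home, attr) in _PARAM_HOMES.items():
        lines.append(f"{key}: {getattr(getattr(config, home), attr)!r}")
    for key in sorted(_TOP_LEVEL):
        lines.append(f"{key}: {getattr(config, key)!r}")
    return "\n".join(lines) + "\n"
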