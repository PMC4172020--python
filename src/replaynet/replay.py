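"""Replay phase: reactivation of recent state-action pairs with STDP on.

After the behaviour phase of a trial, the last (up to) ``n_replay``
state-action pairs are replayed with membrane noise switched off and
plasticity switched on — an abstraction of the sequence reactivation
observed during hippocampal sharp-wave ripples.

Rewarded trials are replayed in forward temporal order: within each
segment the two sensory cells receive the largest current, the recorded
hippocampal winner a slightly smaller one and the recorded motor cell
the smallest, so they spike in sensory -> hippocampal -> motor order a
few milliseconds apart.  Every adjacent pre/post pair then falls inside
the STDP window with pre before post, potentiating the pathway.
Non-rewarded trials are replayed in backward order — segments last to
first with the current magnitudes reversed (motor largest) — so the
spike order inverts and the same pathway is depressed.

Each planned segment is replayed once within the replay budget
``t_replay`` (400 ms by default, much shorter than the behaviour phase
it compresses).
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import NetworkConfig, SynapseSet
from .neurons import LayerState, NeuronParams, step_layer
from .plasticity import PlasticityParams, apply_stdp_to_path
from .task import TaskParams, TrialRecord, Triplet

__all__ = ["ReplaySegment", "ReplayPlan", "build_replay_plan", "run_replay"]


@dataclass(frozen=True)
class ReplaySegment:
    """One reactivated (stimulus, hippocampal winner, motor cell) triple."""

    triplet: Triplet
    hippo_cell: int
    motor_cell: int


@dataclass(frozen=True)
class ReplayPlan:
    """Ordered replay segments and the direction they are played in."""

    segments: tuple[ReplaySegment, ...]
    forward: bool


def build_replay_plan(record: TrialRecord, n_replay: int = 2) -> ReplayPlan:
    """Plan the replay of a completed (non-timed-out) trial.

    Takes the last ``n_replay`` action steps of the trial.  The plan is
    forward (segments in temporal order) when the trial was rewarded and
    backward (segments last to first; the within-segment spike order is
    inverted at run time by the current assignment) otherwise.
    """
    if record.timed_out:
        raise ValueError("timed-out trials are not replayed")
    if not record.steps:
        raise ValueError("cannot replay a trial with no actions")
    tail = record.steps[-n_replay:]
    segments = tuple(
        ReplaySegment(s.triplet, s.hippo_winner, s.action) for s in tail
    )
    if not record.rewarded:
        segments = segments[::-1]
    return ReplayPlan(segments=segments, forward=record.rewarded)


#: cache of simulated single-cell first-spike times keyed by the membrane
#: constants, step and drive — replay playback timing is deterministic.
_spike_time_cache: dict[tuple, float] = {}


def first_spike_time(
    current: float, neuron_params: NeuronParams, dt: float, max_time: float = 0.5
) -> float:
    """Euler-simulated charging time from rest to the first spike.

    During replay the reactivated cells are driven directly (no
    winner-take-all routing, no noise, no interaction), so each cell's
    spike time under its injected current is the charging time of a
    single cell from rest.  Raises if the cell does not spike within
    ``max_time``.
    """
    key = (
        current,
        dt,
        neuron_params.capacitance,
        neuron_params.leak_conductance,
        neuron_params.v_threshold,
        neuron_params.v_reset,
    )
    cached = _spike_time_cache.get(key)
    if cached is not None:
        return cached
    layer = LayerState.at_rest(1, neuron_params)
    layer.input_currents[0] = current
    for step in range(int(round(max_time / dt))):
        step_layer(layer, neuron_params, dt, rng=None)
        if layer.spiked[0]:
            t = (step + 1) * dt
            _spike_time_cache[key] = t
            return t
    raise ValueError(f"current {current!r} A does not elicit a spike in {max_time} s")


def _playback_log(
    seg: ReplaySegment,
    forward: bool,
    config: NetworkConfig,
    neuron_params: NeuronParams,
    dt: float,
) -> tuple[dict[str, dict[int, list[float]]], float]:
    """Spike log and duration of one deterministic segment playback.

    Forward: the sensory cells get ``i_sensory``, the recorded
    hippocampal winner ``i_hippo`` and the recorded motor cell
    ``i_motor``, so spiking runs sensory -> hippocampal -> motor with a
    few milliseconds between stages (the smaller the current, the later
    the spike).  Backward: the magnitude assignment is mirrored so the
    spike order inverts.
    """
    cp, item = seg.triplet.sensory_cells
    if forward:
        t_sens = first_spike_time(config.i_sensory, neuron_params, dt)
        t_hipp = first_spike_time(config.i_hippo, neuron_params, dt)
        t_moto = first_spike_time(config.i_motor, neuron_params, dt)
    else:
        t_moto = first_spike_time(config.i_sensory, neuron_params, dt)
        t_hipp = first_spike_time(config.i_hippo, neuron_params, dt)
        t_sens = first_spike_time(config.i_motor, neuron_params, dt)
    log = {
        "sensory": {cp: [t_sens], item: [t_sens]},
        "hippo": {seg.hippo_cell: [t_hipp]},
        "motor": {seg.motor_cell: [t_moto]},
    }
    return log, max(t_sens, t_hipp, t_moto)


def run_replay(
    config: NetworkConfig,
    synapses: SynapseSet,
    plan: ReplayPlan,
    plasticity: PlasticityParams,
    neuron_params: NeuronParams,
    task_params: TaskParams,
    dt: float,
) -> SynapseSet:
    """Replay the planned segments once each and apply STDP per playback.

    Each segment is played back once, in plan order, provided it still
    fits in the ``t_replay`` budget (a full two-segment replay lasts
    ~260 ms, well inside the 400 ms budget).  One playback per segment
    suffices because the soft-bounded updates saturate: with the default
    pairing scale a further repetition of the same pairing changes the
    weight marginally.  Weights are updated in place and the synapse set
    is returned.
    """
    budget = task_params.t_replay
    elapsed = 0.0
    for seg in plan.segments:
        log, t_seg = _playback_log(seg, plan.forward, config, neuron_params, dt)
        if elapsed + t_seg > budget:
            break
        elapsed += t_seg
        apply_stdp_to_path(synapses, log, plasticity)
    return synapses
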