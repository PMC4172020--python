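"""The context-dependent item-reward task and the behaviour phase.

A model rat is in one of two contexts (A or B), each containing two
places (1 and 2).  Each place holds one of two items (X or Y, one of
each per trial).  Digging at an item is rewarded when the item matches
the context's rule — X in context A, Y in context B — independent of
place; at a non-rewarded item the correct response is to move to the
other place (which always switches both place and sensed item, never
context).

Actions are driven by motor-layer spikes with adaptive spike-count
thresholds: both thresholds start at five spikes, each move lowers the
digging threshold by one (so digging is forced after at most five
moves), and executed actions reset their counters.  The behaviour phase
runs the full network with membrane noise on and plasticity off until a
dig ends the trial or the trial budget ``t_trial`` runs out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import DIG, MOVE, NetworkConfig, SynapseSet
from .neurons import IntegrationError, NeuronParams

__all__ = [
    "Triplet",
    "TaskParams",
    "TaskState",
    "ActionStep",
    "TrialRecord",
    "TRIPLETS",
    "new_trial",
    "encode_stimulus",
    "execute_action",
    "run_behavior_phase",
]

_CP_INDEX = {("A", 1): 0, ("A", 2): 1, ("B", 1): 2, ("B", 2): 3}
_ITEM_INDEX = {"X": 4, "Y": 5}

#: If True, a layer's winner tracks the subthreshold ramp until the first
#: presynaptic spike of a stimulus (all layers charge concurrently, actions
#: take ~0.65 s); if False the downstream current pulse starts only with the
#: first presynaptic spike (strictly spike-gated, actions take ~0.9 s and
#: multi-move trials exceed the trial budget, which starves learning of
#: replay events).
RAMP_BOOTSTRAP = True


@dataclass(frozen=True)
class Triplet:
    """One context-place-item combination, e.g. A1X."""

    context: str  # "A" or "B"
    place: int  # 1 or 2
    item: str  # "X" or "Y"

    @property
    def rewarded(self) -> bool:
        """Reward rule: X pays in context A, Y pays in context B."""
        return (self.context == "A") == (self.item == "X")

    @property
    def label(self) -> str:
        return f"{self.context}{self.place}{self.item}"

    @property
    def sensory_cells(self) -> tuple[int, int]:
        """(context-place cell, item cell) indices in the sensory layer."""
        return (_CP_INDEX[(self.context, self.place)], _ITEM_INDEX[self.item])


#: All eight triplets in canonical order.
TRIPLETS = tuple(
    Triplet(c, p, i) for c in ("A", "B") for p in (1, 2) for i in ("X", "Y")
)


@dataclass(frozen=True)
class TaskParams:
    """Task-level constants: action thresholds and time budgets (seconds)."""

    move_threshold: int = 5
    dig_threshold: int = 5
    t_trial: float = 4.0
    t_replay: float = 0.4
    n_replay: int = 2
    reset_counts_between_actions: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.move_threshold <= 5 and 0 < self.dig_threshold <= 5):
            raise ValueError("spike-count thresholds must be in 1..5")
        if self.t_trial <= 0 or self.t_replay <= 0:
            raise ValueError("time budgets must be positive")
        if self.n_replay < 1:
            raise ValueError("n_replay must be at least 1")


@dataclass
class TaskState:
    """Current trial state: where the rat is, what is where, thresholds."""

    context: str
    place: int
    item_at_place: dict[int, str]  # place -> item, a bijection
    dig_threshold: int
    move_threshold: int
    elapsed_time: float = 0.0

    @property
    def triplet(self) -> Triplet:
        return Triplet(self.context, self.place, self.item_at_place[self.place])


def new_trial(rng: np.random.Generator, params: TaskParams | None = None) -> TaskState:
    """Draw a fresh trial: uniform context, start place and item layout.

    The item-to-place assignment is a uniform bijection, so moving always
    changes both place and sensed item.  Both action thresholds reset to
    their initial values and the clock restarts.
    """
    if params is None:
        params = TaskParams()
    context = "A" if rng.integers(2) == 0 else "B"
    place = 1 if rng.integers(2) == 0 else 2
    items = ("X", "Y") if rng.integers(2) == 0 else ("Y", "X")
    return TaskState(
        context=context,
        place=place,
        item_at_place={1: items[0], 2: items[1]},
        dig_threshold=params.dig_threshold,
        move_threshold=params.move_threshold,
    )


def encode_stimulus(state: TaskState, config: NetworkConfig) -> np.ndarray:
    """Sensory input currents for the current triplet.

    Exactly two cells are driven with ``i_sensory``: the context-place
    cell and the item cell; all others receive zero.
    """
    currents = np.zeros(config.n_sensory)
    cp, item = state.triplet.sensory_cells
    currents[cp] = config.i_sensory
    currents[item] = config.i_sensory
    return currents


def execute_action(
    state: TaskState, action: int, params: TaskParams | None = None
) -> tuple[TaskState, bool, bool]:
    """Apply a triggered action; returns (state, trial_ended, rewarded).

    A move toggles the place (and hence the sensed item), lowers the
    digging threshold by one (floor zero) and resets the moving
    threshold.  A dig ends the trial with the reward of the current
    triplet, resets the digging threshold and lowers the moving threshold
    by one (the trial-start reset makes the latter inert in practice).
    """
    if params is None:
        params = TaskParams()
    if action == MOVE:
        state.place = 2 if state.place == 1 else 1
        state.dig_threshold = max(state.dig_threshold - 1, 0)
        state.move_threshold = params.move_threshold
        return state, False, False
    if action == DIG:
        rewarded = state.triplet.rewarded
        state.dig_threshold = params.dig_threshold
        state.move_threshold = max(state.move_threshold - 1, 0)
        return state, True, rewarded
    raise ValueError(f"unknown action {action!r}")


@dataclass(frozen=True)
class ActionStep:
    """One executed action with the stimulus and routing that produced it."""

    triplet: Triplet
    hippo_winner: int
    action: int  # DIG or MOVE
    t_start: float  # stimulus onset, seconds from trial start
    t_end: float  # action execution time


@dataclass
class TrialRecord:
    """Everything the behaviour phase of one trial produced."""

    steps: list[ActionStep]
    rewarded: bool
    timed_out: bool
    duration: float
    spikes: dict[str, list[tuple[int, float]]] = field(default_factory=dict)

    @property
    def n_actions(self) -> int:
        return len(self.steps)


def run_behavior_phase(
    config: NetworkConfig,
    synapses: SynapseSet,
    state: TaskState,
    neuron_params: NeuronParams,
    task_params: TaskParams,
    dt: float,
    rng: np.random.Generator,
) -> TrialRecord:
    """Run one behaviour phase: noisy network dynamics, plasticity off.

    Each step the three layers take one Euler step; the winner-take-all
    rule routes the hippocampal and motor input-current pulses.  A
    layer's winner is re-evaluated on the steps its presynaptic layer
    spikes and held in between; until the first presynaptic spike of a
    stimulus the winner tracks the subthreshold ramp, so all three
    layers charge concurrently and spike a few milliseconds apart each
    theta cycle.  Because membrane noise can desynchronise the two
    driven sensory cells by an Euler step, the spike-step evaluation
    occasionally selects a different hippocampal winner — the noise-driven
    exploration that lets runs escape poor weight configurations.

    Motor spikes are counted against the adaptive thresholds; a dig ends
    the trial, a move switches the stimulus (re-initialising the
    membrane state).  If no dig occurs within ``t_trial`` the trial
    times out unrewarded.

    The three layers are stepped as one fused potential vector for
    speed; the update and the order of random draws are identical to
    stepping each layer with :func:`replaynet.neurons.step_layer` in
    sensory, hippocampal, motor order.
    """
    n_s, n_h, n_m = config.n_sensory, config.n_hippo, config.n_motor
    n_tot = n_s + n_h + n_m
    h_lo, h_hi = n_s, n_s + n_h
    v_reset = neuron_params.v_reset
    v_th = neuron_params.v_threshold
    v_peak = neuron_params.v_peak
    decay = 1.0 - dt * neuron_params.leak_conductance / neuron_params.capacitance
    leak_base = (1.0 - decay) * v_reset
    c_dt = dt / neuron_params.capacitance
    sd = neuron_params.noise_sd
    w_sh = synapses.exc_sensory_to_hippo
    w_hm = synapses.exc_hippo_to_motor
    w_ih = synapses.inh_hippo
    w_im = synapses.inh_motor

    potentials = np.full(n_tot, v_reset)
    currents = np.zeros(n_tot)
    currents[:n_s] = encode_stimulus(state, config)
    base = leak_base + c_dt * currents
    prev_spiked: np.ndarray | None = None  # indices at peak last step

    steps: list[ActionStep] = []
    spikes: dict[str, list[tuple[int, float]]] = {
        "sensory": [],
        "hippo": [],
        "motor": [],
    }
    counts = [0, 0]
    hippo_winner = -1
    hippo_current = -1  # cell holding the current pulse
    motor_current = -1
    h_gated = not RAMP_BOOTSTRAP
    m_gated = not RAMP_BOOTSTRAP
    seg_start = 0.0
    max_steps = int(round(task_params.t_trial / dt))
    rewarded = False
    timed_out = True
    t = 0.0

    for step in range(max_steps):
        t = (step + 1) * dt
        potentials *= decay
        potentials += base
        if sd > 0.0:
            potentials += sd * rng.standard_normal(n_tot)
        if prev_spiked is not None:
            potentials[prev_spiked] = v_reset
            prev_spiked = None
        crossed = potentials > v_th
        if crossed.any():
            prev_spiked = np.flatnonzero(crossed)
            potentials[prev_spiked] = v_peak
            if not np.isfinite(potentials).all():
                raise IntegrationError(
                    "non-finite membrane potential; dt too large for the "
                    "current/voltage scale"
                )

        # Route the current pulses.  The winner of a layer is re-evaluated
        # on the steps its presynaptic layer spikes and the pulse is held
        # between spikes; before the first presynaptic spike of a stimulus
        # the winner tracks the subthreshold ramp so all three layers
        # charge concurrently.  At spike steps the (noise-desynchronised)
        # spiking cells dominate the score, so which cell wins can vary
        # from cycle to cycle — membrane noise explores winners.
        sens_spiked = False
        hipp_spiked = False
        if prev_spiked is not None:
            sens_spiked = bool(prev_spiked[0] < n_s)
            hipp_spiked = bool((prev_spiked >= h_lo).any() and
                               (prev_spiked < h_hi).any())
        drive_s = potentials[:n_s] - v_reset
        drive_h = potentials[h_lo:h_hi] - v_reset
        drive_m = potentials[h_hi:] - v_reset
        if sens_spiked or not h_gated:
            h_scores = drive_s @ w_sh - drive_h @ w_ih
            w = _route(h_scores, rng)
            if sens_spiked:
                h_gated = True
            if w != hippo_current:
                currents[h_lo:h_hi] = 0.0
                if w >= 0:
                    currents[h_lo + w] = config.i_hippo
                hippo_current = w
                base = leak_base + c_dt * currents
            if w >= 0:
                hippo_winner = w
        if hipp_spiked or not m_gated:
            m_scores = drive_h @ w_hm - drive_m @ w_im
            m = _route(m_scores, rng)
            if hipp_spiked:
                m_gated = True
            if m != motor_current:
                currents[h_hi:] = 0.0
                if m >= 0:
                    currents[h_hi + m] = config.i_motor
                motor_current = m
                base = leak_base + c_dt * currents

        if prev_spiked is None:
            continue
        for i in prev_spiked:
            i = int(i)
            if i < h_lo:
                spikes["sensory"].append((i, t))
            elif i < h_hi:
                spikes["hippo"].append((i - h_lo, t))
            else:
                m_cell = i - h_hi
                spikes["motor"].append((m_cell, t))
                counts[m_cell] += 1
                dig_now = state.dig_threshold == 0 or (
                    m_cell == DIG and counts[DIG] >= state.dig_threshold
                )
                if dig_now:
                    steps.append(
                        ActionStep(state.triplet, hippo_winner, DIG, seg_start, t)
                    )
                    state, _, rewarded = execute_action(state, DIG, task_params)
                    timed_out = False
                    break
                if m_cell == MOVE and counts[MOVE] >= state.move_threshold:
                    steps.append(
                        ActionStep(state.triplet, hippo_winner, MOVE, seg_start, t)
                    )
                    state, _, _ = execute_action(state, MOVE, task_params)
                    if task_params.reset_counts_between_actions:
                        counts = [0, 0]
                    seg_start = t
                    # the executed action changes the stimulus: the membrane
                    # state is re-initialized so the next decision cascade is
                    # driven by the new triplet, not by potentials left over
                    # from the previous one
                    potentials[:] = v_reset
                    currents[:] = 0.0
                    currents[:n_s] = encode_stimulus(state, config)
                    hippo_current = -1
                    motor_current = -1
                    h_gated = not RAMP_BOOTSTRAP
                    m_gated = not RAMP_BOOTSTRAP
                    base = leak_base + c_dt * currents
        if not timed_out:
            break

    state.elapsed_time = t
    return TrialRecord(
        steps=steps,
        rewarded=rewarded,
        timed_out=timed_out,
        duration=t,
        spikes=spikes,
    )


def _route(scores: np.ndarray, rng: np.random.Generator) -> int:
    """Winner index of a score vector, -1 when nothing has positive drive."""
    m = scores.max()
    if m <= 0.0:
        return -1
    tied = np.flatnonzero(scores == m)
    if tied.shape[0] == 1:
        return int(tied[0])
    return int(rng.choice(tied))
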