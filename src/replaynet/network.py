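"""Three-layer architecture and winner-take-all routing.

The network has a sensory layer of six cells (four context-place cells
A1, A2, B1, B2 and two item cells X, Y), a hippocampal layer of eight
cells (configurable) and a motor layer of two cells (dig, move).
Excitatory all-to-all weights connect successive layers; fixed inhibitory
weights connect cells within the hippocampal and motor layers (zero
diagonal — no self-inhibition).

Activity is routed by a winner-take-all rule: each step, the single
downstream cell with the largest weighted presynaptic drive

    score(j) = sum_i (V_i - V_reset) W_exc[i, j]
             - sum_{i != j} (V_post_i - V_reset) W_inh[i, j]

receives its layer's input current; all other cells of that layer
receive none.  The inhibitory sum runs over the receiving layer's own
potentials (lateral inhibition), which gives the current winner
hysteresis and prevents activity left over from an earlier stimulus in
the trial from leaking into the next action.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neurons import LayerState

__all__ = [
    "NetworkConfig",
    "SynapseSet",
    "SENSORY_LABELS",
    "MOTOR_LABELS",
    "DIG",
    "MOVE",
    "init_weights",
    "wta_scores",
    "argmax_with_ties",
    "select_winner",
]

#: Sensory cell ordering: context-place cells first, then item cells.
SENSORY_LABELS = ("A1", "A2", "B1", "B2", "X", "Y")
MOTOR_LABELS = ("Dig", "Move")
DIG, MOVE = 0, 1


@dataclass(frozen=True)
class NetworkConfig:
    """Layer sizes and the per-layer input-current amplitudes.

    The currents decrease from sensory to motor (1.00 > 0.98 > 0.96 nA
    by default); a cell charging under a slightly smaller current reaches
    threshold slightly later, so one stimulus cycle produces an ordered
    sensory -> hippocampal -> motor succession of spikes a few
    milliseconds apart — inside the STDP window during replay.
    """

    n_sensory: int = 6
    n_hippo: int = 8
    n_motor: int = 2
    i_sensory: float = 1.00e-9
    i_hippo: float = 0.98e-9
    i_motor: float = 0.96e-9

    def __post_init__(self) -> None:
        if min(self.n_sensory, self.n_hippo, self.n_motor) <= 0:
            raise ValueError("layer sizes must be positive")
        if not (self.i_sensory > self.i_hippo > self.i_motor > 0):
            raise ValueError("require i_sensory > i_hippo > i_motor > 0")


@dataclass
class SynapseSet:
    """All weight matrices of the network.

    Excitatory matrices are plastic and bounded to ``[w_min, w_max]``;
    inhibitory matrices are fixed after initialization and have an
    exactly zero diagonal.
    """

    exc_sensory_to_hippo: np.ndarray  # (n_sensory, n_hippo)
    exc_hippo_to_motor: np.ndarray  # (n_hippo, n_motor)
    inh_hippo: np.ndarray  # (n_hippo, n_hippo), zero diagonal
    inh_motor: np.ndarray  # (n_motor, n_motor), zero diagonal

    def copy(self) -> "SynapseSet":
        return SynapseSet(
            self.exc_sensory_to_hippo.copy(),
            self.exc_hippo_to_motor.copy(),
            self.inh_hippo.copy(),
            self.inh_motor.copy(),
        )


def init_weights(config: NetworkConfig, rng: np.random.Generator) -> SynapseSet:
    """Draw all weights i.i.d. uniform on [0, 1].

    Inhibitory weights are drawn from the same distribution but stay
    fixed afterwards; their diagonals are forced to zero so no cell
    inhibits itself.
    """
    w_sh = rng.uniform(0.0, 1.0, size=(config.n_sensory, config.n_hippo))
    w_hm = rng.uniform(0.0, 1.0, size=(config.n_hippo, config.n_motor))
    w_ih = rng.uniform(0.0, 1.0, size=(config.n_hippo, config.n_hippo))
    w_im = rng.uniform(0.0, 1.0, size=(config.n_motor, config.n_motor))
    np.fill_diagonal(w_ih, 0.0)
    np.fill_diagonal(w_im, 0.0)
    return SynapseSet(w_sh, w_hm, w_ih, w_im)


def wta_scores(
    pre_potentials: np.ndarray,
    post_potentials: np.ndarray,
    weights_exc: np.ndarray,
    weights_inh: np.ndarray,
    v_reset: float,
) -> np.ndarray:
    """Per-candidate winner-take-all scores for the receiving layer.

    Excitatory drive is the presynaptic potentials above rest weighted by
    ``weights_exc``; the lateral-inhibition term subtracts the receiving
    layer's own above-rest potentials weighted by ``weights_inh`` (whose
    zero diagonal exempts each candidate from inhibiting itself).
    """
    drive = pre_potentials - v_reset
    inh = post_potentials - v_reset
    return drive @ weights_exc - inh @ weights_inh


def argmax_with_ties(scores: np.ndarray, rng: np.random.Generator) -> int:
    """Index of the maximum score; exact ties resolved uniformly at random."""
    m = scores.max()
    tied = np.flatnonzero(scores == m)
    if tied.shape[0] == 1:
        return int(tied[0])
    return int(rng.choice(tied))


def select_winner(
    pre_state: LayerState,
    weights_exc: np.ndarray,
    weights_inh: np.ndarray,
    post_potentials: np.ndarray,
    v_reset: float,
    rng: np.random.Generator,
) -> int | None:
    """Winner-take-all selection triggered by a presynaptic spike.

    Returns ``None`` when no presynaptic cell spiked this step, otherwise
    the single downstream index maximizing :func:`wta_scores` (ties are
    drawn uniformly from the run's random stream).
    """
    if not pre_state.spiked.any():
        return None
    scores = wta_scores(
        pre_state.potentials, post_potentials, weights_exc, weights_inh, v_reset
    )
    return argmax_with_ties(scores, rng)


def route_currents(
    scores: np.ndarray,
    amplitude: float,
    rng: np.random.Generator,
    out: np.ndarray,
) -> int | None:
    """Assign the current pulse to the winning downstream cell, in place.

    The winner of ``scores`` receives ``amplitude``; every other cell
    receives zero.  When no candidate has positive drive (all presynaptic
    potentials at rest, as at the start of a trial) no cell is driven and
    ``None`` is returned.
    """
    out[:] = 0.0
    if scores.max() <= 0.0:
        return None
    j = argmax_with_ties(scores, rng)
    out[j] = amplitude
    return j
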