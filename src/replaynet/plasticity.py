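"""Pair-based spike-timing dependent plasticity with soft weight bounds.

A synapse is updated from the relative timing ``delta = t_post - t_pre``
of a pre/post spike pair.  Pre-before-post (``delta > 0``) potentiates
with amplitude ``A_plus`` and decay ``tau_plus``; post-before-pre
(``delta < 0``) depresses with amplitude ``A_minus`` (negative) and decay
``tau_minus``.  Both branches are scaled by the soft-bound factors
``(w_max - w)`` and ``-(w_min - w)`` so weights saturate smoothly at the
bounds and never leave ``[w_min, w_max]``.

Plasticity is applied only during replay (noise off, single ordered
spikes per cell), so pairing is nearest-neighbour within a short
evaluation window: each post-synaptic spike is paired with the closest
pre-synaptic spike, and pairs further apart than ``pair_window`` are
ignored.

The continuous rule carries a weight time constant ``tau_w``; a spike
pair contributes one discrete increment of the selected branch scaled by
``pair_dt / tau_w``.  ``pair_dt`` is the effective duration a pair acts
on the synapse and is the model's single learning-rate calibration: by
default a pairing acts for the full 10 ms evaluation window, which
equals ``tau_w``, so each pairing contributes its whole term once —
this makes rewarded pathways consolidate within a few replays while
depression (one third the amplitude) dismantles wrong associations over
several failures, and the task is learned within roughly 100-130
trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .network import SynapseSet

__all__ = ["PlasticityParams", "SpikePair", "stdp_increment", "stdp_term",
           "apply_stdp_to_path"]


@dataclass(frozen=True)
class PlasticityParams:
    """STDP constants.

    ``tau_plus`` / ``tau_minus`` (seconds) set the exponential decay of
    potentiation / depression with pair timing; ``amp_plus`` /
    ``amp_minus`` their amplitudes (``amp_minus`` is negative for normal
    learning; the depression-ablation control uses +1.0 / -1.0).
    ``pair_window`` (seconds) is the evaluation window outside which
    spike pairs are discarded.  ``pair_dt`` (seconds) is the effective
    integration time of one pair against ``tau_w`` — the learning rate.
    """

    tau_plus: float = 10e-3
    tau_minus: float = 10e-3
    amp_plus: float = 1.2
    amp_minus: float = -0.4
    w_min: float = 0.0
    w_max: float = 1.0
    tau_w: float = 10e-3
    pair_window: float = 10e-3
    pair_dt: float = 10e-3

    def __post_init__(self) -> None:
        if min(self.tau_plus, self.tau_minus, self.tau_w) <= 0:
            raise ValueError("time constants must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("require w_min < w_max")
        if self.amp_plus <= 0:
            raise ValueError("amp_plus must be positive")
        if self.pair_window <= 0 or self.pair_dt <= 0:
            raise ValueError("pair_window and pair_dt must be positive")


@dataclass(frozen=True)
class SpikePair:
    """One pre/post spike pairing; ``delta = post_time - pre_time``."""

    pre_time: float
    post_time: float

    @property
    def delta(self) -> float:
        return self.post_time - self.pre_time


def stdp_term(w: float, delta: float, params: PlasticityParams) -> float:
    """Unscaled weight-change term for a single pair timing.

    Returns ``(w_max - w) * A_plus * exp(-delta/tau_plus)`` for
    ``delta > 0`` and ``-(w_min - w) * A_minus * exp(delta/tau_minus)``
    for ``delta < 0``; zero for a simultaneous pair.
    """
    if delta > 0:
        return (params.w_max - w) * params.amp_plus * math.exp(-delta / params.tau_plus)
    if delta < 0:
        return -(params.w_min - w) * params.amp_minus * math.exp(delta / params.tau_minus)
    return 0.0


def stdp_increment(
    w: float,
    pair: SpikePair,
    params: PlasticityParams,
    dt: float | None = None,
) -> float:
    """New weight after one spike pair.

    The branch selected by the sign of ``pair.delta`` is scaled by
    ``dt / tau_w`` (``dt`` defaults to ``params.pair_dt``) and the result
    is clamped to ``[w_min, w_max]``.  Pairs with ``delta == 0`` or
    ``|delta| > pair_window`` leave the weight unchanged.
    """
    delta = pair.delta
    if delta == 0.0 or abs(delta) > params.pair_window:
        return w
    if dt is None:
        dt = params.pair_dt
    w_new = w + stdp_term(w, delta, params) * (dt / params.tau_w)
    return min(max(w_new, params.w_min), params.w_max)


def _nearest(value: float, sorted_times: Sequence[float]) -> float:
    best = sorted_times[0]
    gap = abs(value - best)
    for t in sorted_times[1:]:
        d = abs(value - t)
        if d < gap:
            best, gap = t, d
    return best


def apply_pairwise_stdp(
    weights,  # np.ndarray, shape (n_pre, n_post), modified in place
    pre_spikes: Mapping[int, Sequence[float]],
    post_spikes: Mapping[int, Sequence[float]],
    params: PlasticityParams,
) -> None:
    """Update one weight matrix from pre/post spike trains, in place.

    Each post-synaptic spike is paired with its nearest pre-synaptic
    spike; pairs within ``pair_window`` produce one
    :func:`stdp_increment` on the corresponding weight.
    """
    for j, post_times in post_spikes.items():
        if not post_times:
            continue
        for i, pre_times in pre_spikes.items():
            if not pre_times:
                continue
            w = weights[i, j]
            for t_post in post_times:
                t_pre = _nearest(t_post, pre_times)
                w = stdp_increment(w, SpikePair(t_pre, t_post), params)
            weights[i, j] = w


def apply_stdp_to_path(
    synapses: "SynapseSet",
    spike_log: Mapping[str, Mapping[int, Sequence[float]]],
    params: PlasticityParams,
) -> "SynapseSet":
    """Apply STDP along the sensory->hippocampal->motor pathway.

    ``spike_log`` maps layer names (``"sensory"``, ``"hippo"``,
    ``"motor"``) to per-cell spike-time lists recorded during one replay
    episode (noise off).  Both excitatory stages are updated with the
    same parameters; inhibitory weights are fixed.  An empty log leaves
    the weights unchanged.  Returns ``synapses`` (modified in place).
    """
    sens = spike_log.get("sensory", {})
    hipp = spike_log.get("hippo", {})
    moto = spike_log.get("motor", {})
    apply_pairwise_stdp(synapses.exc_sensory_to_hippo, sens, hipp, params)
    apply_pairwise_stdp(synapses.exc_hippo_to_motor, hipp, moto, params)
    return synapses
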