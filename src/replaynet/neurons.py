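"""Leaky integrate-and-fire membrane dynamics.

Every cell in the model — sensory, hippocampal and motor — is a point
neuron whose membrane potential ``V`` relaxes toward a resting value
``V_reset`` with conductance ``G_l`` while being charged by an input
current ``I``:

    C dV/dt = -G_l (V - V_reset) + I + eta

``eta`` is an additive Gaussian fluctuation applied once per Euler step.
When ``V`` crosses the firing threshold ``V_th`` the cell is held at the
peak potential ``V_peak`` for exactly one step (the spike) and is then
clamped back to ``V_reset`` on the following step.

The integrator is explicit Euler with a fixed step ``dt``; with the
default membrane constants and a 0.5 ms step, a constant 1.00 nA drive
produces an inter-spike interval of ~124 ms (8.1 Hz, theta band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "LayerState",
    "IntegrationError",
    "SubthresholdCurrentError",
    "step_layer",
    "analytic_time_to_threshold",
]


class IntegrationError(RuntimeError):
    """A membrane potential became non-finite or left the physical range.

    This signals that the Euler step is too large for the current/voltage
    scale in use, not a recoverable condition.
    """


class SubthresholdCurrentError(ValueError):
    """The constant current cannot drive the potential up to threshold."""


@dataclass(frozen=True)
class NeuronParams:
    """Membrane constants shared by every cell of one layer.

    Parameters
    ----------
    capacitance : float
        Membrane capacitance C in farads.
    leak_conductance : float
        Leak conductance G_l in siemens.
    v_peak : float
        Potential the cell is held at during its spike step, volts.
    v_threshold : float
        Firing threshold V_th, volts.
    v_reset : float
        Reset / resting potential V_reset, volts.
    noise_sd : float
        Standard deviation of the Gaussian increment added to the
        potential once per Euler step, volts.  Set to zero (or pass
        ``rng=None`` to :func:`step_layer`) for deterministic replay.
    """

    capacitance: float = 5.5e-9
    leak_conductance: float = 10e-9
    v_peak: float = 0.0
    v_threshold: float = -50e-3
    v_reset: float = -70e-3
    noise_sd: float = 1e-6

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        if self.leak_conductance <= 0:
            raise ValueError("leak_conductance must be positive")
        if not (self.v_reset < self.v_threshold < self.v_peak):
            raise ValueError("require v_reset < v_threshold < v_peak")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def tau(self) -> float:
        """Membrane time constant C / G_l in seconds."""
        return self.capacitance / self.leak_conductance


@dataclass
class LayerState:
    """Mutable per-cell state of one layer.

    ``potentials`` holds the membrane potential of each cell in volts,
    ``spiked`` flags cells currently at their spike step, and
    ``input_currents`` the drive (amperes) applied on the next step.
    """

    potentials: np.ndarray
    spiked: np.ndarray
    input_currents: np.ndarray

    @classmethod
    def at_rest(cls, n: int, params: NeuronParams) -> "LayerState":
        """A layer of ``n`` cells at the resting potential with zero drive."""
        if n <= 0:
            raise ValueError("cell count must be positive")
        return cls(
            potentials=np.full(n, params.v_reset, dtype=float),
            spiked=np.zeros(n, dtype=bool),
            input_currents=np.zeros(n, dtype=float),
        )

    @property
    def n(self) -> int:
        return self.potentials.shape[0]

    def copy(self) -> "LayerState":
        return LayerState(
            self.potentials.copy(), self.spiked.copy(), self.input_currents.copy()
        )


def step_layer(
    state: LayerState,
    params: NeuronParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> LayerState:
    """Advance one layer by a single Euler step, in place.

    Cells flagged as spiking on the previous step are clamped to
    ``v_reset`` and unflagged; all other cells take one Euler step of the
    leak-toward-``v_reset`` dynamics driven by their input current, plus a
    Gaussian increment of standard deviation ``noise_sd`` when ``rng`` is
    given.  Cells whose new potential exceeds ``v_threshold`` are set to
    ``v_peak`` and flagged as spiking.

    Returns the same ``state`` object for chaining.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = state.potentials
    prev = state.spiked

    dv = (dt / params.capacitance) * (
        params.leak_conductance * (params.v_reset - v) + state.input_currents
    )
    if rng is not None and params.noise_sd > 0:
        dv += params.noise_sd * rng.standard_normal(v.shape[0])
    v += dv
    # spike step is over: clamp to reset before threshold detection so a
    # cell cannot re-trigger off its own peak potential
    if prev.any():
        v[prev] = params.v_reset

    if not np.isfinite(v).all():
        raise IntegrationError(
            "non-finite membrane potential; dt too large for the "
            "current/voltage scale"
        )

    crossed = v > params.v_threshold
    if crossed.any():
        v[crossed] = params.v_peak
    state.spiked = crossed
    return state


def analytic_time_to_threshold(params: NeuronParams, current: float) -> float:
    """Closed-form charging time from reset to threshold at constant drive.

    For the noise-free subthreshold dynamics the potential approaches the
    asymptote ``V_reset + I/G_l`` exponentially with time constant
    ``tau = C/G_l``; the threshold is reached after

        tau * ln( (I/G_l) / (I/G_l - (V_th - V_reset)) )

    This is the independent oracle used to validate the Euler integrator.

    Raises
    ------
    SubthresholdCurrentError
        If ``I/G_l <= V_th - V_reset`` so the threshold is unreachable.
    """
    drive = current / params.leak_conductance
    gap = params.v_threshold - params.v_reset
    if drive <= gap:
        raise SubthresholdCurrentError(
            f"current {current!r} A cannot reach threshold "
            f"(I/G_l = {drive:.4g} V <= {gap:.4g} V)"
        )
    return params.tau * np.log(drive / (drive - gap))
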