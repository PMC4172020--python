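import numpy as np
import pytest
from hypothesis import settings

from replaynet import NetworkConfig, NeuronParams, PlasticityParams, TaskParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def neuron_params() -> NeuronParams:
    return NeuronParams()


@pytest.fixture
def plasticity_params() -> PlasticityParams:
    return PlasticityParams()


@pytest.fixture
def network_config() -> NetworkConfig:
    return NetworkConfig()


@pytest.fixture
def task_params() -> TaskParams:
    return TaskParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def naive_synapses():
    """The hand-wired one-cell-per-triplet connectivity.

    Each hippocampal cell responds to exactly one context-place/item pair
    and projects to the action that pair requires (dig for rewarded
    triplets, move otherwise).  Sensory row order: A1, A2, B1, B2, X, Y.
    """
    from replaynet.network import SynapseSet

    w_sh = np.zeros((6, 8))
    w_hm = np.zeros((8, 2))
    # cells 0-3 are the rewarded triplets A1X, B1Y, A2X, B2Y -> dig
    # cells 4-7 are the non-rewarded triplets A1Y, B1X, A2Y, B2X -> move
    wiring = [
        ("A1", "X", 0, 0), ("B1", "Y", 1, 0), ("A2", "X", 2, 0), ("B2", "Y", 3, 0),
        ("A1", "Y", 4, 1), ("B1", "X", 5, 1), ("A2", "Y", 6, 1), ("B2", "X", 7, 1),
    ]
    sensory_index = {"A1": 0, "A2": 1, "B1": 2, "B2": 3, "X": 4, "Y": 5}
    for cp, item, cell, action in wiring:
        w_sh[sensory_index[cp], cell] = 1.0
        w_sh[sensory_index[item], cell] = 1.0
        w_hm[cell, action] = 1.0
    return SynapseSet(
        exc_sensory_to_hippo=w_sh,
        exc_hippo_to_motor=w_hm,
        inh_hippo=np.zeros((8, 8)),
        inh_motor=np.zeros((2, 2)),
    )


@pytest.fixture
def naive_wiring():
    return naive_synapses()
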