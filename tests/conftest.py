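import numpy as np
import pytest

from plasticnet import Network, PopulationSpec, SimConfig, build_topology
from plasticnet.network import EXCITATORY, INHIBITORY


@pytest.fixture(scope="session")
def recovery():
    """Feedforward Poisson toy, 300 s of learning (shared: it is the
    costliest fixture after the self-organisation run)."""
    from plasticnet.pipeline import rate_recovery_experiment

    return rate_recovery_experiment(duration_s=300.0, seed=1)


@pytest.fixture
def sim_cfg():
    return SimConfig()


@pytest.fixture
def two_neuron_net():
    """One stimulus neuron feeding one excitatory neuron."""
    pops = [
        PopulationSpec("D", 1, 1, 1.0, EXCITATORY, 0.0, 0.0),
        PopulationSpec("E", 1, 1, 1.0, EXCITATORY, 0.0, 0.0),
    ]
    topo = build_topology(pops, radius=10.0)
    return Network(topo, SimConfig(), {
        ("D", "E"): {"gamma": 1e-3, "epsilon": 1e-6, "w_init": 1e-2},
    })


@pytest.fixture
def small_net():
    """A 3x3 stimulus grid over a 4x4 excitatory and 2x2 inhibitory grid."""
    pops = [
        PopulationSpec("D", 3, 3, 4.0 / 3.0, EXCITATORY, 0.0, 0.0),
        PopulationSpec("E", 4, 4, 1.0, EXCITATORY, 0.0, 0.0),
        PopulationSpec("I", 2, 2, 2.0, INHIBITORY, -80.0, 0.0),
    ]
    topo = build_topology(pops, radius=3.0)
    params = {
        ("D", "E"): {"gamma": 6.83e-4, "epsilon": 1.25e-6, "w_init": 2.2e-2},
        ("D", "I"): {"gamma": 2.73e-3, "epsilon": 1.25e-6, "w_init": 2.2e-2},
        ("E", "E"): {"gamma": 1.67e-3, "epsilon": 5.12e-7, "w_init": 1e-3},
        ("E", "I"): {"gamma": 6.67e-3, "epsilon": 5.12e-7, "w_init": 1e-3},
        ("I", "E"): {"gamma": 2.78e-4, "epsilon": 1.13e-6, "w_init": 1e-3},
        ("I", "I"): {"gamma": 1.11e-3, "epsilon": 1.13e-6, "w_init": 1e-3},
    }
    return Network(topo, SimConfig(), params)


def constant_stimulus(neuron_steps, n_steps, n_neurons, dt=0.1):
    """StimulusSpikes from an explicit {step: [neurons]} mapping."""
    from plasticnet.stimulus import StimulusSpikes

    steps = []
    neurons = []
    for s in sorted(neuron_steps):
        for j in neuron_steps[s]:
            steps.append(s)
            neurons.append(j)
    steps = np.asarray(steps, dtype=np.int64)
    neurons = np.asarray(neurons, dtype=np.int64)
    indptr = np.searchsorted(steps, np.arange(n_steps + 1))
    return StimulusSpikes(n_steps=n_steps, indptr=indptr, neuron=neurons,
                          n_neurons=n_neurons, dt=dt)
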