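import numpy as np
import pytest

from behavnet import Behaviour, Network, NeuronGroup, SynapseGroup


class CallLogger(Behaviour):
    """Appends a label to a shared log on every iteration (pipeline probe)."""

    def __init__(self, label, log, **kw):
        super().__init__(label=label, **kw)
        self.label = label
        self.log = log

    def new_iteration(self, parent):
        self.log.append(self.label)


class Counter(Behaviour):
    def set_variables(self, parent):
        self.count = 0

    def new_iteration(self, parent):
        self.count += 1


class WriteValue(Behaviour):
    """Writes a constant into a state vector each step (order probe)."""

    def __init__(self, name, value, **kw):
        super().__init__(name=name, value=value, **kw)

    def set_variables(self, parent):
        parent.new_state_vector(self.init_params["name"], 0.0)

    def new_iteration(self, parent):
        parent.state[self.init_params["name"]][:] = self.init_params["value"]


class ReadValue(Behaviour):
    """Snapshots a state vector each step into .seen (order probe)."""

    def __init__(self, name, **kw):
        super().__init__(name=name, **kw)

    def set_variables(self, parent):
        self.seen = []

    def new_iteration(self, parent):
        self.seen.append(parent.state[self.init_params["name"]].copy())


@pytest.fixture
def simple_net():
    net = Network(seed=0)
    ng = NeuronGroup(net, 10, tag="cells")
    return net, ng


@pytest.fixture
def pair_net():
    net = Network(seed=0)
    src = NeuronGroup(net, 3, tag="src")
    dst = NeuronGroup(net, 4, tag="dst")
    sg = SynapseGroup(net, src, dst, tag="fwd")
    return net, src, dst, sg


def final_state(net):
    """Flat copy of every registered state vector / matrix for bitwise compares."""
    out = {}
    for i, ng in enumerate(net.neuron_groups):
        for name, vec in ng.state.items():
            out[f"ng{i}.{name}"] = np.array(vec, copy=True)
    for i, sg in enumerate(net.synapse_groups):
        for name, mat in sg.matrices.items():
            out[f"sg{i}.{name}"] = np.array(mat, copy=True)
    return out


def assert_states_equal(a, b):
    assert a.keys() == b.keys()
    for key in a:
        np.testing.assert_array_equal(a[key], b[key], err_msg=key)
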