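"""Bundled example networks, built deterministically from a seed.

``build_lif_grid`` is the canonical worked example: 100 leaky
integrate-and-fire neurons on a 10 x 10 grid, coupled by one recurrent
excitatory synapse group, driven by uniform membrane noise.  The default
parameters (threshold 0.5, leak 0.9, noise U(0, 0.1), synaptic strength 0.1,
10 % connection density with afferent sums scaled to 1) give sparse sustained
spiking without runaway excitation.
"""
from __future__ import annotations

from .behaviours import (LIF, STDP, IntrinsicPlasticity, Izhikevich,
                         NormalizeAfferent, Refractory, SynapticInput)
from .core import Network, NeuronGroup, SynapseGroup
from .recording import Recorder

DEFAULT_RECORD = ("n.voltage", "n.spike", "np.mean(n.voltage)")


def build_lif_grid(width=10, height=10, depth=1, seed=0, threshold=0.5,
                   leak_factor=0.9, noise_amplitude=0.1, strength=0.1,
                   density=0.1, receptive_field=None, norm_rows=1.0,
                   record=DEFAULT_RECORD, record_interval=1) -> Network:
    """Recurrent LIF grid: model key 1, synaptic input key 2, recorder key 9."""
    net = Network(tag="lif_example", seed=seed)
    ng = NeuronGroup(net, width * height * depth, tag="exc_neurons")
    ng.add_spatial_layout(width, height, depth)
    SynapseGroup(net, ng, ng, tag="Glutamate,recurrent")
    ng.add_behaviour(1, LIF(threshold=threshold, leak_factor=leak_factor,
                            noise_amplitude=noise_amplitude))
    ng.add_behaviour(2, SynapticInput(strength=strength, weight_init="uniform",
                                      density=density,
                                      receptive_field=receptive_field,
                                      norm_rows=norm_rows))
    if record:
        ng.add_behaviour(9, Recorder(*record, interval=record_interval))
    return net


def build_izhikevich(size=100, seed=0, a=0.02, b=0.2, c=-65.0, d=8.0, I=10.0,
                     record=("n.v", "n.spike"), record_interval=1) -> Network:
    """Uncoupled Izhikevich population (regular-spiking defaults, tonic drive)."""
    net = Network(tag="izhikevich_example", seed=seed)
    ng = NeuronGroup(net, size, tag="izhikevich_neurons")
    ng.add_behaviour(1, Izhikevich(a=a, b=b, c=c, d=d, I=I))
    if record:
        ng.add_behaviour(9, Recorder(*record, interval=record_interval))
    return net


def build_sorn(width=10, height=10, depth=1, seed=0, threshold=0.5,
               leak_factor=0.9, noise_amplitude=0.1, strength=0.1, density=0.1,
               eta_stdp=0.005, norm_target=1.0, eta_ip=0.001, target_rate=0.1,
               refractory_steps=1, record=("n.spike", "np.mean(n.spike)"),
               record_interval=1) -> Network:
    """Self-organizing recurrent network: LIF + STDP + normalization + IP."""
    net = Network(tag="sorn_example", seed=seed)
    ng = NeuronGroup(net, width * height * depth, tag="exc_neurons")
    ng.add_spatial_layout(width, height, depth)
    sg = SynapseGroup(net, ng, ng, tag="Glutamate,recurrent")
    ng.add_behaviour(1, LIF(threshold=threshold, leak_factor=leak_factor,
                            noise_amplitude=noise_amplitude))
    ng.add_behaviour(2, SynapticInput(strength=strength, weight_init="uniform",
                                      density=density, norm_rows=norm_target))
    ng.add_behaviour(3, Refractory(refractory_steps=refractory_steps))
    sg.add_behaviour(5, STDP(eta_stdp=eta_stdp))
    ng.add_behaviour(6, NormalizeAfferent(norm_target=norm_target))
    ng.add_behaviour(7, IntrinsicPlasticity(eta_ip=eta_ip, target_rate=target_rate))
    if record:
        ng.add_behaviour(9, Recorder(*record, interval=record_interval))
    return net


EXAMPLES = {
    "lif": build_lif_grid,
    "izhikevich": build_izhikevich,
    "sorn": build_sorn,
}
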