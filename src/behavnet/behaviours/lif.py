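"""Leaky integrate-and-fire dynamics and recurrent synaptic input.

The LIF variant here is the simplest useful one: resting and reset voltages
are zero, the membrane decays multiplicatively by ``leak_factor`` per step,
uniform noise drives the cell, and crossing ``threshold`` emits a spike and
resets the voltage.  Per-step update order: leak, noise, threshold test,
reset.  All parameters accept diversification strings (e.g.
``leak_factor="normal(0.9,0.1)"``) for per-neuron heterogeneity.
"""
from __future__ import annotations

import warnings

import numpy as np

from ..core import Behaviour, NetworkError


class LIF(Behaviour):
    """Leaky integrate-and-fire neuron model.

    Parameters
    ----------
    threshold : float or spec, default 0.5
        Voltage above which a spike is emitted (arbitrary units).  Registered
        as a per-neuron state vector so homeostatic behaviours can adapt it.
    leak_factor : float or spec in (0, 1], default 0.9
        Multiplicative voltage decay per step.  Values outside (0, 1] are
        allowed but flagged with a warning.
    noise_amplitude : float >= 0, default 0.1
        Per-step membrane noise drawn uniformly from [0, noise_amplitude).
    v_init : float or spec, default 0.0
        Initial voltage.
    """

    reads = frozenset({"voltage", "threshold"})
    writes = frozenset({"voltage", "spike"})

    def set_variables(self, neurons):
        self.leak = self.get_init_attr("leak_factor", 0.9, parent=neurons)
        leak_arr = np.atleast_1d(np.asarray(self.leak, dtype=float))
        if np.any((leak_arr <= 0) | (leak_arr > 1)):
            warnings.warn(
                "leak_factor outside (0, 1]: voltages will grow or flip sign",
                UserWarning, stacklevel=2)
        self.noise_amplitude = float(
            self.get_init_attr("noise_amplitude", 0.1, parent=neurons, diversify=False))
        if self.noise_amplitude < 0:
            raise NetworkError("noise_amplitude must be >= 0")
        neurons.new_state_vector("voltage", self.get_init_attr("v_init", 0.0, parent=neurons))
        neurons.new_state_vector(
            "threshold", self.get_init_attr("threshold", 0.5, parent=neurons))
        neurons.register_state("spike", np.zeros(neurons.size, dtype=bool))

    def new_iteration(self, neurons):
        v = neurons.voltage
        v = self.leak * v
        if self.noise_amplitude > 0:
            v = v + self.rng.uniform(0.0, self.noise_amplitude, neurons.size)
        spike = v > neurons.threshold
        v[spike] = 0.0
        neurons.voltage = v
        neurons.spike = spike


class SynapticInput(Behaviour):
    """Propagate spikes through every afferent synapse group (dot product).

    At initialization a weight matrix ``W`` (dst.size x src.size) is created
    on each afferent synapse group that does not already carry one, with the
    requested value spec / density / receptive field.  Each step adds
    ``strength * (W . spike_src)`` to the destination voltages, using the
    spike vectors produced earlier in the same step's pipeline order.

    Active presynaptic columns are accumulated sequentially in ascending
    global source index.  This fixed summation order is what makes a
    partitioned network bitwise identical to the unpartitioned original.
    """

    reads = frozenset({"spike"})
    writes = frozenset({"voltage"})

    def set_variables(self, neurons):
        self.strength = float(
            self.get_init_attr("strength", 0.1, parent=neurons, diversify=False))
        weight_init = self.init_params.get("weight_init", "uniform")
        density = self.init_params.get("density", 1.0)
        receptive_field = self.init_params.get("receptive_field", None)
        autapses = self.init_params.get("autapses", True)
        norm_rows = self.init_params.get("norm_rows", None)
        for sg in neurons.afferent:
            if weight_init is None or "W" in sg.matrices:
                continue                  # existing matrices survive partitioning
            W = sg.new_matrix("W", init=weight_init, density=density,
                              receptive_field=receptive_field, autapses=autapses)
            if norm_rows is not None:
                sums = W.sum(axis=1)
                nz = sums != 0
                W[nz] *= (float(norm_rows) / sums[nz])[:, None]

    def new_iteration(self, neurons):
        strength = self.strength
        for sg in neurons.afferent:
            W = sg.matrices.get("W")
            if W is None:
                raise NetworkError(
                    f"synapse group {sg.tags or sg} has no weight matrix 'W'")
            src_spike = sg.src.spike
            active = np.flatnonzero(src_spike)
            if active.size == 0:
                continue
            acc = np.zeros(W.shape[0])
            for j in active:              # ascending source index, sequential adds
                acc += W[:, j]
            sg.dst.voltage = sg.dst.voltage + strength * acc


class Refractory(Behaviour):
    """Suppress spiking for ``refractory_steps`` steps after each spike.

    Attach with a key *after* the neuron model: neurons whose counter is still
    running have their spike forced off and voltage reset; an allowed spike
    restarts the counter.  ``refractory_steps=0`` is bitwise identical to not
    attaching the behaviour at all.
    """

    reads = frozenset({"spike"})
    writes = frozenset({"spike", "voltage"})

    def set_variables(self, neurons):
        steps = self.get_init_attr("refractory_steps", 0, parent=neurons, diversify=False)
        if not float(steps).is_integer() or steps < 0:
            raise NetworkError(f"refractory_steps must be a non-negative integer, got {steps}")
        self.steps = int(steps)
        self.counter = np.zeros(neurons.size, dtype=int)

    def new_iteration(self, neurons):
        if self.steps == 0:
            return
        blocked = self.counter > 0
        if blocked.any():
            spike = neurons.spike.copy()
            spike[blocked] = False
            neurons.spike = spike
            v = neurons.voltage
            v[blocked] = 0.0
            neurons.voltage = v
            self.counter[blocked] -= 1
        self.counter[neurons.spike] = self.steps


class NoiseInjection(Behaviour):
    """Add per-neuron uniform noise to a state vector after the model step.

    Useful to drive two differently implemented models with the *identical*
    noise sequence: the injection draws from its own child stream, determined
    only by the network seed and the behaviour's key.
    """

    writes = frozenset({"voltage"})

    def set_variables(self, neurons):
        self.low = float(self.get_init_attr("low", 0.0, diversify=False))
        self.high = float(self.get_init_attr("high", 0.1, diversify=False))
        self.target = self.get_init_attr("target", "voltage", diversify=False)

    def new_iteration(self, neurons):
        xi = self.rng.uniform(self.low, self.high, neurons.size)
        neurons.state[self.target] = neurons.state[self.target] + xi


class ForcedSpikes(Behaviour):
    """Drive the group's spike vector from a prescribed (T x N) train.

    A test/probe behaviour: at iteration t the group emits row t-1 of the
    train; past the end of the train the group is silent.
    """

    writes = frozenset({"spike"})

    def set_variables(self, neurons):
        train = np.asarray(self.init_params["train"], dtype=bool)
        if train.ndim != 2 or train.shape[1] != neurons.size:
            raise NetworkError(
                f"spike train must have shape (T, {neurons.size}), got {train.shape}")
        self.train = train
        neurons.register_state("spike", np.zeros(neurons.size, dtype=bool))

    def new_iteration(self, neurons):
        t = neurons.network.iteration - 1
        if 0 <= t < len(self.train):
            neurons.spike = self.train[t].copy()
        else:
            neurons.spike = np.zeros(neurons.size, dtype=bool)
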