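"""Izhikevich's two-variable spiking neuron model.

Quadratic membrane dynamics with a slow recovery variable, integrated by
forward Euler at dt = 1 ms (parameters in the customary mV/ms scaling):

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

Both derivatives are evaluated on pre-step values.  A spike is detected at
v >= 30 mV *before* the reset: v <- c, u <- u + d.  The classic parameter
quadruples (regular spiking a=0.02, b=0.2, c=-65, d=8, etc.) apply.
"""
from __future__ import annotations

import numpy as np

from ..core import Behaviour


class Izhikevich(Behaviour):

    reads = frozenset({"v", "u"})
    writes = frozenset({"v", "u", "spike"})

    def set_variables(self, neurons):
        self.a = self.get_init_attr("a", 0.02, parent=neurons)
        self.b = self.get_init_attr("b", 0.2, parent=neurons)
        self.c = self.get_init_attr("c", -65.0, parent=neurons)
        self.d = self.get_init_attr("d", 8.0, parent=neurons)
        self.I = self.get_init_attr("I", 0.0, parent=neurons)
        if np.ndim(self.c):
            neurons.register_state("v", np.array(self.c, dtype=float))
        else:
            neurons.new_state_vector("v", float(self.c))
        neurons.register_state("u", np.asarray(self.b * neurons.v, dtype=float))
        neurons.register_state("spike", np.zeros(neurons.size, dtype=bool))

    def new_iteration(self, neurons):
        v, u = neurons.v, neurons.u
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + self.I
        du = self.a * (self.b * v - u)
        v = v + dv
        u = u + du
        spike = v >= 30.0
        if np.ndim(self.c):
            v[spike] = np.asarray(self.c)[spike]
        else:
            v[spike] = self.c
        u[spike] = u[spike] + (np.asarray(self.d)[spike] if np.ndim(self.d) else self.d)
        neurons.v = v
        neurons.u = u
        neurons.spike = spike
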