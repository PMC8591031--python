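"""Plasticity mechanisms in the self-organizing recurrent network (SORN) style:
binary-spike STDP, afferent synaptic weight normalization, and intrinsic
plasticity of firing thresholds.

Each behaviour keeps the spike buffers it needs as private state, so the
neuron model stays ignorant of plasticity.
"""
from __future__ import annotations

import warnings

import numpy as np

from ..core import Behaviour, NetworkError


class STDP(Behaviour):
    """Spike-timing-dependent plasticity on one synapse group.

    With binary spike vectors the weight update is

        dW_ij = eta * [ s_dst_i(t) * s_src_j(t-1)  -  s_dst_i(t-1) * s_src_j(t) ]

    i.e. pre-before-post potentiates by ``eta_stdp`` and post-before-pre
    depresses by the same amount.  Weights are clipped to ``[w_min, w_max]``
    and structurally absent synapses (zeros of the initial density mask) stay
    exactly zero.
    """

    def set_variables(self, synapses):
        self.eta = float(self.get_init_attr("eta_stdp", 0.001, diversify=False))
        self.w_min = float(self.get_init_attr("w_min", 0.0, diversify=False))
        self.w_max = float(self.get_init_attr("w_max", 1.0, diversify=False))
        if self.eta < 0:
            raise NetworkError("eta_stdp must be >= 0")
        if self.w_min > self.w_max:
            raise NetworkError("w_min must not exceed w_max")
        self.structure: np.ndarray | None = None
        self.prev_src = np.zeros(synapses.src.size, dtype=float)
        self.prev_dst = np.zeros(synapses.dst.size, dtype=float)

    def new_iteration(self, synapses):
        W = synapses.matrices.get("W")
        if W is None:
            raise NetworkError(
                f"synapse group {synapses.tags or synapses} has no weight matrix 'W'")
        if self.structure is None:
            self.structure = W != 0
        src = np.asarray(synapses.src.spike, dtype=float)
        dst = np.asarray(synapses.dst.spike, dtype=float)
        if self.eta != 0.0:
            dW = self.eta * (np.outer(dst, self.prev_src) - np.outer(self.prev_dst, src))
            W += dW
            W[~self.structure] = 0.0
            np.clip(W, self.w_min, self.w_max, out=W)
        self.prev_src = src
        self.prev_dst = dst


class NormalizeAfferent(Behaviour):
    """Scale each neuron's total afferent weight sum to ``norm_target``.

    Attached to the *NeuronGroup*: the sum runs jointly over all afferent
    synapse groups (including parts created by partitioning), so the joint
    per-neuron sum — not the per-group sum — equals the target.  Rows with a
    zero total are left untouched.  Negative weights are still normalized by
    the plain sum of values, with a warning.
    """

    def set_variables(self, neurons):
        self.target = float(self.get_init_attr("norm_target", 1.0, diversify=False))
        self.matrix = self.get_init_attr("matrix", "W", diversify=False)
        self._warned_negative = False

    def new_iteration(self, neurons):
        sums = np.zeros(neurons.size)
        pairs = []
        for sg in neurons.afferent:
            W = sg.matrices.get(self.matrix)
            if W is None:
                continue
            if not self._warned_negative and np.any(W < 0):
                warnings.warn(
                    "normalizing rows containing negative weights by their plain sum",
                    UserWarning, stacklevel=2)
                self._warned_negative = True
            idx = sg.dst_indices
            sums[idx] += W.sum(axis=1)
            pairs.append((sg, W, idx))
        factors = np.ones(neurons.size)
        nz = sums != 0
        factors[nz] = self.target / sums[nz]
        for sg, W, idx in pairs:
            W *= factors[idx][:, None]


class IntrinsicPlasticity(Behaviour):
    """Per-neuron threshold adaptation toward a target firing rate.

    Every step: ``threshold_i += eta_ip * (spike_i - target_rate)``.  With a
    noise-driven neuron model this drives the empirical per-step spike
    probability to ``target_rate``.
    """

    reads = frozenset({"spike", "threshold"})
    writes = frozenset({"threshold"})

    def set_variables(self, neurons):
        self.eta = float(self.get_init_attr("eta_ip", 0.001, diversify=False))
        self.target_rate = float(self.get_init_attr("target_rate", 0.05, diversify=False))
        if self.eta < 0:
            raise NetworkError("eta_ip must be >= 0")
        if "threshold" not in neurons.state:
            neurons.new_state_vector("threshold", 0.5)

    def new_iteration(self, neurons):
        if self.eta == 0.0:
            return
        neurons.threshold = neurons.threshold + self.eta * (
            np.asarray(neurons.spike, dtype=float) - self.target_rate)
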