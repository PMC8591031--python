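# behavnet

A modular, behaviour-driven spiking neural network simulation toolkit for
computational neuroscientists who need full control over their model code.
Instead of a fixed neuron/synapse vocabulary, `behavnet` provides a minimal
scaffold — `Network`, `NeuronGroup`, `SynapseGroup` — that carries **no
dynamics of its own**. All computation lives in exchangeable `Behaviour`
modules attached under positive numeric keys; at initialization the keys are
sorted across the whole network into one flat execution pipeline, which the
main loop walks once per time step.

On top of that core the package bundles:

- **Tagging**: `net["my_tag"]` retrieves any tagged object in the tree, with
  transparent caching; recorder expression strings double as tags.
- **Recorders**: compiled expression strings (`"n.voltage"`,
  `"np.mean(n.voltage)"`) captured at a configurable interval, plus recorder
  merging.
- **Behaviour library**: leaky integrate-and-fire neurons, recurrent synaptic
  input, refractory periods, SORN-style STDP / synaptic weight normalization /
  intrinsic plasticity, diffusive (nitric-oxide-like) homeostasis, and the
  Izhikevich model.
- **Equation engine**: Brian2-flavoured model definition from strings like
  `"dv/dt = -v/tau : volt"` with full dimensional checking and forward-Euler
  integration.
- **Partitioning**: replace one large, sparse, locally connected synapse
  group by many small dense ones over masked subgroups — bitwise identical
  simulation results.
- **Evolution**: population-based parameter search through the
  `get_gene(key, default)` / `set_score(score)` contract, so the same script
  runs standalone or under the optimizer.
- **Storage + CLI**: per-run `Data/<experiment>/run_k/` folders (HDF5 arrays,
  JSON parameters), run comparison tables, DOT flow-chart export, and the
  `behavnet` command line.

## The model at the core of the worked example

The bundled example is a grid of simplified leaky integrate-and-fire neurons
with zero resting and reset potential. Per step (forward Euler, arbitrary
units):

```
v  <-  λ v + ξ,          ξ ~ U(0, a)          (leak λ = 0.9, noise a = 0.1)
spike = v > θ;  v[spike] <- 0                  (threshold θ = 0.5)
v_dst <- v_dst + s · (W · spike_src)           (strength s = 0.1)
```

`W` is a dst×src weight matrix with 10 % connection density and per-neuron
afferent sums scaled to 1. Any scalar parameter accepts a *diversification
string* such as `leak_factor="normal(0.9,0.1)"`, which silently turns it into
a per-neuron vector.

## Worked example

```python
import behavnet as bn

net = bn.examples.build_lif_grid(seed=1)     # 100 LIF neurons, 10x10 grid
net.initialize()
net.simulate_iterations(1000)

spikes = net["n.spike"][0].np                # tag query -> recorded trace
print(f"mean rate: {spikes.mean():.4f} spikes/neuron/step")
print(f"mean voltage: {net['np.mean(n.voltage)'][0].np.mean():.3f}")
```

prints

```
mean rate: 0.0435 spikes/neuron/step
mean voltage: 0.314
```

i.e. sparse sustained activity (~4 % of neurons fire per step) with the mean
membrane potential resting well below the 0.5 threshold. The same network is
available from a shell:

```bash
behavnet run-example lif --steps 1000 --seed 1
behavnet export-graph --example lif --out lif.dot
```

A custom behaviour is a small class:

```python
class Dampen(bn.Behaviour):
    def set_variables(self, neurons):
        self.factor = self.get_init_attr("factor", 0.5, parent=neurons)

    def new_iteration(self, neurons):
        neurons.voltage = neurons.voltage * self.factor

net.neuron_groups[0].add_behaviour(3, Dampen(factor="uniform"))
```

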