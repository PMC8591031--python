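# Methods

## Execution model

A simulation is a `Network` holding `NeuronGroup`s (registries of equal-length
state vectors), `SynapseGroup`s (registries of dst×src matrices) and
`Behaviour` modules attached to any of the three under positive numeric keys
(floats allowed, so `2.5` slots between `2` and `3`). `Network.initialize()`
flattens all behaviours into one pipeline sorted by key across every object;
`simulate_iterations(n)` advances the iteration counter and then executes the
whole pipeline, once per step. Behaviours therefore observe 1-based iteration
values, and a recorder with interval *k* fires at iterations k, 2k, … — the
convention all recording semantics in the package are defined against.

**Equal keys.** Ties are executed in registration order and flagged with a
warning; `Network(shuffle_equal_keys=True)` instead permutes each tie bucket
with a stream derived from the network seed. Reproducibility outranks
randomizing tie order: a silently random schedule makes bitwise regression
comparisons impossible.

**Randomness.** The network owns a single root seed. Every group and
behaviour receives an independent `numpy` Generator derived from
`SeedSequence([seed, crc32(object path)])`, where the path encodes the
group's registration index and the behaviour's key. Consequences: adding an
observer (recorder) cannot perturb dynamics; re-initialization resets all
streams, so `initialize → simulate(n)` replays identically; and two networks
built by the same code with the same seed agree bitwise.

**Subgroups.** `SubNeuronGroup` is a masked shared view: reads return the
masked entries, writes land in the parent's vectors. This is the substrate of
partitioning.

## Diversification strings

Scalar behaviour parameters may be given as `NUMBER`, `NAME(args)[;plot]`
(NAME ∈ uniform, normal, lognormal, poisson — drawn per neuron from the
owner's stream), or a callable `f(rng, size)`. Bare `"uniform"` means
U(0, 1). The `;plot` suffix is parsed and ignored by the core (it is a
histogram-preview request for interactive front ends; the library never opens
windows).

## Expression recorders

Recorder sources are compiled once and evaluated in a sandbox exposing only
`n` (parent group), `np` (whitelisted reductions: mean, sum, max, min, std,
…) and `s`/`synapse` on synapse groups; all other names are rejected at
compile time. Recorded arrays are deep-copied — without this, every vector
entry of a trace would alias the final state. The source string is
simultaneously the trace's tag, so `net["np.mean(n.voltage)"]` retrieves the
series. `merge_recorders` collapses redundant recorders on one group into a
single recorder (union of expressions, gcd of intervals) adopting the longest
existing trace per expression; an identical expression recorded under
*different* transforms is deliberately kept as two traces.

Tag queries cache their result on the queried root, keyed by a network-wide
structure version that every structural edit increments; a cached answer is
therefore always identical to a fresh recursive search (property-tested with
randomized edit sequences).

## Bundled dynamics

**LIF** (arbitrary units, rest = reset = 0): per step `v ← λv + U(0, a)`,
spike on `v > θ`, reset to 0; order leak → noise → threshold → reset.
Defaults λ = 0.9, a = 0.1, θ = 0.5 with synaptic strength 0.1, 10 % density
and afferent row sums scaled to 1 were chosen so the 100-neuron example shows
sparse sustained spiking (~4 % per step) rather than silence or runaway
excitation. θ is always registered as a per-neuron vector so homeostatic
rules can adapt it.

**Synaptic input** adds `s·(W·spike_src)` for every afferent synapse group.
The dot product is computed by accumulating active presynaptic columns
sequentially in ascending global source index. This fixed summation order is
deliberate: zero-weight columns contribute exactly 0.0 to a non-negative
accumulator, so a partitioned network — whose parts see only a subset of the
columns — performs the *same* sequence of effective additions and reproduces
the unpartitioned run bitwise, not merely to rounding.

**STDP** (binary spikes, SORN style):
`ΔW_ij = η·[s_dst_i(t)·s_src_j(t−1) − s_dst_i(t−1)·s_src_j(t)]`, clipped to
[w_min, w_max]; structurally absent synapses stay exactly zero. The previous
step's spike vectors are private behaviour state, keeping the neuron model
plasticity-agnostic. Swapping the two spike trains transposes and negates the
update exactly; for a single pre/post pair this is elementwise negation.

**Synaptic normalization** attaches to the *neuron* group and scales each
neuron's total afferent sum — jointly across all afferent synapse groups,
including partition parts — to `norm_target`; zero-sum rows are left alone,
negative weights are normalized by the plain sum with a warning.

**Intrinsic plasticity**: `θ_i ← θ_i + η_ip·(spike_i − r*)`. With
noise-driven LIF neurons this drives the empirical per-step spike probability
to the target; at η_ip = 0.01, r* = 0.05, 200 neurons, the rate over the last
5 000 of 20 000 steps lands within a fraction of a percent of target.

**NOX homeostasis** is a minimal discrete rendition of diffusive
(nitric-oxide-like) homeostasis, not a re-implementation of a detailed
reaction–diffusion model: `n ← (1−λ)n + α·spike + D·∇²n` on the group's grid
with a zero-flux (replicated-edge) Laplacian, then `θ ← θ + η·(n − n*)`. The
replicate-edge Laplacian sums to zero, so with λ = 0 the total messenger mass
is conserved (to ~1e−13 over hundreds of steps in float64). Stability
requires D < 1/(2k) for k diffusing grid dimensions.

**Izhikevich**: `v' = 0.04v² + 5v + 140 − u + I`, `u' = a(bv − u)`, Euler at
dt = 1 ms with both derivatives on pre-step values; spike at v ≥ 30 mV is
detected *before* the reset `v ← c, u ← u + d`. Note that with b = 0.2 the
textbook start v = c = −65, u = bv is not an exact equilibrium — the cell
drifts to the stable rest near −70 mV and stays silent without input, which
is the behaviour the tests pin down.

## Equation engine

Grammar: one definition per line, `d<name>/dt = <expr> : <unit>` for ODEs and
`<name> = <expr> : <unit>` for derived quantities recomputed (not integrated)
each step. Units are second/volt/amp/Hz with power-of-ten prefixes plus `1`
for dimensionless; unit names may appear inside expressions (`y/second`).
Dimensions are checked at parse time by evaluating the expression tree on
unit-carrying quantities — an equation set that parses cannot raise a
dimension error while stepping. States are stored as SI magnitudes of their
declared unit. Integration is forward Euler only, with all right-hand sides
evaluated on pre-step values (simultaneous update); the suite verifies
first-order convergence directly (halving dt halves the max error within
10 %). Per-step noise is available as the reserved symbol `xi_uniform(a,b)`,
drawn from the behaviour's child stream.

**Bitwise engine equivalence.** The equation-defined LIF and the hand-coded
one agree to float rounding for any parameters, and agree *bitwise* when the
per-step contraction is exactly representable: with τ = 2 s and dt = 1 s the
Euler update `v + dt·(−v/τ)` equals `0.5·v` exactly (Sterbenz's lemma), the
same operation the hand-coded model performs with leak 0.5. The packaged
equivalence check uses this configuration, injecting the identical noise
sequence into both models through a shared post-step injection behaviour
whose stream depends only on the seed and its key.

## Partitioning

`infer_max_distance` returns the maximal Chebyshev grid distance spanned by
any nonzero weight (Chebyshev matches axis-aligned block dilation).
`partition_synapse_group` cuts the destination grid into axis-aligned blocks
(`numpy.array_split` semantics; oversized block counts degrade to fewer
blocks), pairs each with the source block dilated by that distance, slices
every registered matrix, and clones the group's behaviours onto each part.
Parts are registered in ascending block index (x fastest), fixing the
cross-part summation order. Partitioning runs on an initialized network —
weight matrices only exist after `set_variables` — and the pipeline is
updated in place without resetting state; bundled behaviours guard against
re-creating an existing matrix, so cloned parts keep the sliced weights.
Normalization stays joint across parts because it sums over all afferent
groups through the parts' destination index maps.

## Evolution

Truncation selection: the top ⌈f·N⌉ by score survive unchanged with cached
scores (elitism ⇒ the best score per generation is non-decreasing); the pool
is refilled by cloning uniformly chosen survivors and perturbing each gene
multiplicatively by `exp(N(0, σ))`, clipped to optional bounds (per-gene
additive mode available). Multiplicative log-normal mutation was chosen as
the default because most neural parameters are positive and scale-like.
Genes discovered at run time via `get_gene` on keys absent from the config
are registered at their defaults for the following generation. A NaN score or
a missing `set_score` marks the individual failed (ranked −∞, never a
survivor); if an entire generation fails the run aborts with the history
intact. `survivor_fraction = 1` is accepted as the degenerate
population-frozen case. Selection is rank-based with a deterministic lineage
tie-break, so outcomes do not depend on evaluation order; evaluations run
sequentially in-process (remote/ssh distribution is out of scope).

## Storage, graphs, CLI

Runs live in `Data/<experiment>/run_<k>/` with `arrays.h5` (HDF5, bitwise
array round-trip), `parameters.json`, `results.json`; indices are allocated
by atomic `mkdir`, so concurrent callers cannot collide and folders are never
overwritten. `compare_runs` returns a pandas table (missing values NaN, never
an error). Flow-chart export writes DOT: nodes are pipeline entries in
execution order; edges come only from the `reads`/`writes` sets behaviours
declare — undeclared access yields a node without edges rather than wrong
edges. The `behavnet` CLI wraps the bundled examples (`run-example`), the
optimizer (`evolve`, plain-text key=value configs), and `export-graph`.

## Problem sizes and limitations

The packaged checks use a 100-neuron grid (500–1000 steps), 200 neurons ×
20 000 steps for the intrinsic-plasticity convergence, 30 generations × 20
individuals for the optimizer, and 200 randomized cases for the tag-cache
property — sizes at which every headline quantity is stable across seeds
while the whole suite runs in seconds. Known limitations: dense matrices only
(partitioning, not sparse storage, addresses locality); forward Euler only;
no synaptic delays or conductance-based synapses; no GUI or video export;
expression and equation sandboxes intentionally reject arbitrary code. The
generator-driven tests show correctness of the mechanisms under the stated
noise model (uniform drive, binary spikes); they do not certify behaviour on
biological spike statistics beyond those assumptions.
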