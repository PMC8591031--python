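"""Network / group / behaviour object model and the global execution pipeline.

The simulation scaffold is deliberately thin: a :class:`Network` holds
:class:`NeuronGroup` and :class:`SynapseGroup` containers, which carry no
dynamics of their own.  All computation lives in :class:`Behaviour` modules
attached to any of the three, each under a positive numeric key.  At
initialization the keys are sorted across the whole network into one flat
pipeline; ``simulate_iterations`` then walks that pipeline once per time step.

Randomness: the network owns a single root seed.  Every group and every
behaviour derives an independent child stream from a stable object path, so
attaching an observer (e.g. a recorder) can never perturb the dynamics.
"""
from __future__ import annotations

import math
import warnings
import zlib
from numbers import Number

import numpy as np

from .diversify import resolve_spec


class NetworkError(Exception):
    """Structural or usage error in the network scaffold."""


class NotInitializedError(NetworkError):
    """An operation that requires an initialized network was called too early."""


def _derive_rng(seed: int, path: str) -> np.random.Generator:
    """Independent child stream for one object, stable under unrelated edits."""
    h = zlib.crc32(path.encode("utf8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))


def _split_tags(tag) -> list[str]:
    if tag is None:
        return []
    if isinstance(tag, (list, tuple, set)):
        return [str(t) for t in tag]
    return [t.strip() for t in str(tag).split(",") if t.strip()]


class NetworkObject:
    """Base for every object participating in the tag tree."""

    def __init__(self, tag=None):
        self.tags: list[str] = _split_tags(tag)
        self.network: "Network | None" = None
        self._tag_cache: dict = {}

    def add_tag(self, tag: str):
        if tag not in self.tags:
            self.tags.append(tag)
        if self.network is not None:
            self.network._bump_structure()

    def _children(self):
        return []

    def __getitem__(self, tag):
        from .tagging import find_by_tag
        return find_by_tag(self, tag)


class Behaviour(NetworkObject):
    """Unit of custom computation attached to a network object.

    Subclasses implement ``set_variables`` (called once at network
    initialization, parent bound) and ``new_iteration`` (called once per
    simulated step in pipeline order).  Constructor keyword arguments are kept
    raw in ``init_params`` and retrieved with :meth:`get_init_attr`, which
    transparently expands diversification strings into per-neuron vectors.
    """

    #: state names this behaviour reads / writes, used for flow-chart export
    reads: frozenset = frozenset()
    writes: frozenset = frozenset()

    def __init__(self, tag=None, **init_params):
        super().__init__(tag)
        cls_tag = type(self).__name__
        if cls_tag not in self.tags:
            self.tags.append(cls_tag)
        self.init_params = dict(init_params)
        self.key = None
        self.parent = None
        self.rng: np.random.Generator | None = None
        self._initialized = False

    def get_init_attr(self, name, default=None, parent=None, diversify=True):
        value = self.init_params.get(name, default)
        if diversify and parent is not None and (isinstance(value, str) or callable(value)):
            rng = self.rng if self.rng is not None else np.random.default_rng(0)
            return resolve_spec(value, rng, parent.size)
        return value

    def set_variables(self, parent):  # pragma: no cover - default hook
        pass

    def new_iteration(self, parent):  # pragma: no cover - default hook
        pass

    def _describe(self) -> str:
        tags = [t for t in self.tags if t != type(self).__name__]
        extra = f" tagged {tags}" if tags else ""
        return f"{type(self).__name__}{extra}"


class SubNeuronGroup:
    """Masked shared view on a parent :class:`NeuronGroup`.

    Reading a registered state variable returns exactly the masked entries;
    writing through the subgroup is visible in the parent (shared-view
    contract).  Anything that is not a state variable is delegated to the
    parent group.
    """

    def __init__(self, parent: "NeuronGroup", mask):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (parent.size,):
            raise NetworkError(
                f"subgroup mask has length {mask.size}, parent group has size {parent.size}")
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "indices", np.flatnonzero(mask))
        object.__setattr__(self, "size", int(mask.sum()))
        object.__setattr__(self, "tags", list(parent.tags))

    def __getattr__(self, name):
        parent = object.__getattribute__(self, "parent")
        state = parent.__dict__.get("state", {})
        if name in state:
            return state[name][object.__getattribute__(self, "indices")]
        return getattr(parent, name)

    def __setattr__(self, name, value):
        parent = self.__dict__["parent"]
        state = parent.__dict__.get("state", {})
        if name in state:
            state[name][self.__dict__["indices"]] = value
        else:
            object.__setattr__(self, name, value)


class SpatialLayout:
    """Grid coordinates for a neuron group.

    The linearization is x-fastest row-major: neuron ``i`` sits at
    ``x = i % width``, ``y = (i // width) % height``, ``z = i // (width*height)``.
    """

    def __init__(self, width: int, height: int, depth: int):
        if min(width, height, depth) < 1:
            raise NetworkError("grid dimensions must be positive")
        self.width, self.height, self.depth = int(width), int(height), int(depth)
        n = self.width * self.height * self.depth
        i = np.arange(n)
        self.x = i % self.width
        self.y = (i // self.width) % self.height
        self.z = i // (self.width * self.height)

    @property
    def size(self) -> int:
        return self.width * self.height * self.depth

    def index_of(self, x: int, y: int, z: int) -> int:
        return x + self.width * (y + self.height * z)


class NeuronGroup(NetworkObject):
    """Population of neurons: a registry of equal-length state vectors.

    Carries no dynamics by default ("empty shell"); behaviours fill it with
    state and update rules.  Registered state vectors are accessible as plain
    attributes (``group.voltage``); assigning to such an attribute validates
    the vector length, so the registry can never drift out of shape.
    """

    def __init__(self, net: "Network", size: int, behaviours: dict | None = None, tag=None):
        super().__init__(tag)
        if type(self).__name__ not in self.tags:
            self.tags.append(type(self).__name__)
        size = int(size)
        if size <= 0:
            raise NetworkError(f"NeuronGroup size must be positive, got {size}")
        self.size = size
        self.behaviours: dict = {}
        self.afferent: list[SynapseGroup] = []
        self.efferent: list[SynapseGroup] = []
        self.layout: SpatialLayout | None = None
        self.rng: np.random.Generator | None = None
        self.state: dict[str, np.ndarray] = {}
        net._register_neuron_group(self)
        for key, beh in (behaviours or {}).items():
            self.add_behaviour(key, beh)

    # -- attribute <-> registry bridge ------------------------------------
    def __getattr__(self, name):
        state = object.__getattribute__(self, "__dict__").get("state")
        if state is not None and name in state:
            return state[name]
        raise AttributeError(f"{type(self).__name__} has no attribute or state {name!r}")

    def __setattr__(self, name, value):
        state = self.__dict__.get("state")
        if state is not None and name in state:
            arr = np.asarray(value)
            if arr.ndim == 0:
                arr = np.full(self.size, value)
            if arr.shape != (self.size,):
                raise NetworkError(
                    f"state vector {name!r} must have length {self.size}, got {arr.shape}")
            state[name] = arr
        else:
            object.__setattr__(self, name, value)

    # -- state helpers ----------------------------------------------------
    def vector(self, init=0.0, dtype=None, rng=None) -> np.ndarray:
        """Unregistered length-``size`` vector from a scalar or diversification spec."""
        if isinstance(init, Number) and not isinstance(init, bool):
            vec = np.full(self.size, float(init))
        elif isinstance(init, bool):
            vec = np.full(self.size, init, dtype=bool)
        elif isinstance(init, (np.ndarray, list, tuple)):
            vec = np.asarray(init)
            if vec.shape != (self.size,):
                raise NetworkError(
                    f"initial vector must have length {self.size}, got {vec.shape}")
            vec = vec.copy()
        else:
            use = rng if rng is not None else self.rng
            if use is None:
                raise NotInitializedError(
                    "random initialization requires an initialized group (no RNG yet)")
            vec = resolve_spec(init, use, self.size)
        return vec.astype(dtype) if dtype is not None else vec

    def new_state_vector(self, name: str, init=0.0, dtype=None, rng=None) -> np.ndarray:
        """Create and register a state vector under ``name``."""
        vec = self.vector(init, dtype=dtype, rng=rng)
        self.state[name] = vec
        return vec

    def register_state(self, name: str, vec: np.ndarray):
        vec = np.asarray(vec)
        if vec.shape != (self.size,):
            raise NetworkError(
                f"state vector {name!r} must have length {self.size}, got {vec.shape}")
        self.state[name] = vec

    # -- structure --------------------------------------------------------
    def add_behaviour(self, key, behaviour: Behaviour):
        self.network._attach_behaviour(self, key, behaviour)
        return behaviour

    def subgroup(self, mask) -> SubNeuronGroup:
        return SubNeuronGroup(self, mask)

    def add_spatial_layout(self, width: int, height: int, depth: int = 1) -> SpatialLayout:
        """Attach grid coordinates; registers ``x``, ``y``, ``z`` as state vectors."""
        layout = SpatialLayout(width, height, depth)
        if layout.size != self.size:
            raise NetworkError(
                f"grid {width}x{height}x{depth} has {layout.size} cells "
                f"but the group has {self.size} neurons")
        self.layout = layout
        self._register_layout_state()
        return layout

    def _register_layout_state(self):
        if self.layout is not None:
            self.register_state("x", self.layout.x.copy())
            self.register_state("y", self.layout.y.copy())
            self.register_state("z", self.layout.z.copy())

    def _children(self):
        return list(self.behaviours.values())


class SynapseGroup(NetworkObject):
    """Connection container between a source and a destination group.

    Registered matrices follow the D x S convention: ``dst.size`` rows,
    ``src.size`` columns.  ``src``/``dst`` may be :class:`NeuronGroup` or
    :class:`SubNeuronGroup`; afferent/efferent bookkeeping always lives on the
    underlying parent groups.
    """

    def __init__(self, net: "Network", src, dst, behaviours: dict | None = None, tag=None):
        super().__init__(tag)
        if type(self).__name__ not in self.tags:
            self.tags.append(type(self).__name__)
        self.src = src
        self.dst = dst
        self.behaviours: dict = {}
        self.rng: np.random.Generator | None = None
        self.matrices: dict[str, np.ndarray] = {}
        net._register_synapse_group(self)
        for key, beh in (behaviours or {}).items():
            self.add_behaviour(key, beh)

    # parent groups and index maps (identity for whole groups)
    @property
    def src_group(self) -> NeuronGroup:
        return self.src.parent if isinstance(self.src, SubNeuronGroup) else self.src

    @property
    def dst_group(self) -> NeuronGroup:
        return self.dst.parent if isinstance(self.dst, SubNeuronGroup) else self.dst

    @property
    def src_indices(self) -> np.ndarray:
        if isinstance(self.src, SubNeuronGroup):
            return self.src.indices
        return np.arange(self.src.size)

    @property
    def dst_indices(self) -> np.ndarray:
        if isinstance(self.dst, SubNeuronGroup):
            return self.dst.indices
        return np.arange(self.dst.size)

    def __getattr__(self, name):
        mats = object.__getattribute__(self, "__dict__").get("matrices")
        if mats is not None and name in mats:
            return mats[name]
        raise AttributeError(f"{type(self).__name__} has no attribute or matrix {name!r}")

    def __setattr__(self, name, value):
        mats = self.__dict__.get("matrices")
        if mats is not None and name in mats:
            arr = np.asarray(value)
            shape = (self.dst.size, self.src.size)
            if arr.shape != shape:
                raise NetworkError(f"matrix {name!r} must have shape {shape}, got {arr.shape}")
            mats[name] = arr
        else:
            object.__setattr__(self, name, value)

    def new_matrix(self, name: str, init=1.0, density: float = 1.0,
                   receptive_field: int | None = None, autapses: bool = True,
                   rng=None) -> np.ndarray:
        """Create and register a D x S weight matrix.

        ``density`` selects exactly ``round(density * n_support)`` nonzero
        positions without replacement from the group's seeded stream, where the
        support is all D*S pairs, or — when ``receptive_field`` is given — the
        pairs within that Chebyshev grid distance (both groups need spatial
        layouts).  Nonzero values follow ``init`` (scalar, diversification
        string, or callable).
        """
        if not (0.0 < density <= 1.0):
            raise NetworkError(f"density must be in (0, 1], got {density}")
        use = rng if rng is not None else self.rng
        if use is None:
            raise NotInitializedError(
                "matrix initialization requires an initialized synapse group (no RNG yet)")
        D, S = self.dst.size, self.src.size
        if receptive_field is None:
            support = np.arange(D * S)
            if not autapses and self.src_group is self.dst_group:
                d_idx, s_idx = np.divmod(support, S)
                support = support[self.dst_indices[d_idx] != self.src_indices[s_idx]]
        else:
            src_l, dst_l = self.src_group.layout, self.dst_group.layout
            if src_l is None or dst_l is None:
                raise NetworkError(
                    "receptive_field initialization requires spatial layouts on both groups")
            si, di = self.src_indices, self.dst_indices
            dx = np.abs(dst_l.x[di][:, None] - src_l.x[si][None, :])
            dy = np.abs(dst_l.y[di][:, None] - src_l.y[si][None, :])
            dz = np.abs(dst_l.z[di][:, None] - src_l.z[si][None, :])
            within = np.maximum(np.maximum(dx, dy), dz) <= receptive_field
            if not autapses and self.src_group is self.dst_group:
                within &= di[:, None] != si[None, :]
            support = np.flatnonzero(within.ravel())
        k = int(round(density * support.size))
        chosen = use.choice(support, size=k, replace=False) if k < support.size else support
        mat = np.zeros((D, S))
        mat.flat[np.sort(chosen)] = resolve_spec(init, use, k)
        self.matrices[name] = mat
        return mat

    def register_matrix(self, name: str, mat: np.ndarray):
        mat = np.asarray(mat)
        shape = (self.dst.size, self.src.size)
        if mat.shape != shape:
            raise NetworkError(f"matrix {name!r} must have shape {shape}, got {mat.shape}")
        self.matrices[name] = mat

    def add_behaviour(self, key, behaviour: Behaviour):
        self.network._attach_behaviour(self, key, behaviour)
        return behaviour

    def _children(self):
        return list(self.behaviours.values())


class Network(NetworkObject):
    """Container of all groups plus the globally ordered behaviour pipeline."""

    def __init__(self, tag=None, behaviours: dict | None = None, seed: int = 0,
                 shuffle_equal_keys: bool = False):
        super().__init__(tag)
        if "Network" not in self.tags:
            self.tags.append("Network")
        self.network = self
        self.neuron_groups: list[NeuronGroup] = []
        self.synapse_groups: list[SynapseGroup] = []
        self.behaviours: dict = {}
        self.iteration = 0
        self.seed = int(seed)
        self.shuffle_equal_keys = shuffle_equal_keys
        self._entries: list | None = None          # (key, reg_index, behaviour, parent)
        self._reg_counter = 0
        self._structure_version = 0
        for key, beh in (behaviours or {}).items():
            self.add_behaviour(key, beh)

    # -- structure bookkeeping -------------------------------------------
    def _bump_structure(self):
        self._structure_version += 1

    def _register_neuron_group(self, ng: NeuronGroup):
        ng.network = self
        ng._path = f"neurons[{len(self.neuron_groups)}]"
        self.neuron_groups.append(ng)
        self._bump_structure()

    def _register_synapse_group(self, sg: SynapseGroup):
        if sg.src_group not in self.neuron_groups or sg.dst_group not in self.neuron_groups:
            raise NetworkError("SynapseGroup endpoints must be groups of the same network")
        sg.network = self
        sg._path = f"synapses[{len(self.synapse_groups)}]"
        self.synapse_groups.append(sg)
        sg.dst_group.afferent.append(sg)
        sg.src_group.efferent.append(sg)
        self._bump_structure()

    def _attach_behaviour(self, parent, key, behaviour: Behaviour):
        if not isinstance(key, Number) or isinstance(key, bool) or not key > 0:
            raise NetworkError(
                f"behaviour key must be a positive number, got {key!r} "
                f"for {behaviour._describe()}")
        if key in parent.behaviours:
            raise NetworkError(f"key {key!r} already used on this object")
        parent.behaviours[key] = behaviour
        behaviour.network = self
        self._bump_structure()
        if self._entries is not None:            # live insertion into a running network
            self._bind_behaviour(key, behaviour, parent)
            self._insert_entry(key, behaviour, parent)
            behaviour.set_variables(parent)
            behaviour._initialized = True

    def _remove_behaviour(self, parent, key):
        beh = parent.behaviours.pop(key)
        if self._entries is not None:
            self._entries = [e for e in self._entries if e[2] is not beh]
        self._bump_structure()
        return beh

    def _remove_synapse_group(self, sg: SynapseGroup):
        self.synapse_groups.remove(sg)
        sg.dst_group.afferent.remove(sg)
        sg.src_group.efferent.remove(sg)
        if self._entries is not None:
            self._entries = [e for e in self._entries if e[3] is not sg]
        self._bump_structure()

    def add_behaviour(self, key, behaviour: Behaviour):
        self._attach_behaviour(self, key, behaviour)
        return behaviour

    def _parent_path(self, parent) -> str:
        return "network" if parent is self else parent._path

    def _bind_behaviour(self, key, behaviour, parent):
        behaviour.key = key
        behaviour.parent = parent
        behaviour.rng = _derive_rng(self.seed, f"{self._parent_path(parent)}/behaviour[{key!r}]")

    def _insert_entry(self, key, behaviour, parent):
        self._reg_counter += 1
        entry = (key, self._reg_counter, behaviour, parent)
        pos = len(self._entries)
        for i, e in enumerate(self._entries):
            if e[0] > key:
                pos = i
                break
        self._entries.insert(pos, entry)

    # -- initialization ---------------------------------------------------
    def initialize(self, seed: int | None = None):
        """Sort all behaviours into the pipeline and call their ``set_variables``.

        Re-initialization resets the iteration counter, every state registry,
        and all RNG streams, so a re-initialized network replays a fresh run.
        """
        if seed is not None:
            self.seed = int(seed)
        self.iteration = 0
        self.rng = _derive_rng(self.seed, "network")
        for ng in self.neuron_groups:
            ng.rng = _derive_rng(self.seed, ng._path)
            ng.state.clear()
            ng._register_layout_state()
        for sg in self.synapse_groups:
            sg.rng = _derive_rng(self.seed, sg._path)
            sg.matrices.clear()

        entries = []
        reg = 0
        for parent in [self, *self.neuron_groups, *self.synapse_groups]:
            for key, beh in parent.behaviours.items():
                if not isinstance(key, Number) or isinstance(key, bool) or not key > 0:
                    raise NetworkError(
                        f"behaviour key must be a positive number, got {key!r} "
                        f"for {beh._describe()}")
                reg += 1
                entries.append((key, reg, beh, parent))
        self._reg_counter = reg

        keys = [e[0] for e in entries]
        dup = sorted({k for k in keys if keys.count(k) > 1})
        if dup:
            if self.shuffle_equal_keys:
                tie_rng = _derive_rng(self.seed, "tie_shuffle")
                buckets: dict = {}
                for e in entries:
                    buckets.setdefault(e[0], []).append(e)
                entries = []
                for k in sorted(buckets):
                    group = buckets[k]
                    if len(group) > 1:
                        group = [group[i] for i in tie_rng.permutation(len(group))]
                    entries.extend(group)
            else:
                warnings.warn(
                    f"behaviours share keys {dup}; ties run in registration order "
                    "(set shuffle_equal_keys=True to randomize with the network seed)",
                    UserWarning, stacklevel=2)
                entries.sort(key=lambda e: e[0])
        else:
            entries.sort(key=lambda e: e[0])

        self._entries = entries
        for key, _, beh, parent in entries:
            self._bind_behaviour(key, beh, parent)
            beh._initialized = False
        for key, _, beh, parent in entries:
            beh.set_variables(parent)
            beh._initialized = True
        self._bump_structure()
        return self.pipeline

    @property
    def pipeline(self):
        if self._entries is None:
            return None
        return [(k, b, p) for k, _, b, p in self._entries]

    # -- simulation -------------------------------------------------------
    def simulate_iterations(self, n: int):
        """Run ``n`` steps; each step executes the full pipeline in key order."""
        if self._entries is None:
            raise NotInitializedError("network must be initialized before simulating")
        n = int(n)
        if n < 0:
            raise NetworkError(f"cannot simulate a negative number of steps ({n})")
        entries = self._entries
        for _ in range(n):
            self.iteration += 1
            for _, _, beh, parent in entries:
                beh.new_iteration(parent)

    def _children(self):
        return [*self.behaviours.values(), *self.neuron_groups, *self.synapse_groups]
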