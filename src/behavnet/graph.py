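"""Flow-chart export of the execution pipeline in DOT format.

Nodes are behaviour modules in execution order (an ``order`` attribute holds
the pipeline position; ``rankdir=LR`` lays them out left to right).  Directed
edges are derived from declared state access: behaviour classes advertise the
state names they read and write via their ``reads`` / ``writes`` attributes,
and a writer is connected to every reader of the same name.  A behaviour with
undeclared accesses simply yields a node without edges — never wrong edges.
"""
from __future__ import annotations

from .core import Network, NotInitializedError


def _label(beh, parent) -> str:
    tags = [t for t in getattr(parent, "tags", []) if not t.endswith("Group")
            and t != "Network"]
    where = f"\\n({tags[0]})" if tags else ""
    return f"{type(beh).__name__}\\nkey={beh.key}{where}"


def export_module_graph(obj, path=None) -> str:
    """DOT graph of the behaviours of ``obj`` (a group, or a whole Network)."""
    net = obj if isinstance(obj, Network) else obj.network
    if net is None or net.pipeline is None:
        raise NotInitializedError("initialize the network before exporting its graph")
    entries = [(i, beh, parent) for i, (key, beh, parent) in enumerate(net.pipeline)
               if isinstance(obj, Network) or parent is obj]

    lines = ["digraph modules {", "  rankdir=LR;", "  node [shape=box];"]
    ids = {}
    for order, (pos, beh, parent) in enumerate(entries):
        name = f"b{order}"
        ids[id(beh)] = name
        lines.append(f'  {name} [label="{_label(beh, parent)}" order={pos}];')
    for _, writer, _ in entries:
        for _, reader, _ in entries:
            if reader is writer:
                continue
            shared = sorted(frozenset(writer.writes) & frozenset(reader.reads))
            if shared:
                lines.append(
                    f'  {ids[id(writer)]} -> {ids[id(reader)]} '
                    f'[label="{",".join(shared)}"];')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
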