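"""Tag-based object retrieval over the network tree, with caching.

``obj["my_tag"]`` returns all descendants of ``obj`` (including ``obj``
itself) carrying the tag, in depth-first pre-order.  The first query performs
a recursive search; the result is cached on the queried root and reused until
the network structure changes (adding/removing groups, behaviours or
recorders bumps a version counter).  Recorder expression strings double as
tags of the traces they produce, so ``net["np.mean(n.voltage)"]`` retrieves
the recorded series directly.  An unknown tag returns an empty list.
"""
from __future__ import annotations


def iter_tree(root):
    """Depth-first pre-order walk of ``root`` and its descendants."""
    yield root
    for child in root._children():
        yield from iter_tree(child)


def search(root, tag: str) -> list:
    """Fresh, uncached recursive search (also the oracle the cache must match)."""
    return [obj for obj in iter_tree(root) if tag in obj.tags]


def find_by_tag(root, tag: str, use_cache: bool = True) -> list:
    net = getattr(root, "network", None)
    if not use_cache or net is None:
        return search(root, tag)
    version = net._structure_version
    cache = root._tag_cache
    hit = cache.get(tag)
    if hit is not None and hit[0] == version:
        return list(hit[1])
    result = search(root, tag)
    cache[tag] = (version, result)
    return list(result)
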