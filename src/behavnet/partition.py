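"""Replace a large, sparse, locally connected synapse group by dense parts.

For locally connected grids most of a full D x S weight matrix is zero.
Partitioning cuts the destination grid into axis-aligned blocks, pairs each
block with the minimal source block dilated by the maximal connection
distance, and replaces the original synapse group with one small dense part
per block, attached to shared-view subgroups.  Weight values are preserved
exactly, every original nonzero lands in exactly one part, and — because the
bundled input behaviour accumulates sources in a fixed ascending-index order
— simulation results are bitwise identical to the unpartitioned network.

Distances are Chebyshev (box) distances on the grid, matching the
axis-aligned dilation of the source blocks.
"""
from __future__ import annotations

import numpy as np

from .core import Network, NetworkError, SynapseGroup


def _layouts(sg: SynapseGroup):
    src_l, dst_l = sg.src_group.layout, sg.dst_group.layout
    if src_l is None or dst_l is None:
        raise NetworkError(
            "partitioning requires spatial layouts on both the source and the "
            "destination group")
    return src_l, dst_l


def infer_max_distance(sg: SynapseGroup, matrix: str = "W") -> int:
    """Maximal Chebyshev grid distance spanned by any nonzero weight."""
    src_l, dst_l = _layouts(sg)
    W = sg.matrices.get(matrix)
    if W is None:
        raise NetworkError(f"synapse group has no matrix {matrix!r}")
    d_idx, s_idx = np.nonzero(W)
    if d_idx.size == 0:
        return 0
    dg, sg_idx = sg.dst_indices[d_idx], sg.src_indices[s_idx]
    dx = np.abs(dst_l.x[dg] - src_l.x[sg_idx])
    dy = np.abs(dst_l.y[dg] - src_l.y[sg_idx])
    dz = np.abs(dst_l.z[dg] - src_l.z[sg_idx])
    return int(np.max(np.maximum(np.maximum(dx, dy), dz)))


def _axis_blocks(extent: int, blocks: int) -> list[tuple[int, int]]:
    """Split ``range(extent)`` into at most ``blocks`` contiguous chunks."""
    ranges = []
    for chunk in np.array_split(np.arange(extent), max(1, int(blocks))):
        if chunk.size:
            ranges.append((int(chunk[0]), int(chunk[-1]) + 1))
    return ranges


def partition_synapse_group(net: Network, sg: SynapseGroup, blocks_per_axis,
                            matrix: str = "W") -> list[SynapseGroup]:
    """Replace ``sg`` by dense per-block parts over subgroups.

    ``blocks_per_axis`` is an int (same along every axis) or an
    ``(bx, by, bz)`` triple; blocks larger than the grid degrade gracefully to
    a single-block plan.  All matrices registered on ``sg`` are sliced into
    the parts; all behaviours of ``sg`` are cloned onto each part (same class,
    same constructor arguments).  Parts are registered in ascending block
    index (x fastest), which fixes the floating-point summation order of the
    input behaviour.
    """
    src_l, dst_l = _layouts(sg)
    if sg.matrices.get(matrix) is None:
        raise NetworkError(f"synapse group has no matrix {matrix!r}; "
                           "partition after network initialization")
    if isinstance(blocks_per_axis, (int, np.integer)):
        blocks_per_axis = (blocks_per_axis,) * 3
    bx, by, bz = (max(1, int(b)) for b in blocks_per_axis)
    reach = infer_max_distance(sg, matrix)

    src_group, dst_group = sg.src_group, sg.dst_group
    src_x, src_y, src_z = src_l.x[sg.src_indices], src_l.y[sg.src_indices], \
        src_l.z[sg.src_indices]
    dst_x, dst_y, dst_z = dst_l.x[sg.dst_indices], dst_l.y[sg.dst_indices], \
        dst_l.z[sg.dst_indices]
    full = {name: M for name, M in sg.matrices.items()}
    old_behaviours = dict(sg.behaviours)
    base_tags = [t for t in sg.tags if t != "SynapseGroup"]

    net._remove_synapse_group(sg)

    parts: list[SynapseGroup] = []
    index = 0
    for z0, z1 in _axis_blocks(dst_l.depth, bz):
        for y0, y1 in _axis_blocks(dst_l.height, by):
            for x0, x1 in _axis_blocks(dst_l.width, bx):
                dst_sel = ((dst_x >= x0) & (dst_x < x1)
                           & (dst_y >= y0) & (dst_y < y1)
                           & (dst_z >= z0) & (dst_z < z1))
                if not dst_sel.any():
                    continue
                src_sel = ((src_x >= x0 - reach) & (src_x < x1 + reach)
                           & (src_y >= y0 - reach) & (src_y < y1 + reach)
                           & (src_z >= z0 - reach) & (src_z < z1 + reach))
                if not src_sel.any():
                    continue
                dst_mask = np.zeros(dst_group.size, dtype=bool)
                dst_mask[sg.dst_indices[dst_sel]] = True
                src_mask = np.zeros(src_group.size, dtype=bool)
                src_mask[sg.src_indices[src_sel]] = True
                part = SynapseGroup(
                    net, src_group.subgroup(src_mask), dst_group.subgroup(dst_mask),
                    tag=base_tags + [f"part_{index}"])
                rows = np.flatnonzero(dst_sel)
                cols = np.flatnonzero(src_sel)
                for name, M in full.items():
                    part.register_matrix(name, M[np.ix_(rows, cols)].copy())
                for key, beh in old_behaviours.items():
                    clone = type(beh)(tag=[t for t in beh.tags
                                           if t != type(beh).__name__] or None,
                                      **beh.init_params)
                    part.add_behaviour(key, clone)
                parts.append(part)
                index += 1
    return parts
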