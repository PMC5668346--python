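"""Synthetic fixtures: planted-partition graphs with designed bridge hubs,
exact-edge-count ER graphs, and ring lattices.

The planted-partition generator produces graphs with a known community
structure and, optionally, a set of *bridge* nodes whose edges are spread
evenly over all blocks and who are interconnected among themselves — a
designed diverse club. Bridges give the club phenomena something to find
without any empirical download: high participation coefficient, intra-club
interconnection above chance, and inter-community shortest paths that run
through intra-club edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .communities import Partition
from .graph import WeightedGraph

__all__ = ["PlantedPartitionSpec", "planted_partition", "er_graph", "ring_lattice"]


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Parameters of the planted-partition fixture.

    ``bridge_degree`` edges per bridge node are spread evenly over the
    blocks each bridge serves — all of them by default, or a rotating
    subset of ``blocks_per_bridge`` blocks (bridge j serves blocks
    j, j+1, ... mod blocks). Serving subsets makes bridge-bridge edges
    carry the paths between blocks that share no bridge, which is what
    makes intra-diverse-club edges critical. ``p_bridge`` is the edge
    probability between pairs of bridge nodes (the interconnection of the
    designed diverse club).
    """

    blocks: int = 4
    block_size: int = 15
    p_in: float = 0.8
    p_out: float = 0.05
    bridge_nodes: int = 0
    bridge_degree: int = 8
    blocks_per_bridge: int = 0  # 0 = every block
    p_bridge: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.blocks < 2 or self.block_size < 2:
            raise ValueError("need at least 2 blocks of at least 2 nodes")


def planted_partition(spec: PlantedPartitionSpec) -> tuple[WeightedGraph, Partition]:
    """Stochastic block graph plus optional bridge hubs; ground truth attached.

    Bridge nodes are assigned round-robin to block communities in the ground
    truth (their role is to *span* communities, so any single assignment is
    arbitrary; detection algorithms may place them differently).
    """
    rng = np.random.default_rng(spec.seed)
    b, s = spec.blocks, spec.block_size
    n_block = b * s
    labels = [f"b{i // s}_{i % s}" for i in range(n_block)]
    labels += [f"bridge_{j}" for j in range(spec.bridge_nodes)]
    n = len(labels)
    block_of = np.array([i // s for i in range(n_block)])

    pairs, membership = [], list(block_of)
    iu, ju = np.triu_indices(n_block, k=1)
    same = block_of[iu] == block_of[ju]
    p = np.where(same, spec.p_in, spec.p_out)
    take = rng.random(len(iu)) < p
    pairs.extend(zip(iu[take].tolist(), ju[take].tolist()))

    n_served = spec.blocks_per_bridge or b
    per_block = max(spec.bridge_degree // n_served, 1) if spec.bridge_nodes else 0
    for j in range(spec.bridge_nodes):
        bid = n_block + j
        membership.append(j % b)  # round-robin ground-truth community
        for blk in [(j + t) % b for t in range(n_served)]:
            targets = rng.choice(np.arange(blk * s, (blk + 1) * s), size=per_block, replace=False)
            pairs.extend((bid, int(t)) for t in targets)
        for j2 in range(j):
            if rng.random() < spec.p_bridge:
                pairs.append((n_block + j2, bid))

    edges = np.array(sorted({(min(u, v), max(u, v)) for u, v in pairs}), dtype=np.int64)
    g = WeightedGraph(tuple(labels), edges, np.ones(len(edges)))
    if not g.is_connected():
        warnings.warn("planted-partition draw is disconnected", stacklevel=2)
    truth = Partition(graph=g, membership=np.array(membership), algorithm="planted",
                      params={"spec": spec})
    return g, truth


def er_graph(n: int, density: float, seed: int = 0) -> WeightedGraph:
    """Binary ER graph with exactly floor(density * n(n-1)/2) edges."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    m = int(np.floor(density * n * (n - 1) / 2))
    if m < 1:
        raise ValueError("density too low: no edges")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(len(iu), size=m, replace=False)
    edges = np.column_stack([iu[pick], ju[pick]]).astype(np.int64)
    return WeightedGraph(tuple(str(i) for i in range(n)), edges, np.ones(m))


def ring_lattice(n: int, k: int) -> WeightedGraph:
    """Ring of n nodes, each connected to its k nearest neighbors per side."""
    if k < 1 or 2 * k >= n:
        raise ValueError("need 1 <= k and 2k < n")
    pairs = {(min(i, (i + d) % n), max(i, (i + d) % n)) for i in range(n) for d in range(1, k + 1)}
    edges = np.array(sorted(pairs), dtype=np.int64)
    return WeightedGraph(tuple(str(i) for i in range(n)), edges, np.ones(len(edges)))
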